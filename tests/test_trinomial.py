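"""Unit and property tests for the six trinomial association models."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import migsel as ms
from migsel.trinomial import MODEL_K

from conftest import MODEL_FREE_PARAMS, refine_grid_loglik, trinomial_loglik_vec


class TestTrichotomize:
    def test_definition(self):
        case = np.array([True, True, False])
        sym = np.array([True, False, False])
        ctrl = ~case
        assert ms.trichotomize(case, sym, ctrl).tolist() == [2, 1, 0]

    def test_degenerate_stratum_rejected(self):
        case = np.array([True, True, False])
        no_sym = np.zeros(3, bool)
        with pytest.raises(ms.ValidationError):
            ms.trichotomize(case, no_sym, ~case)

    def test_overlap_rejected(self):
        flags = np.array([True, True, False])
        with pytest.raises(ms.ValidationError):
            ms.trichotomize(flags, flags, flags)


class TestNullClosedForm:
    def test_symmetric_counts(self):
        # 4 controls, 2 cases per subclass: alpha = ln(0.5), ll = 4ln.5 + 4ln.25
        g = np.arange(8, dtype=float) % 3
        y = np.array([0, 0, 0, 0, 1, 1, 2, 2])
        fit = ms.fit_model(g, y, "null")
        assert fit.estimates["alpha_minus"] == pytest.approx(np.log(0.5), abs=1e-9)
        assert fit.estimates["alpha_plus"] == pytest.approx(np.log(0.5), abs=1e-9)
        assert fit.loglik == pytest.approx(4 * np.log(0.5) + 4 * np.log(0.25), abs=1e-4)
        assert fit.bic == pytest.approx(-2 * fit.loglik + 2 * np.log(8), abs=1e-9)


@pytest.mark.parametrize("model", ms.MODELS)
def test_loglik_matches_grid_oracle(small_fixture, model):
    """Newton fits agree with an independent grid-refinement maximizer."""
    g, y = small_fixture
    fit = ms.fit_model(g, y, model)
    ll_oracle, _ = refine_grid_loglik(
        trinomial_loglik_vec(g, y, model), MODEL_FREE_PARAMS[model])
    assert fit.loglik == pytest.approx(ll_oracle, abs=1e-3)
    assert fit.bic == pytest.approx(-2 * fit.loglik + MODEL_K[model] * np.log(12),
                                    abs=1e-9)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_likelihood_nesting(seed):
    """general >= each 3-parameter trinomial model >= null wherever the
    maximizers exist.

    With quasi-complete separation the MLE of an unconstrained slope lies
    at infinity; such fits are flagged (and excluded from BIC selection),
    so the nesting inequality is asserted among non-separated fits only.
    """
    rng = np.random.default_rng(seed)
    n = rng.integers(12, 40)
    g = rng.integers(0, 3, n).astype(float)
    y = rng.integers(0, 3, n)
    if np.bincount(y, minlength=3).min() == 0 or np.ptp(g) == 0:
        return
    fits = {m: ms.fit_model(g, y, m)
            for m in ("null", "basic", "subset", "inverse_subset", "general")}
    ok = {m: f.converged and not f.separated for m, f in fits.items()}
    ll = {m: f.loglik for m, f in fits.items()}
    tol = 1e-6
    if ok["general"]:
        rivals = [ll[m] for m in ("basic", "subset", "inverse_subset") if ok[m]]
        if rivals:
            assert ll["general"] >= max(rivals) - tol
    for m in ("basic", "subset", "inverse_subset"):
        if ok[m]:
            assert ll[m] >= ll["null"] - tol
    # monotone ascent from the null start: never below the null likelihood
    for m in ("basic", "subset", "inverse_subset", "general"):
        assert ll[m] >= ll["null"] - tol


def test_label_swap_maps_subset_onto_inverse_subset(rng):
    """Swapping symptom-present/absent exchanges the roles of the slopes."""
    g = rng.integers(0, 3, 500).astype(float)
    y = rng.integers(0, 3, 500)
    y_sw = np.where(y == 1, 2, np.where(y == 2, 1, 0))
    f_sub = ms.fit_model(g, y, "subset")
    f_inv = ms.fit_model(g, y_sw, "inverse_subset")
    assert f_sub.loglik == pytest.approx(f_inv.loglik, abs=1e-6)
    assert f_sub.estimates["beta_plus"] == pytest.approx(
        f_inv.estimates["beta_minus"], abs=1e-6)


class TestSelection:
    def test_penalty_prefers_null_on_equal_loglik(self, small_fixture):
        g, y = small_fixture
        fits = []
        for m in ("null", "basic", "subset", "general"):
            f = ms.fit_model(g, y, m)
            f.loglik = -10.0  # equal fit quality: parameter count decides
            f.bic = -2 * f.loglik + f.k * np.log(f.n)
            fits.append(f)
        chosen, _ = ms.select_model(fits)
        assert chosen.model == "null"

    def test_bic_difference_is_logn_at_equal_loglik(self):
        assert (3 - 4) * np.log(100) == pytest.approx(-np.log(100))
        # one more parameter at equal loglik costs exactly ln(N)
        g = np.tile([0, 1, 2], 40).astype(float)
        y = np.tile([0, 1, 2, 0, 0, 1], 20)
        f3 = ms.fit_model(g, y, "subset")
        f4 = ms.fit_model(g, y, "general")
        gap = (f4.bic - f3.bic) - (-2 * (f4.loglik - f3.loglik))
        assert gap == pytest.approx(np.log(120), abs=1e-9)

    def test_requires_null(self, small_fixture):
        g, y = small_fixture
        with pytest.raises(ms.ValidationError):
            ms.select_model([ms.fit_model(g, y, "basic")])


class TestLrt:
    def test_null_chosen_gives_unit_p(self, small_fixture):
        g, y = small_fixture
        fits = ms.fit_all_models(g, y)
        lam, df, p = ms.lrt(fits["null"], fits["null"])
        assert (lam, df, p) == (0.0, 0, 1.0)

    def test_chi_square_tail(self):
        # 2*(delta loglik)=10 on 1 df
        assert stats.chi2.sf(10, 1) == pytest.approx(0.001565, abs=5e-7)

    def test_general_lrt_follows_chi2_2_under_null(self):
        """Mean of the 2-df LRT statistic is ~2 under null-generated data."""
        rng = np.random.default_rng(11)
        lams = []
        params = dict(alpha_minus=np.log(0.5), alpha_plus=np.log(0.5))
        for _ in range(300):
            g = rng.binomial(2, 0.3, 400).astype(float)
            y = ms.gen_phenotypes_trichotomous(g, "null", params, rng=rng)
            if np.bincount(y, minlength=3).min() == 0:
                continue
            fits = {m: ms.fit_model(g, y, m) for m in ("null", "general")}
            lam, df, _ = ms.lrt(fits["general"], fits["null"])
            assert df == 2
            lams.append(lam)
        assert np.mean(lams) == pytest.approx(2.0, abs=0.35)


class TestSidak:
    @pytest.mark.parametrize("p,m,expected", [
        (0.001, 46, 0.0450), (0.2, 1, 0.2), (1.0, 7, 1.0), (0.0, 46, 0.0)])
    def test_values(self, p, m, expected):
        assert ms.sidak(p, m) == pytest.approx(expected, abs=5e-5)

    def test_monotone_in_m(self):
        assert ms.sidak(0.01, 46) >= ms.sidak(0.01, 2) >= 0.01


class TestPreconditions:
    def test_missing_class_rejected(self):
        g = np.array([0.0, 1, 2, 1])
        with pytest.raises(ms.ValidationError):
            ms.fit_model(g, np.array([0, 0, 1, 1]), "basic")

    def test_constant_genotype_rejected(self):
        g = np.ones(9)
        y = np.tile([0, 1, 2], 3)
        with pytest.raises(ms.ValidationError):
            ms.fit_model(g, y, "general")
        assert ms.fit_model(g, y, "null").converged


def test_parameter_recovery_all_models():
    """Estimates on large generated samples are within 0.05 of truth."""
    truths = {
        "basic": dict(alpha_minus=np.log(0.45), alpha_plus=np.log(0.35),
                      beta_minus=0.3, beta_plus=0.3),
        "subset": dict(alpha_minus=np.log(0.45), alpha_plus=np.log(0.35),
                       beta_minus=0.0, beta_plus=np.log(1.8)),
        "inverse_subset": dict(alpha_minus=np.log(0.45), alpha_plus=np.log(0.35),
                               beta_minus=np.log(1.6), beta_plus=0.0),
        "general": dict(alpha_minus=np.log(0.45), alpha_plus=np.log(0.35),
                        beta_minus=0.2, beta_plus=0.5),
        "modifier": dict(a=-0.6, c=-0.4, gamma=np.log(1.5)),
    }
    rng = np.random.default_rng(5)
    for model, params in truths.items():
        g = rng.binomial(2, 0.3, 50000).astype(float)
        y = ms.gen_phenotypes_trichotomous(g, model, params, rng=rng)
        fit = ms.fit_model(g, y, model)
        for name, truth in params.items():
            assert fit.estimates[name] == pytest.approx(truth, abs=0.05), \
                f"{model}.{name}"
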