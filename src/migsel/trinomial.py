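"""Trinomial likelihood models for symptom-selective genetic association.

For one symptom, a case-control sample is split into three groups:
``0`` = controls (no migraine), ``1`` = cases without the symptom, ``2`` =
cases with the symptom.  Six competing models describe how genotype dose
``g`` (0-2 copies of the effect allele) relates to the two case-vs-control
contrasts, via the multinomial logit

    eta1 = alpha_minus + beta_minus * g     (case without symptom vs control)
    eta2 = alpha_plus  + beta_plus  * g     (case with symptom vs control)
    P(control) = 1 / (1 + exp(eta1) + exp(eta2))

=================  =========================================  ==========
model              constraint                                 free params
=================  =========================================  ==========
null               beta_minus = beta_plus = 0                 2
basic              beta_minus = beta_plus (shared)            3
subset             beta_minus = 0                             3
inverse_subset     beta_plus = 0                              3
general            both slopes free                           4
modifier           factorized: P(case) genotype-free,         3
                   P(symptom | case, g) = logistic(c + gamma*g)
=================  =========================================  ==========

Models are compared by BIC (-2*loglik + k*ln(N)); the selected model is
tested against the null by a likelihood-ratio test.  All fitting works on
the sufficient statistics: counts per (dose level, outcome class), which
makes batched refitting over permutations cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "MODELS",
    "MODEL_K",
    "MODEL_LABEL",
    "ModelFit",
    "SelectionResult",
    "trichotomize",
    "fit_model",
    "bic",
    "select_model",
    "lrt",
    "sidak",
]

MODELS = ("null", "basic", "subset", "inverse_subset", "general", "modifier")
#: free-parameter count per model (intercepts included)
MODEL_K = {
    "null": 2,
    "basic": 3,
    "subset": 3,
    "inverse_subset": 3,
    "general": 4,
    "modifier": 3,
}
#: report labels, matching the field's shorthand
MODEL_LABEL = {
    "null": "-",
    "basic": "basic",
    "subset": "sub",
    "inverse_subset": "i.sub",
    "general": "gen",
    "modifier": "mod",
}
#: fixed tie-break order after parameter count
MODEL_ORDER = {m: i for i, m in enumerate(
    ("null", "basic", "subset", "inverse_subset", "modifier", "general"))}

# Constraint maps theta = A @ phi with theta ordered
# (alpha_minus, alpha_plus, beta_minus, beta_plus).
_A = {
    "null": np.array([[1.0, 0], [0, 1], [0, 0], [0, 0]]),
    "basic": np.array([[1.0, 0, 0], [0, 1, 0], [0, 0, 1], [0, 0, 1]]),
    "subset": np.array([[1.0, 0, 0], [0, 1, 0], [0, 0, 0], [0, 0, 1]]),
    "inverse_subset": np.array([[1.0, 0, 0], [0, 1, 0], [0, 0, 1], [0, 0, 0]]),
    "general": np.eye(4),
}

_GRAD_TOL = 1e-8
_MAX_ITER = 100
_SEPARATION_BOUND = 30.0


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition."""


@dataclass
class ModelFit:
    """A maximum-likelihood fit of one association model."""

    model: str
    estimates: dict[str, float]
    loglik: float
    k: int
    n: int
    bic: float
    converged: bool = True
    iterations: int = 0
    separated: bool = False

    def theta(self) -> np.ndarray:
        """Return (alpha_minus, alpha_plus, beta_minus, beta_plus) when defined."""
        e = self.estimates
        return np.array([e.get("alpha_minus", np.nan), e.get("alpha_plus", np.nan),
                         e.get("beta_minus", 0.0), e.get("beta_plus", 0.0)])


@dataclass
class SelectionResult:
    """BIC selection plus LRT significance for one SNP x symptom x sample."""

    snp_id: str
    symptom: str
    sample_level: str
    chosen: str
    delta_bic_runner_up: float
    delta_bic_basic: float
    lrt_stat: float
    lrt_df: int
    p_asym: float
    p_perm: float | None = None
    p_sidak: float | None = None
    fits: dict[str, ModelFit] = field(default_factory=dict, repr=False)


# ---------------------------------------------------------------------------
# outcome construction

def trichotomize(case_flags, symptom_flags, control_flags) -> np.ndarray:
    """Build the three-group outcome vector from disjoint membership flags.

    Parameters are boolean arrays over the analysis sample: ``case_flags``
    marks active cases, ``symptom_flags`` marks cases reporting the symptom
    (must be a subset of cases), ``control_flags`` marks non-migraineur
    controls.  Every participant must be exactly one of case or control.
    """
    case_flags = np.asarray(case_flags, bool)
    symptom_flags = np.asarray(symptom_flags, bool)
    control_flags = np.asarray(control_flags, bool)
    if np.any(case_flags & control_flags):
        raise ValidationError("case and control flags overlap")
    if not np.all(case_flags | control_flags):
        raise ValidationError("some participants are neither case nor control")
    if np.any(symptom_flags & ~case_flags):
        raise ValidationError("symptom flags set outside the case set")
    y = np.zeros(case_flags.shape, dtype=np.int8)
    y[case_flags] = 1
    y[case_flags & symptom_flags] = 2
    counts = np.bincount(y, minlength=3)
    if counts.min() == 0:
        raise ValidationError(
            f"degenerate stratum: group sizes {tuple(counts)} must all be positive")
    return y


def dose_counts(g: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse (dose, outcome) pairs to levels and a D x 3 count table."""
    g = np.asarray(g, float)
    y = np.asarray(y)
    if g.shape != y.shape:
        raise ValidationError("genotype and outcome vectors differ in length")
    levels, codes = np.unique(g, return_inverse=True)
    counts = np.bincount(codes * 3 + y, minlength=levels.size * 3)
    return levels, counts.reshape(levels.size, 3).astype(float)


# ---------------------------------------------------------------------------
# likelihood / gradient / Hessian on count tables (batched)

def _lgh(theta, g, counts):
    """Loglik, gradient, Hessian of the trinomial logit at theta.

    theta: (..., 4) ordered (a1, a2, b1, b2); g: (D,); counts: (..., D, 3).
    """
    a1, a2, b1, b2 = (theta[..., i, None] for i in range(4))
    eta1 = a1 + b1 * g
    eta2 = a2 + b2 * g
    denom = np.logaddexp(0.0, np.logaddexp(eta1, eta2))
    p1 = np.exp(eta1 - denom)
    p2 = np.exp(eta2 - denom)
    n1 = counts[..., 1]
    n2 = counts[..., 2]
    nd = counts.sum(-1)
    ll = (n1 * eta1 + n2 * eta2 - nd * denom).sum(-1)
    r1 = n1 - nd * p1
    r2 = n2 - nd * p2
    grad = np.stack([r1.sum(-1), r2.sum(-1),
                     (g * r1).sum(-1), (g * r2).sum(-1)], axis=-1)
    # Hessian blocks: -sum_d nd * w_cc' * u u^T with w = diag(p) - p p^T
    w11 = nd * p1 * (1 - p1)
    w22 = nd * p2 * (1 - p2)
    w12 = -nd * p1 * p2
    s = lambda w, pw: (w * pw).sum(-1)  # noqa: E731
    g2 = g * g
    H = np.empty(theta.shape[:-1] + (4, 4))
    H[..., 0, 0] = s(w11, 1.0)
    H[..., 1, 1] = s(w22, 1.0)
    H[..., 0, 1] = H[..., 1, 0] = s(w12, 1.0)
    H[..., 0, 2] = H[..., 2, 0] = s(w11, g)
    H[..., 1, 3] = H[..., 3, 1] = s(w22, g)
    H[..., 0, 3] = H[..., 3, 0] = s(w12, g)
    H[..., 1, 2] = H[..., 2, 1] = s(w12, g)
    H[..., 2, 2] = s(w11, g2)
    H[..., 3, 3] = s(w22, g2)
    H[..., 2, 3] = H[..., 3, 2] = s(w12, g2)
    return ll, grad, -H


def _null_closed_form(counts):
    """Genotype-free multinomial MLE; counts (..., D, 3)."""
    tot = counts.sum(-2)
    n = tot.sum(-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = tot / n
        ll = np.where(tot > 0, tot * np.log(np.where(tot > 0, p, 1.0)), 0.0).sum(-1)
    a1 = np.log(tot[..., 1] / tot[..., 0])
    a2 = np.log(tot[..., 2] / tot[..., 0])
    return ll, a1, a2


def _newton_constrained(counts, g, A, phi0, max_iter=_MAX_ITER, tol=_GRAD_TOL):
    """Batched damped Newton ascent of the constrained trinomial loglik.

    counts: (B, D, 3); phi0: (B, k).  Returns (phi, loglik, converged, iters).
    """
    phi = phi0.copy()
    B = phi.shape[0]
    ll = np.full(B, -np.inf)
    converged = np.zeros(B, bool)
    iters = np.zeros(B, int)
    eye = np.eye(A.shape[1])
    # the score scales with the total count, so the tolerance must too
    gtol = tol * np.maximum(1.0, counts.sum((-2, -1)))
    for it in range(max_iter):
        theta = phi @ A.T
        ll, grad4, H4 = _lgh(theta, g, counts)
        gphi = grad4 @ A
        Hphi = np.einsum("ij,bjk,kl->bil", A.T, H4, A)
        gmax = np.abs(gphi).max(-1)
        newly = (~converged) & (gmax < gtol)
        converged |= newly
        if converged.all():
            break
        active = ~converged
        iters[active] += 1
        # solve -H delta = grad (H is negative definite away from separation)
        Ha = -Hphi[active] + 1e-10 * eye
        try:
            delta = np.linalg.solve(Ha, gphi[active][..., None])[..., 0]
        except np.linalg.LinAlgError:
            delta = np.linalg.solve(Ha + 1e-6 * eye, gphi[active][..., None])[..., 0]
        # step halving on the active subset; candidate steps are clipped to
        # the separation bound *before* acceptance so ascent stays monotone
        step = np.ones((delta.shape[0], 1))
        base_ll = ll[active]
        base_phi = phi[active]
        for _ in range(30):
            trial = np.clip(base_phi + step * delta,
                            -_SEPARATION_BOUND, _SEPARATION_BOUND)
            tll = _lgh(trial @ A.T, g, counts[active])[0]
            bad = tll < base_ll - 1e-12
            if not bad.any():
                break
            step[bad] *= 0.5
        phi[active] = trial
    theta = phi @ A.T
    ll = _lgh(theta, g, counts)[0]
    separated = np.abs(phi).max(-1) >= _SEPARATION_BOUND - 1e-9
    return phi, ll, converged, iters, separated


def _init_phi(counts, A):
    """Start at the null MLE mapped into the constrained space."""
    _, a1, a2 = _null_closed_form(counts)
    theta0 = np.zeros(counts.shape[:-2] + (4,))
    theta0[..., 0] = a1
    theta0[..., 1] = a2
    pinv = np.linalg.pinv(A)
    return theta0 @ pinv.T


def _fit_counts_batch(counts, g, model):
    """Fit one model on a batch of count tables; counts (B, D, 3).

    Returns dict of arrays: loglik (B,), theta (B,4) or modifier params,
    converged, separated.
    """
    counts = np.asarray(counts, float)
    if model == "null":
        ll, a1, a2 = _null_closed_form(counts)
        B = counts.shape[0]
        theta = np.zeros((B, 4))
        theta[:, 0] = a1
        theta[:, 1] = a2
        return {"loglik": ll, "theta": theta, "converged": np.ones(B, bool),
                "separated": np.zeros(B, bool), "iterations": np.zeros(B, int)}
    if model == "modifier":
        return _fit_modifier_batch(counts, g)
    A = _A[model]
    phi0 = _init_phi(counts, A)
    phi, ll, conv, iters, sep = _newton_constrained(counts, g, A, phi0)
    return {"loglik": ll, "theta": phi @ A.T, "converged": conv,
            "separated": sep, "iterations": iters}


def _logistic_newton_batch(succ, trials, g, max_iter=_MAX_ITER, tol=_GRAD_TOL):
    """Batched 2-parameter logistic (intercept + dose slope) on level counts."""
    S = succ.sum(-1)
    M = trials.sum(-1)
    c = np.log((S + 0.5) / (M - S + 0.5))
    gam = np.zeros_like(c)
    converged = np.zeros(c.shape, bool)
    iters = np.zeros(c.shape, int)

    def _ll(c, gam):
        eta = c[..., None] + gam[..., None] * g
        return (succ * eta - trials * np.logaddexp(0.0, eta)).sum(-1)

    ll = _ll(c, gam)
    gtol = tol * np.maximum(1.0, M)  # score scales with the trial count
    for _ in range(max_iter):
        eta = c[..., None] + gam[..., None] * g
        p = 1.0 / (1.0 + np.exp(-eta))
        r = succ - trials * p
        g0 = r.sum(-1)
        g1 = (g * r).sum(-1)
        gmax = np.maximum(np.abs(g0), np.abs(g1))
        converged |= gmax < gtol
        if converged.all():
            break
        w = trials * p * (1 - p)
        h00 = w.sum(-1) + 1e-12
        h01 = (w * g).sum(-1)
        h11 = (w * g * g).sum(-1) + 1e-12
        det = h00 * h11 - h01 * h01
        dc = (h11 * g0 - h01 * g1) / det
        dg = (h00 * g1 - h01 * g0) / det
        act = ~converged
        step = np.ones(c.shape)
        for _ in range(30):
            c_t = np.clip(c + step * dc * act,
                          -_SEPARATION_BOUND, _SEPARATION_BOUND)
            g_t = np.clip(gam + step * dg * act,
                          -_SEPARATION_BOUND, _SEPARATION_BOUND)
            tll = _ll(c_t, g_t)
            bad = act & (tll < ll - 1e-12)
            if not bad.any():
                break
            step[bad] *= 0.5
        c, gam, ll = c_t, g_t, tll
        iters += act
    sep = (np.abs(c) >= _SEPARATION_BOUND - 1e-9) | (np.abs(gam) >= _SEPARATION_BOUND - 1e-9)
    return c, gam, _ll(c, gam), converged, sep, iters


def _fit_modifier_batch(counts, g):
    """Factorized case-only model: genotype-free case margin x logistic symptom."""
    n0 = counts[..., 0].sum(-1)
    cases_d = counts[..., 1] + counts[..., 2]
    ncase = cases_d.sum(-1)
    n = n0 + ncase
    ll_margin = ncase * np.log(ncase / n) + n0 * np.log(n0 / n)
    a = np.log(ncase / n0)
    c, gam, ll_sym, conv, sep, iters = _logistic_newton_batch(
        counts[..., 2], cases_d, g)
    B = counts.shape[0]
    theta = np.stack([a, c, gam], axis=-1)
    return {"loglik": ll_margin + ll_sym, "theta": theta, "converged": conv,
            "separated": sep, "iterations": iters}


# ---------------------------------------------------------------------------
# generic C-contrast multinomial logit (used by the latent-class extension)

def _lgh_multinomial(theta, g, counts):
    """Loglik/gradient/Hessian of a C-contrast multinomial logit.

    theta: (..., 2C) ordered [alpha_1..alpha_C, beta_1..beta_C];
    g: (D,); counts: (..., D, C+1) with column 0 the reference class.
    """
    C = counts.shape[-1] - 1
    alpha = theta[..., :C]
    beta = theta[..., C:]
    eta = alpha[..., None, :] + beta[..., None, :] * g[:, None]  # (..., D, C)
    mx = np.maximum(eta.max(-1), 0.0)
    denom = mx + np.log(np.exp(-mx) + np.exp(eta - mx[..., None]).sum(-1))
    p = np.exp(eta - denom[..., None])
    nd = counts.sum(-1)
    ll = ((counts[..., 1:] * eta).sum(-1) - nd * denom).sum(-1)
    r = counts[..., 1:] - nd[..., None] * p  # (..., D, C)
    grad = np.concatenate([r.sum(-2), (g[:, None] * r).sum(-2)], axis=-1)
    ndp = nd[..., None] * p

    def _w(q):
        # sum_d q_d * nd * (diag(p) - p p^T)
        m = (q[:, None] * ndp).sum(-2)
        M = np.einsum("...dc,...dk->...ck", q[:, None] * ndp, p)
        W = -M
        idx = np.arange(C)
        W[..., idx, idx] += m
        return W

    one = np.ones_like(g)
    Waa = _w(one)
    Wab = _w(g)
    Wbb = _w(g * g)
    H = np.empty(theta.shape[:-1] + (2 * C, 2 * C))
    H[..., :C, :C] = -Waa
    H[..., :C, C:] = -Wab
    H[..., C:, :C] = -np.swapaxes(Wab, -1, -2)
    H[..., C:, C:] = -Wbb
    return ll, grad, H


def _newton_multinomial(counts, g, A, max_iter=_MAX_ITER, tol=_GRAD_TOL):
    """Batched damped Newton ascent of the constrained multinomial loglik.

    counts: (B, D, C+1); A maps free params phi to theta (2C,).  Returns
    (loglik, phi, converged, separated).
    """
    counts = np.asarray(counts, float)
    C = counts.shape[-1] - 1
    tot = counts.sum(-2)  # (B, C+1)
    theta0 = np.zeros(counts.shape[:-2] + (2 * C,))
    theta0[..., :C] = np.log(tot[..., 1:] / tot[..., :1])
    phi = theta0 @ np.linalg.pinv(A).T
    B = phi.shape[0]
    converged = np.zeros(B, bool)
    eye = np.eye(A.shape[1])
    ll = np.full(B, -np.inf)
    gtol = tol * np.maximum(1.0, counts.sum((-2, -1)))
    for _ in range(max_iter):
        ll, grad, H = _lgh_multinomial(phi @ A.T, g, counts)
        gphi = grad @ A
        Hphi = np.einsum("ij,bjk,kl->bil", A.T, H, A)
        converged |= np.abs(gphi).max(-1) < gtol
        if converged.all():
            break
        act = ~converged
        delta = np.linalg.solve(-Hphi[act] + 1e-10 * eye, gphi[act][..., None])[..., 0]
        step = np.ones((delta.shape[0], 1))
        base_ll = ll[act]
        base_phi = phi[act]
        for _ in range(30):
            trial = np.clip(base_phi + step * delta,
                            -_SEPARATION_BOUND, _SEPARATION_BOUND)
            tll = _lgh_multinomial(trial @ A.T, g, counts[act])[0]
            bad = tll < base_ll - 1e-12
            if not bad.any():
                break
            step[bad] *= 0.5
        phi[act] = trial
    ll = _lgh_multinomial(phi @ A.T, g, counts)[0]
    separated = np.abs(phi).max(-1) >= _SEPARATION_BOUND - 1e-9
    return ll, phi, converged, separated


# ---------------------------------------------------------------------------
# public single-fit API

def fit_model(g, y, model: str) -> ModelFit:
    """Maximum-likelihood fit of one of the six association models.

    Parameters
    ----------
    g : array-like
        Genotype dose per participant (any values; hard calls 0/1/2 typical).
    y : array-like
        Trichotomous outcome: 0 control, 1 case without symptom, 2 case with.
    model : str
        One of :data:`MODELS`.
    """
    if model not in MODELS:
        raise ValidationError(f"unknown model {model!r}; expected one of {MODELS}")
    g = np.asarray(g, float)
    y = np.asarray(y)
    counts3 = np.bincount(y, minlength=3)
    if counts3.min() == 0:
        raise ValidationError(
            f"each outcome class needs >=1 observation; got {tuple(counts3)}")
    if model != "null" and np.ptp(g) == 0:
        raise ValidationError("genotype is constant; genotype models are undefined")
    levels, counts = dose_counts(g, y)
    res = _fit_counts_batch(counts[None], levels, model)
    theta = res["theta"][0]
    if model == "modifier":
        estimates = {"a": theta[0], "c": theta[1], "gamma": theta[2]}
    else:
        estimates = {"alpha_minus": theta[0], "alpha_plus": theta[1],
                     "beta_minus": theta[2], "beta_plus": theta[3]}
    n = int(counts.sum())
    ll = float(res["loglik"][0])
    k = MODEL_K[model]
    fit = ModelFit(model=model, estimates=estimates, loglik=ll, k=k, n=n,
                   bic=-2.0 * ll + k * np.log(n),
                   converged=bool(res["converged"][0]),
                   iterations=int(res["iterations"][0]),
                   separated=bool(res["separated"][0]))
    return fit


def bic(fit: ModelFit) -> float:
    """Bayesian Information Criterion, -2*loglik + k*ln(N)."""
    return -2.0 * fit.loglik + fit.k * np.log(fit.n)


def select_model(fits) -> tuple[ModelFit, list[ModelFit]]:
    """Choose the minimum-BIC model among converged fits.

    Ties (within 1e-6 BIC) break toward fewer parameters, then the fixed
    order null, basic, subset, inverse_subset, modifier, general.  Returns
    the chosen fit and the full ranking.
    """
    fits = list(fits)
    usable = [f for f in fits if f.converged and not f.separated]
    if not any(f.model == "null" for f in usable):
        raise ValidationError("selection requires a converged null fit")
    if len(usable) < 2:
        warnings.warn("only the null model converged; returning null")
    best_bic = min(f.bic for f in usable)
    tied = [f for f in usable if f.bic <= best_bic + 1e-6]
    chosen = min(tied, key=lambda f: (f.k, MODEL_ORDER[f.model]))
    ranking = sorted(usable, key=lambda f: (f.bic, f.k, MODEL_ORDER[f.model]))
    return chosen, ranking


def lrt(fit_chosen: ModelFit, fit_null: ModelFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of the chosen model against the nested null."""
    if fit_chosen.model == "null":
        return 0.0, 0, 1.0
    lam = 2.0 * (fit_chosen.loglik - fit_null.loglik)
    if lam < -1e-6:
        raise RuntimeError(
            f"negative LRT statistic {lam}: optimizer failed on {fit_chosen.model}")
    lam = max(lam, 0.0)
    df = fit_chosen.k - fit_null.k
    return lam, df, float(stats.chi2.sf(lam, df))


def sidak(p: float, m: int) -> float:
    """Family-wise correction 1 - (1-p)^m for m independent tests."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError("p must lie in [0, 1]")
    if m < 1:
        raise ValidationError("m must be >= 1")
    return float(np.clip(-np.expm1(m * np.log1p(-p)) if p < 1 else 1.0, 0.0, 1.0))


def fit_all_models(g, y, models=MODELS) -> dict[str, ModelFit]:
    """Fit every requested model on one (genotype, outcome) pair."""
    return {m: fit_model(g, y, m) for m in models}


def analyze_snp_symptom(g, y, snp_id="snp", symptom="symptom",
                        sample_level="all_migraineurs") -> SelectionResult:
    """Fit all six models, select by BIC, and test the winner against null."""
    fits = fit_all_models(g, y)
    chosen, ranking = select_model(fits.values())
    lam, df, p = lrt(chosen, fits["null"])
    runner = ranking[1].bic - ranking[0].bic if len(ranking) > 1 else np.nan
    dbb = chosen.bic - fits["basic"].bic if "basic" in fits else np.nan
    return SelectionResult(snp_id=snp_id, symptom=symptom, sample_level=sample_level,
                           chosen=chosen.model, delta_bic_runner_up=float(runner),
                           delta_bic_basic=float(dbb), lrt_stat=lam, lrt_df=df,
                           p_asym=p, fits=fits)
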