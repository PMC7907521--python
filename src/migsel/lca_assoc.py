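"""Selective genetic association with latent class membership.

The six-model framework extends from observed symptoms to fitted latent
classes: for one class c, cases are split into members vs non-members of c
(modal assignment), giving the familiar three-group outcome against the
shared controls — the per-class "subset" analog.  A global test asks
whether the genotype effect differs across classes at all: a multinomial
logit with one contrast per class,

    eta_c = alpha_c + beta_c * g   (class c vs control),

comparing {beta_c free} against {beta_c all equal} by LRT with K - 1
degrees of freedom.  Permutation correction shuffles genotypes and takes
the min p over all classes of all K values actually tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .trinomial import ValidationError, _lgh_multinomial, _newton_multinomial

__all__ = ["ClassSelectivityResult", "class_trichotomize", "global_class_test",
           "class_selectivity_scan"]


@dataclass
class ClassSelectivityResult:
    snp_id: str
    K: int
    class_index: int | str
    chosen: str
    lrt_stat: float
    lrt_df: int
    p_asym: float
    p_perm: float | None = None
    p_sidak: float | None = None
    beta_per_class: np.ndarray | None = None


def class_trichotomize(assignments, class_index: int, case_mask) -> np.ndarray:
    """Three-group outcome from modal class membership.

    ``assignments`` has one class label per case (in case order);
    ``case_mask`` marks cases within the full analysis sample.  Labels:
    0 control, 1 case not in the class, 2 case in the class.  Classes with
    fewer than 10 members are refused (too unstable to test).
    """
    assignments = np.asarray(assignments)
    case_mask = np.asarray(case_mask, bool)
    if assignments.size != case_mask.sum():
        raise ValidationError("assignments do not align with the case set")
    K = int(assignments.max()) + 1
    if not 0 <= class_index < K:
        raise ValidationError(f"class {class_index} out of range for K={K}")
    members = int((assignments == class_index).sum())
    if members < 10:
        raise ValidationError(
            f"class {class_index} has only {members} members (< 10); skipped")
    y = np.zeros(case_mask.size, np.int8)
    y[case_mask] = np.where(assignments == class_index, 2, 1)
    if (y == 1).sum() == 0:
        raise ValidationError("every case falls in the tested class")
    return y


def _class_counts(g, y_multi, n_cat):
    levels, codes = np.unique(np.asarray(g, float), return_inverse=True)
    counts = np.bincount(codes * n_cat + y_multi, minlength=levels.size * n_cat)
    return levels, counts.reshape(levels.size, n_cat).astype(float)


def _fit_class_models(levels, counts):
    """Log-likelihoods of the free-slope and shared-slope multinomial logits."""
    C = counts.shape[1] - 1
    A_free = np.eye(2 * C)
    A_shared = np.zeros((2 * C, C + 1))
    A_shared[:C, :C] = np.eye(C)
    A_shared[C:, C] = 1.0
    ll_free = _newton_multinomial(counts[None], levels, A_free)[0]
    ll_shared = _newton_multinomial(counts[None], levels, A_shared)[0]
    return float(ll_free[0]), float(ll_shared[0])


def global_class_test(g, assignments, case_mask, snp_id: str = "snp",
                      B: int = 0, seed: int = 0) -> ClassSelectivityResult:
    """Test for class-heterogeneous genotype effects (the "general" analog).

    LRT of per-class slopes against a shared slope, df = K - 1.  With
    ``B > 0`` a genotype-permutation p-value is attached.
    """
    g = np.asarray(g, float)
    case_mask = np.asarray(case_mask, bool)
    assignments = np.asarray(assignments)
    K = int(assignments.max()) + 1
    if K == 1:
        return ClassSelectivityResult(snp_id=snp_id, K=1, class_index="global",
                                      chosen="shared", lrt_stat=0.0, lrt_df=0,
                                      p_asym=1.0)
    y_multi = np.zeros(case_mask.size, np.int64)
    y_multi[case_mask] = assignments + 1
    if np.bincount(y_multi, minlength=K + 1).min() == 0:
        raise ValidationError("all classes and the control group must be populated")

    def _stat(gvec):
        levels, counts = _class_counts(gvec, y_multi, K + 1)
        ll_free, ll_shared = _fit_class_models(levels, counts)
        lam = max(2.0 * (ll_free - ll_shared), 0.0)
        return lam

    lam = _stat(g)
    df = K - 1
    p = float(stats.chi2.sf(lam, df))
    res = ClassSelectivityResult(snp_id=snp_id, K=K, class_index="global",
                                 chosen="free_slopes" if lam > 0 else "shared",
                                 lrt_stat=lam, lrt_df=df, p_asym=p)
    if B > 0:
        rng = np.random.default_rng(seed)
        perm = np.array([_stat(rng.permutation(g)) for _ in range(B)])
        res.p_perm = float((1.0 + np.sum(perm >= lam)) / (B + 1.0))
    return res


def class_selectivity_scan(g, assignments, case_mask, snp_id: str = "snp",
                           B: int = 199, seed: int = 0, min_class: int = 10):
    """Per-class subset-analog scan with a joint permutation correction.

    For every class of the fitted solution, trichotomize and run the full
    six-model selection (reusing the symptom machinery); the permutation
    min-p is taken over all tested classes, mirroring the multiplicity of
    probing every class of every solution examined.
    """
    from .permutation import permutation_correct

    assignments = np.asarray(assignments)
    K = int(assignments.max()) + 1
    cols, names = [], []
    for c in range(K):
        try:
            cols.append(class_trichotomize(assignments, c, case_mask))
        except ValidationError as err:
            warnings.warn(str(err))
            continue
        names.append(f"class{c}")
    if not cols:
        raise ValidationError("no testable classes")
    Y = np.column_stack(cols)
    return permutation_correct(g, Y, B=B, seed=seed, snp_id=snp_id, symptoms=names)
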