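"""Covariate-adjusted logistic effect estimates per case subclass.

After model selection flags a selective association, the magnitude of the
per-dose effect is estimated separately for the two case subclasses
(symptom present vs controls; symptom absent vs controls) by
maximum-likelihood logistic regression adjusting for age and ancestry
principal components.  Intervals are Wald (exp(beta +/- 1.96 se)); the
subclass comparison is descriptive only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .trinomial import ValidationError

__all__ = ["EffectEstimate", "adjusted_logistic", "contrast_effects",
           "subclass_effects"]

_Z95 = 1.959963984540054


@dataclass
class EffectEstimate:
    snp_id: str
    contrast: str
    beta: float
    se: float
    or_: float
    ci95: tuple[float, float]
    wald_p: float
    n: int
    separated: bool = False


def adjusted_logistic(g, case_indicator, covariates=None, snp_id: str = "snp",
                      contrast: str = "case_vs_control") -> EffectEstimate:
    """Logistic regression of case status on dose, adjusting for covariates.

    ``covariates`` is an optional (n, p) matrix (e.g. age plus PCs).  With
    no covariates and a binary exposure the estimate equals the closed-form
    2x2 log odds ratio.
    """
    g = np.asarray(g, float)
    y = np.asarray(case_indicator, int)
    if y.min() == y.max():
        raise ValidationError("both outcome classes must be present")
    if np.ptp(g) == 0:
        raise ValidationError("genotype is constant; no contrast to estimate")
    X = g[:, None]
    if covariates is not None:
        cov = np.asarray(covariates, float)
        if cov.ndim == 1:
            cov = cov[:, None]
        X = np.column_stack([X, cov])
    X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("design matrix is rank deficient")
    with np.errstate(all="ignore"):
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    beta = float(res.params[1])
    se = float(res.bse[1])
    separated = (not res.mle_retvals.get("converged", True)) or abs(beta) > 15 or se > 100
    lo, hi = np.exp(beta - _Z95 * se), np.exp(beta + _Z95 * se)
    if separated:
        lo, hi = 0.0, np.inf
    return EffectEstimate(snp_id=snp_id, contrast=contrast, beta=beta, se=se,
                          or_=float(np.exp(beta)), ci95=(float(lo), float(hi)),
                          wald_p=float(res.pvalues[1]), n=int(y.size),
                          separated=separated)


def subclass_effects(g, y_trichotomous, covariates=None, snp_id: str = "snp"):
    """Fit both subclass-vs-control contrasts on the shared control set.

    ``y_trichotomous``: 0 control, 1 case without symptom, 2 case with.
    Returns (estimate_present, estimate_absent).
    """
    g = np.asarray(g, float)
    y = np.asarray(y_trichotomous, int)
    out = []
    for label, contrast in ((2, "symptom_present_vs_control"),
                            (1, "symptom_absent_vs_control")):
        keep = (y == 0) | (y == label)
        cov = None if covariates is None else np.asarray(covariates, float)[keep]
        out.append(adjusted_logistic(g[keep], (y[keep] == label).astype(int),
                                     covariates=cov, snp_id=snp_id,
                                     contrast=contrast))
    return tuple(out)


def contrast_effects(est_present: EffectEstimate, est_absent: EffectEstimate) -> dict:
    """Descriptive comparison of the two subclass effects (no inference)."""
    d = est_present.beta - est_absent.beta
    if abs(est_present.beta) > abs(est_absent.beta):
        larger = "symptom_present"
    elif abs(est_present.beta) < abs(est_absent.beta):
        larger = "symptom_absent"
    else:
        larger = "tie"
    return {"snp_id": est_present.snp_id, "beta_present": est_present.beta,
            "beta_absent": est_absent.beta, "beta_difference": d,
            "larger_effect": larger}
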