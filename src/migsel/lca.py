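"""Latent class analysis of binary symptom indicators via EM.

The model is a finite mixture of independent Bernoulli items: class
prevalences pi_k and item-response probabilities rho_kj, with likelihood

    l = sum_i log sum_k pi_k prod_j rho_kj^{y_ij} (1 - rho_kj)^{1 - y_ij}

Each fit starts from random rho ~ Uniform[0.05, 0.95] and uniform pi and
runs EM to convergence (relative log-likelihood change < 1e-8, at most
5000 iterations); rho is clamped to [1e-6, 1-1e-6].  A sweep fits a range
of K with many restarts, keeps the best log-likelihood per K, counts how
often the best solution recurs across restarts (a stability diagnostic),
and reports min-max scaled BIC curves so sweeps over nested samples can
be compared on one axis.

Parameter count is (K - 1) + K*J; BIC = -2*l + n_params*ln(N).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .trinomial import ValidationError

__all__ = ["LCAModel", "LCASweep", "em_fit", "restart_sweep",
           "solutions_match", "scaled_bic", "modal_assignments"]

_RHO_CLAMP = 1e-6
_DEGENERATE_PI = 1e-8


@dataclass
class LCAModel:
    K: int
    pi: np.ndarray
    rho: np.ndarray
    loglik: float
    n_params: int
    bic: float
    n: int
    seed: int | None
    iterations: int
    converged: bool
    degenerate: bool = False
    loglik_trace: np.ndarray | None = field(default=None, repr=False)


@dataclass
class LCASweep:
    sample_label: str
    stratum: str
    k_values: list[int]
    best: dict[int, LCAModel]
    recurrence: dict[int, int]
    n_degenerate: dict[int, int]

    def bic_curve(self) -> np.ndarray:
        return np.array([self.best[k].bic for k in self.k_values])


def _validate(data, K):
    y = np.asarray(data, float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise ValidationError("data must be an N x J matrix with J >= 2")
    if np.isnan(y).any():
        raise ValidationError("missing entries are not supported")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValidationError("items must be binary 0/1")
    if K < 1:
        raise ValidationError("K must be >= 1")
    J = y.shape[1]
    if K * J + K - 1 >= 2 ** J - 1:
        warnings.warn(f"K={K}, J={J}: parameter count {K*J+K-1} reaches the "
                      f"available degrees of freedom {2**J - 1}; model may be "
                      "unidentified")
    return y


def _log_components(y, pi, rho):
    """(N, K) log pi_k + sum_j log Bernoulli terms, via a single matmul."""
    lr = np.log(rho)
    l1r = np.log1p(-rho)
    return np.log(pi)[None, :] + y @ (lr - l1r).T + l1r.sum(1)[None, :]


def em_fit(data, K: int, seed: int | None = 0, max_iter: int = 5000,
           tol: float = 1e-8, keep_trace: bool = False) -> LCAModel:
    """One EM fit from a random start; the log-likelihood is checked to be
    non-decreasing at every iteration."""
    y = _validate(data, K)
    n, J = y.shape
    rng = np.random.default_rng(seed)
    pi = np.full(K, 1.0 / K)
    rho = rng.uniform(0.05, 0.95, size=(K, J))
    prev_ll = -np.inf
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logc = _log_components(y, pi, rho)
        mx = logc.max(1, keepdims=True)
        resp = np.exp(logc - mx)
        norm = resp.sum(1, keepdims=True)
        ll = float((mx + np.log(norm)).sum())
        if ll < prev_ll - 1e-8 * max(1.0, abs(prev_ll)):
            raise RuntimeError(
                f"EM log-likelihood decreased ({prev_ll} -> {ll}) at iter {it}")
        trace.append(ll)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) < tol * abs(ll):
            converged = True
            break
        prev_ll = ll
        resp /= norm
        wk = resp.sum(0)
        pi = wk / n
        rho = (resp.T @ y) / np.maximum(wk[:, None], 1e-300)
        np.clip(rho, _RHO_CLAMP, 1.0 - _RHO_CLAMP, out=rho)
    degenerate = bool((pi < _DEGENERATE_PI).any())
    pi = pi / pi.sum()
    n_params = (K - 1) + K * J
    return LCAModel(K=K, pi=pi, rho=rho, loglik=ll, n_params=n_params,
                    bic=-2.0 * ll + n_params * np.log(n), n=n, seed=seed,
                    iterations=it, converged=converged, degenerate=degenerate,
                    loglik_trace=np.array(trace) if keep_trace else None)


def solutions_match(model_a: LCAModel, model_b: LCAModel, tol: float = 1e-3) -> bool:
    """Do two fitted solutions agree up to class relabeling?

    Classes are aligned by the assignment minimizing total |rho_a - rho_b|
    row distance; the solutions match when max |rho| and |pi| differences
    are below ``tol`` and log-likelihoods agree to a relative 1e-4.
    """
    if model_a.K != model_b.K or model_a.rho.shape != model_b.rho.shape:
        raise ValidationError("models must share K and J")
    cost = np.abs(model_a.rho[:, None, :] - model_b.rho[None, :, :]).sum(-1)
    ri, ci = linear_sum_assignment(cost)
    rho_diff = np.abs(model_a.rho[ri] - model_b.rho[ci]).max()
    pi_diff = np.abs(model_a.pi[ri] - model_b.pi[ci]).max()
    ll_ok = abs(model_a.loglik - model_b.loglik) < 1e-4 * abs(model_a.loglik)
    return bool(rho_diff < tol and pi_diff < tol and ll_ok)


def restart_sweep(data, k_values=range(2, 16), restarts: int = 50, seed: int = 0,
                  sample_label: str = "sample", stratum: str = "combined",
                  match_tol: float = 1e-3, **em_kwargs) -> LCASweep:
    """Multi-restart EM over a K range; tracks recurrence of the best fit.

    Recurrence at K counts restarts whose solution matches the best one
    (:func:`solutions_match`); near-zero recurrence across K mirrors an
    unstable latent structure.  Degenerate restarts (an emptied class) are
    excluded and counted.
    """
    k_values = list(k_values)
    children = np.random.SeedSequence(seed).spawn(len(k_values))
    best: dict[int, LCAModel] = {}
    recur: dict[int, int] = {}
    ndeg: dict[int, int] = {}
    for k, child in zip(k_values, children):
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in child.spawn(restarts)]
        fits = [em_fit(data, k, seed=s, **em_kwargs) for s in seeds]
        good = [f for f in fits if not f.degenerate]
        ndeg[k] = restarts - len(good)
        if not good:
            warnings.warn(f"all {restarts} restarts degenerate at K={k}; skipped")
            continue
        top = max(good, key=lambda f: f.loglik)
        best[k] = top
        recur[k] = sum(solutions_match(top, f, tol=match_tol) for f in good)
    return LCASweep(sample_label=sample_label, stratum=stratum,
                    k_values=[k for k in k_values if k in best],
                    best=best, recurrence=recur, n_degenerate=ndeg)


def scaled_bic(bics) -> np.ndarray:
    """Min-max scale a BIC curve to [0, 1] (constant curves map to zeros)."""
    b = np.asarray(bics, float)
    if b.size == 0:
        raise ValidationError("empty BIC curve")
    span = b.max() - b.min()
    if span == 0:
        warnings.warn("constant BIC across K; returning zeros")
        return np.zeros_like(b)
    return (b - b.min()) / span


def modal_assignments(model: LCAModel, data) -> np.ndarray:
    """Hard class assignment per row: argmax posterior membership."""
    y = _validate(data, model.K)
    return np.argmax(_log_components(y, model.pi, model.rho), axis=1)
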