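"""Permutation minP correction across symptoms, and Sidak across SNPs.

For one SNP, the observed statistic is the minimum, over symptoms and
over the five genotype-dependent models, of the asymptotic LRT p-value
against the null.  (The null model's own p is identically 1, so including
it would collapse the statistic onto an atom at 1 whenever BIC prefers
null and destroy the resolution of the correction; minimizing over the
alternatives keeps the statistic continuous while still charging for the
model-selection multiplicity.)  Each permutation shuffles the genotype
vector over participants (phenotypes fixed, so the symptom correlation
structure is preserved), recomputes every fit, and records its own
minimum p.  The corrected p-value is the add-one estimator
(1 + #{permuted minP <= observed minP}) / (B + 1), accounting jointly for
the ten-symptom and six-model multiplicity.  An optional strata vector
restricts shuffling to within strata (e.g. coarse ancestry groups) for
confounding robustness.

Refitting is done on sufficient statistics: per-permutation (dose level x
outcome class) count tables, with all five genotype-dependent models fit
by batched Newton across permutations at once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .trinomial import (MODEL_K, ValidationError, _fit_counts_batch,
                        analyze_snp_symptom, sidak)

__all__ = ["PermutationResult", "permutation_correct", "permuted_min_p", "analyze_panel"]

# column order matters: argmin takes the first minimum, which reproduces the
# tie-break "fewer parameters, then fixed order"
_BATCH_MODELS = ("null", "basic", "subset", "inverse_subset", "modifier", "general")


@dataclass
class PermutationResult:
    snp_id: str
    observed_min_p: float
    p_perm: float
    B: int
    per_symptom: dict = field(default_factory=dict)


def _permute_genotypes(g, B, rng, strata=None):
    """(B, N) matrix of independently permuted copies of g."""
    G = np.tile(g, (B, 1))
    if strata is None:
        return rng.permuted(G, axis=1)
    strata = np.asarray(strata)
    for s in np.unique(strata):
        cols = np.flatnonzero(strata == s)
        G[:, cols] = rng.permuted(G[:, cols], axis=1)
    return G


def _batch_tables(gcodes, y, n_levels):
    """Count tables (B, D, 3) for a batch of permuted genotype codes."""
    B, N = gcodes.shape
    key = gcodes * 3 + y[None, :] + (np.arange(B) * 3 * n_levels)[:, None]
    flat = np.bincount(key.ravel(), minlength=B * 3 * n_levels)
    return flat.reshape(B, n_levels, 3).astype(float)


def _batch_min_p(tables, levels, n):
    """Min over the five alternative models of the LRT p against null.

    tables: (B, D, 3).  Non-converged or separated fits contribute p = 1.
    """
    B = tables.shape[0]
    ll_null = _fit_counts_batch(tables, levels, "null")["loglik"]
    pmin = np.ones(B)
    for m in _BATCH_MODELS[1:]:
        res = _fit_counts_batch(tables, levels, m)
        ok = res["converged"] & ~res["separated"]
        lam = np.maximum(2.0 * (res["loglik"] - ll_null), 0.0)
        p = stats.chi2.sf(lam, MODEL_K[m] - 2)
        p[~ok] = 1.0
        pmin = np.minimum(pmin, p)
    return pmin


def min_model_p(fits) -> float:
    """Observed statistic: min LRT p over the five alternative models."""
    from .trinomial import lrt

    null_fit = fits["null"]
    ps = [lrt(f, null_fit)[2] for m, f in fits.items()
          if m != "null" and f.converged and not f.separated]
    return min(ps) if ps else 1.0


def permuted_min_p(g, Y, B, rng, strata=None):
    """Permutation distribution of the min-over-symptoms selected-model p.

    ``Y`` is an (N, S) matrix of trichotomous outcomes sharing controls.
    Returns an array of length B.
    """
    g = np.asarray(g, float)
    Y = np.atleast_2d(np.asarray(Y))
    if Y.shape[0] != g.size:
        Y = Y.T
    levels, gcode_obs = np.unique(g, return_inverse=True)
    G = _permute_genotypes(gcode_obs, B, rng, strata=strata)
    minp = np.full(B, np.inf)
    n = g.size
    for s in range(Y.shape[1]):
        tables = _batch_tables(G, Y[:, s].astype(np.int64), levels.size)
        minp = np.minimum(minp, _batch_min_p(tables, levels, n))
    return minp


def permutation_correct(g, Y, B: int = 999, seed: int = 0, strata=None,
                        snp_id: str = "snp", symptoms=None) -> PermutationResult:
    """Permutation-corrected p-value for one SNP across all symptoms.

    With a constant genotype no genotype model can improve the likelihood
    and the corrected p is 1 by convention.
    """
    if B < 99:
        warnings.warn(f"B={B} gives at best p = {1/(B+1):.3g}; consider B >= 99")
    g = np.asarray(g, float)
    Y = np.atleast_2d(np.asarray(Y))
    if Y.shape[0] == g.size and Y.ndim == 2:
        pass
    elif Y.shape[-1] == g.size:
        Y = Y.T
    else:
        raise ValidationError("outcome matrix does not align with genotype length")
    S = Y.shape[1]
    names = list(symptoms) if symptoms is not None else [f"symptom{j}" for j in range(S)]
    if np.ptp(g) == 0:
        return PermutationResult(snp_id=snp_id, observed_min_p=1.0, p_perm=1.0, B=B)
    per_symptom = {}
    obs_min = np.inf
    for j in range(S):
        sel = analyze_snp_symptom(g, Y[:, j], snp_id=snp_id, symptom=names[j])
        per_symptom[names[j]] = sel
        obs_min = min(obs_min, min_model_p(sel.fits))
    rng = np.random.default_rng(seed)
    minp = permuted_min_p(g, Y, B, rng, strata=strata)
    p_perm = (1.0 + np.sum(minp <= obs_min)) / (B + 1.0)
    return PermutationResult(snp_id=snp_id, observed_min_p=float(obs_min),
                             p_perm=float(p_perm), B=B, per_symptom=per_symptom)


def analyze_panel(G, Y, snp_ids=None, symptoms=None, B: int = 999, seed: int = 0,
                  strata=None, sample_level: str = "all_migraineurs"):
    """Full selective-association analysis of a SNP panel.

    ``G`` is (N, M) dosages, ``Y`` (N, S) trichotomous outcomes.  Runs BIC
    selection + LRT per SNP x symptom, permutation correction per SNP, and
    Sidak correction across the M SNPs.  Returns a list of
    :class:`~migsel.trinomial.SelectionResult` with all p-values filled in.
    """
    G = np.asarray(G, float)
    if G.ndim == 1:
        G = G[:, None]
    M = G.shape[1]
    ids = list(snp_ids) if snp_ids is not None else [f"snp{i+1}" for i in range(M)]
    ss = np.random.SeedSequence(seed).spawn(M)
    results = []
    for i in range(M):
        pr = permutation_correct(G[:, i], Y, B=B,
                                 seed=ss[i].generate_state(1)[0] % (2**31),
                                 strata=strata, snp_id=ids[i], symptoms=symptoms)
        p_sid = sidak(pr.p_perm, M)
        for name, sel in pr.per_symptom.items():
            sel.p_perm = pr.p_perm
            sel.p_sidak = p_sid
            sel.sample_level = sample_level
            results.append(sel)
    return results
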