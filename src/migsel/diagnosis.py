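"""Diagnostic classification of active migraineurs and sample construction.

Active migraineurs are graded against three criteria adapted from the
second International Classification of Headache Disorders (ICHD-2):

* **B** — attack duration of 4-72 hours;
* **C** — at least two of {unilateral pain, pulsating pain, aggravation by
  physical activity, pain inhibiting daily activities};
* **D** — nausea/vomiting, or both photophobia and phonophobia.

``full`` migraine satisfies all three; ``probable`` migraine misses exactly
one; everything else is ``other``.  Aura and the >=6-attacks/year frequency
item are characteristics under study, never diagnostic criteria, and the
attack-count criterion is not evaluable from a dichotomized frequency item
(duration is 100% among full migraineurs while high frequency is not, so
frequency cannot be obligate).

Three nested case samples share one control set (never-migraineurs):
full only, full + probable, and all active migraineurs; prior migraineurs
and participants with missing status are excluded throughout.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .simulate import SYMPTOMS, Cohort
from .trinomial import ValidationError

__all__ = [
    "CLASSES",
    "LEVELS",
    "classify",
    "classify_cohort",
    "build_nested_samples",
    "prevalence_table",
    "symptom_correlation",
]

CLASSES = ("full", "probable", "other", "nonmigraineur",
           "excluded_prior", "excluded_missing")
LEVELS = ("full_only", "full_plus_probable", "all_migraineurs")

_CRIT_C_ITEMS = ("unilateral", "pulsating", "aggravation_physical", "inhibits_daily")


def _criteria(profile: dict) -> tuple[bool, bool, bool]:
    b = profile["duration_4_72h"] == 1
    c = sum(int(profile[i]) for i in _CRIT_C_ITEMS) >= 2
    d = profile["nausea_vomiting"] == 1 or (
        profile["photophobia"] == 1 and profile["phonophobia"] == 1)
    return b, c, d


def classify(profile: dict | None, status: str) -> str:
    """Diagnostic class for one participant.

    ``status`` is ``none`` / ``prior`` / ``active`` / ``missing``; for
    active participants ``profile`` maps each of the ten symptom names to
    0/1 and must be complete.
    """
    if status == "none":
        return "nonmigraineur"
    if status == "prior":
        return "excluded_prior"
    if status == "missing":
        return "excluded_missing"
    if status != "active":
        raise ValidationError(f"unknown migraine status {status!r}")
    if profile is None:
        raise ValidationError("active migraineur with no symptom profile")
    for s in SYMPTOMS:
        v = profile.get(s)
        if v is None or (isinstance(v, float) and np.isnan(v)) or v not in (0, 1):
            raise ValidationError(f"active migraineur with missing/non-binary {s!r}")
    n_fail = sum(not ok for ok in _criteria(profile))
    return ("full", "probable", "other", "other")[n_fail]


def classify_cohort(cohort: Cohort) -> pd.Series:
    """Vectorized :func:`classify` over a cohort; returns a class per row."""
    out = np.empty(cohort.n, object)
    status = cohort.migraine_status
    out[status == "none"] = "nonmigraineur"
    out[status == "prior"] = "excluded_prior"
    out[status == "missing"] = "excluded_missing"
    act = status == "active"
    sym = cohort.symptoms[act]
    if np.isnan(sym).any():
        raise ValidationError("active migraineur rows contain missing symptoms")
    j = {s: i for i, s in enumerate(SYMPTOMS)}
    b = sym[:, j["duration_4_72h"]] == 1
    c = sym[:, [j[i] for i in _CRIT_C_ITEMS]].sum(1) >= 2
    d = (sym[:, j["nausea_vomiting"]] == 1) | (
        (sym[:, j["photophobia"]] == 1) & (sym[:, j["phonophobia"]] == 1))
    n_fail = (~b).astype(int) + (~c).astype(int) + (~d).astype(int)
    lab = np.where(n_fail == 0, "full", np.where(n_fail == 1, "probable", "other"))
    out[act] = lab
    return pd.Series(out, name="diagnostic_class")


def build_nested_samples(classes: pd.Series) -> dict[str, dict[str, np.ndarray]]:
    """Index sets for the three nested case samples and the shared controls.

    Returns ``{level: {"cases": idx, "controls": idx}}``; raises when a
    level has no cases or there are no controls.
    """
    classes = pd.Series(classes)
    controls = np.flatnonzero(classes == "nonmigraineur")
    if controls.size == 0:
        raise ValidationError("no non-migraineur controls in the cohort")
    case_sets = {
        "full_only": ("full",),
        "full_plus_probable": ("full", "probable"),
        "all_migraineurs": ("full", "probable", "other"),
    }
    out = {}
    for level, labels in case_sets.items():
        cases = np.flatnonzero(classes.isin(labels))
        if cases.size == 0:
            raise ValidationError(f"sample {level!r} has no cases")
        out[level] = {"cases": cases, "controls": controls}
    return out


def _round_pct(count: int, n: int) -> float:
    pct = Decimal(100 * count) / Decimal(n)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def prevalence_table(symptoms: np.ndarray | pd.DataFrame,
                     samples: dict[str, dict[str, np.ndarray]]) -> pd.DataFrame:
    """Per-symptom case counts and percentages for each nested sample.

    ``symptoms`` is the (n, 10) item matrix over the whole cohort (NaN for
    non-cases).  Percentages are 100*count/N rounded half-up to one decimal.
    """
    if isinstance(symptoms, pd.DataFrame):
        symptoms = symptoms[list(SYMPTOMS)].to_numpy(float)
    rows = []
    for s_i, s in enumerate(SYMPTOMS):
        row = {"symptom": s}
        for level, idx in samples.items():
            vals = symptoms[idx["cases"], s_i]
            n = idx["cases"].size
            cnt = int(np.nansum(vals))
            row[f"{level}_n"] = cnt
            row[f"{level}_pct"] = _round_pct(cnt, n)
        rows.append(row)
    return pd.DataFrame(rows).set_index("symptom")


def symptom_correlation(symptoms: np.ndarray | pd.DataFrame, case_idx: np.ndarray,
                        drop_obligate: bool = True) -> pd.DataFrame:
    """Pairwise phi (Pearson) correlations of the ten items over a case set.

    Items that are constant in the sample (e.g. the obligate duration item
    among full migraineurs) are dropped when ``drop_obligate`` is set,
    otherwise an error is raised because their correlation is undefined.
    """
    if isinstance(symptoms, pd.DataFrame):
        symptoms = symptoms[list(SYMPTOMS)].to_numpy(float)
    sub = pd.DataFrame(symptoms[case_idx], columns=list(SYMPTOMS))
    if sub.empty:
        raise ValidationError("empty case sample")
    const = [c for c in sub.columns if sub[c].nunique() <= 1]
    if const:
        if not drop_obligate:
            raise ValidationError(
                f"correlation undefined for constant items {const}")
        import logging
        logging.getLogger(__name__).info("dropping constant items: %s", const)
        sub = sub.drop(columns=const)
    return sub.corr()
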