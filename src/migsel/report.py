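"""Report rendering: the model grid per SNP x symptom x nested sample."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .trinomial import MODEL_LABEL, SelectionResult

__all__ = ["model_grid_report", "selection_frame"]


def selection_frame(results: list[SelectionResult]) -> pd.DataFrame:
    """One row per SNP x symptom x sample with all selection statistics."""
    rows = []
    for r in results:
        rows.append({
            "snp_id": r.snp_id, "symptom": r.symptom, "sample_level": r.sample_level,
            "chosen": r.chosen, "label": MODEL_LABEL[r.chosen],
            "delta_bic_runner_up": r.delta_bic_runner_up,
            "delta_bic_basic": r.delta_bic_basic,
            "lrt_stat": r.lrt_stat, "lrt_df": r.lrt_df, "p_asym": r.p_asym,
            "p_perm": r.p_perm, "p_sidak": r.p_sidak,
        })
    return pd.DataFrame(rows)


def model_grid_report(results: list[SelectionResult],
                      alpha: float = 0.05) -> pd.DataFrame:
    """Grid of selected-model labels, starred when the Sidak-corrected
    permutation p-value is <= ``alpha``.

    Rows are (SNP, sample level); columns are symptoms; cells carry the
    shorthand label ('-' null, 'basic', 'sub', 'i.sub', 'gen', 'mod') with
    a trailing '*' for significant selections.
    """
    df = selection_frame(results)

    def cell(row):
        star = ""
        p = row["p_sidak"] if row["p_sidak"] is not None else np.nan
        if np.isfinite(p) and p <= alpha:
            star = "*"
        return row["label"] + star

    df["cell"] = df.apply(cell, axis=1)
    grid = df.pivot_table(index=["snp_id", "sample_level"], columns="symptom",
                          values="cell", aggfunc="first", sort=False)
    return grid
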