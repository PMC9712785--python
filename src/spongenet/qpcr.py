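"""Relative qPCR quantification by the 2^-ddCT method.

For each sample, dCT = CT(gene) - CT(reference gene); the calibrator is the
mean control-group dCT, so ddCT = dCT - mean(control dCT) and the relative
expression is 2^-ddCT.  By this convention the control-group ddCT mean is
exactly 0 and the geometric mean of control-group folds exactly 1.  Group
differences are tested with a two-sided, equal-variance Student's t-test,
on the fold changes by default or on dCT values via ``on``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .records import CtTable

__all__ = ["FoldChangeResult", "delta_delta_ct", "group_compare", "quantify_genes"]


@dataclass(frozen=True)
class FoldChangeResult:
    gene_id: str
    per_sample: pd.DataFrame  # sample_id, group, dct, ddct, fold
    case_mean_fold: float
    case_sd_fold: float
    control_mean_fold: float
    control_sd_fold: float
    t_statistic: float
    p_value: float


def delta_delta_ct(table: CtTable, gene: str) -> pd.DataFrame:
    """Per-sample dCT, ddCT and 2^-ddCT fold changes for one gene.

    Requires at least one control sample (the calibrator is the mean
    control dCT).
    """
    frame = table.frame
    rows = frame[frame["gene_id"] == gene]
    if rows.empty:
        raise KeyError(f"gene {gene!r} not in CtTable")
    reference = rows["reference_gene"].iloc[0]
    ref_ct = frame[frame["gene_id"] == reference].set_index("sample_id")["ct"]
    out = rows.loc[:, ["sample_id", "group"]].copy()
    out["dct"] = rows["ct"].to_numpy() - ref_ct.loc[rows["sample_id"]].to_numpy()
    control_dct = out.loc[out["group"] == "control", "dct"]
    if control_dct.empty:
        raise ValueError(f"gene {gene!r}: no control samples to calibrate against")
    out["ddct"] = out["dct"] - control_dct.mean()
    out["fold"] = 2.0 ** (-out["ddct"])
    return out.reset_index(drop=True)


def group_compare(folds_case, folds_control) -> tuple[float, float]:
    """Two-sided equal-variance Student's t-test between the two groups."""
    case = np.asarray(folds_case, dtype=float)
    control = np.asarray(folds_control, dtype=float)
    if np.ptp(case) == 0 and np.ptp(control) == 0:
        # degenerate zero-variance samples: identical means are the exact null
        return 0.0, 1.0 if case.mean() == control.mean() else 0.0
    t, p = stats.ttest_ind(case, control, equal_var=True)
    return float(t), float(p)


def quantify_genes(table: CtTable, genes=None, on: str = "fold") -> list[FoldChangeResult]:
    """2^-ddCT summaries plus group tests for each gene in the table.

    ``on`` selects the values handed to the t-test: ``"fold"`` (as usually
    plotted) or ``"dct"``.
    """
    if on not in ("fold", "dct"):
        raise ValueError("on must be 'fold' or 'dct'")
    results = []
    for gene in genes if genes is not None else table.genes():
        per_sample = delta_delta_ct(table, gene)
        case = per_sample[per_sample["group"] == "case"]
        control = per_sample[per_sample["group"] == "control"]
        t, p = group_compare(case[on], control[on])
        results.append(
            FoldChangeResult(
                gene_id=gene,
                per_sample=per_sample,
                case_mean_fold=float(case["fold"].mean()),
                case_sd_fold=float(case["fold"].std(ddof=1)) if len(case) > 1 else 0.0,
                control_mean_fold=float(control["fold"].mean()),
                control_sd_fold=float(control["fold"].std(ddof=1)) if len(control) > 1 else 0.0,
                t_statistic=t,
                p_value=p,
            )
        )
    return results
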