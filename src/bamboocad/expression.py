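"""FPKM expression filtering, heatmap preparation and fold-change calls.

Works on gene x sample FPKM tables (pandas DataFrames, genes as the index).
The expression filter keeps genes with at least ``min_fpkm`` in at least
``min_samples`` samples (the "0.05 FPKM in more than six of 26 tissues"
convention, read as >= 7).  Stress responsiveness is a plain fold-change
call: treated/control ratio after a pseudocount, two-fold in either
direction by default, with weakly expressed genes flagged and excluded
from calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

DEFAULT_MIN_FPKM = 0.05
DEFAULT_MIN_SAMPLES = 7
DEFAULT_FOLD_CHANGE = 2.0
DEFAULT_PSEUDOCOUNT = 0.1
DEFAULT_LOW_EXPR = 1.0


def read_expression_tsv(path) -> pd.DataFrame:
    """Read a tab-separated FPKM matrix (genes x samples, header row)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    validate_expression(df)
    return df


def validate_expression(em: pd.DataFrame) -> None:
    if em.index.duplicated().any():
        dups = sorted(em.index[em.index.duplicated()].unique())
        raise ValueError(f"duplicate gene IDs: {dups}")
    if em.columns.duplicated().any():
        raise ValueError("duplicate sample IDs")
    values = em.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("FPKM matrix contains NaN")
    if (values < 0).any():
        raise ValueError("FPKM values must be non-negative")


def expression_filter(
    em: pd.DataFrame,
    min_fpkm: float = DEFAULT_MIN_FPKM,
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> pd.DataFrame:
    """Keep genes with FPKM >= ``min_fpkm`` in >= ``min_samples`` samples.

    Row order is preserved.  An empty result is a warning, not an error.
    """
    if min_samples > em.shape[1]:
        raise ValueError(
            f"min_samples={min_samples} exceeds sample count {em.shape[1]}"
        )
    keep = (em >= min_fpkm).sum(axis=1) >= min_samples
    out = em.loc[keep]
    if out.empty:
        warnings.warn("expression_filter removed every gene", stacklevel=2)
    return out


def heatmap_matrix(em: pd.DataFrame) -> pd.DataFrame:
    """log2(FPKM + 1) transform for heatmap display; zero maps to zero."""
    return np.log2(em + 1.0)


@dataclass(frozen=True)
class FoldChangeRecord:
    gene: str
    condition: str
    timepoint: str
    fc: float
    direction: str  # up | down | unchanged
    control_mean: float
    treated_mean: float
    low_expression: bool


def fold_change(
    control: float,
    treated: float,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    up_threshold: float = DEFAULT_FOLD_CHANGE,
) -> tuple[float, str]:
    """Ratio (treated + eps) / (control + eps) and its direction call.

    ``up`` iff fc >= up_threshold, ``down`` iff fc <= 1/up_threshold.  The
    pseudocount keeps the ratio finite when the control is zero.
    """
    if np.isnan(control) or np.isnan(treated) or control < 0 or treated < 0:
        raise ValueError("FPKM inputs must be non-negative numbers")
    if pseudocount <= 0 and (control == 0 or treated == 0):
        raise ValueError("pseudocount must be > 0 when either value is 0")
    fc = (treated + pseudocount) / (control + pseudocount)
    if fc >= up_threshold:
        direction = "up"
    elif fc <= 1.0 / up_threshold:
        direction = "down"
    else:
        direction = "unchanged"
    return fc, direction


def read_design_tsv(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "condition", "timepoint", "replicate"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    return design


def stress_response_table(
    em: pd.DataFrame,
    design: pd.DataFrame,
    control_condition: str = "control",
    up_threshold: float = DEFAULT_FOLD_CHANGE,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    low_expr: float = DEFAULT_LOW_EXPR,
) -> pd.DataFrame:
    """Fold-change calls per gene x (condition, timepoint) vs matched control.

    Replicates are averaged (arithmetic mean FPKM) before the ratio.  The
    control for a treatment timepoint is the ``control_condition`` at the
    same timepoint.  Genes whose maximum FPKM over all samples is below
    ``low_expr`` are flagged as too weakly expressed and receive no up/down
    call.
    """
    unknown = set(design["sample"]) - set(em.columns)
    if unknown:
        raise ValueError(f"design samples absent from matrix: {sorted(unknown)}")
    group_means: dict[tuple[str, str], pd.Series] = {}
    for (cond, tp), grp in design.groupby(["condition", "timepoint"]):
        group_means[(cond, tp)] = em[grp["sample"].tolist()].mean(axis=1)
    treatments = sorted(
        (c, t) for (c, t) in group_means if c != control_condition
    )
    if not treatments:
        raise ValueError("design contains no treatment groups")
    low = em.max(axis=1) < low_expr
    records: list[FoldChangeRecord] = []
    for cond, tp in treatments:
        if (control_condition, tp) not in group_means:
            raise ValueError(
                f"condition {cond!r} at timepoint {tp!r} has no matched "
                f"{control_condition!r} samples"
            )
        ctrl = group_means[(control_condition, tp)]
        trt = group_means[(cond, tp)]
        for gene in em.index:
            fc, direction = fold_change(
                ctrl[gene], trt[gene], pseudocount, up_threshold
            )
            flagged = bool(low[gene])
            records.append(
                FoldChangeRecord(
                    gene=gene,
                    condition=cond,
                    timepoint=tp,
                    fc=fc,
                    direction="unchanged" if flagged else direction,
                    control_mean=float(ctrl[gene]),
                    treated_mean=float(trt[gene]),
                    low_expression=flagged,
                )
            )
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "condition": r.condition,
                "timepoint": r.timepoint,
                "control_mean": r.control_mean,
                "treated_mean": r.treated_mean,
                "fc": r.fc,
                "direction": r.direction,
                "low_expression": r.low_expression,
            }
            for r in records
        ]
    )
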