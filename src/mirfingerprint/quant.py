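"""Relative quantification of qPCR targets by the 2^-ddCt model.

Chain per cohort: a per-sample reference Ct (arithmetic mean of the selected
reference genes' Cts, equivalent to the geometric mean of their linear
expressions), target dCt = Ct - refCt, ddCt calibrated against the control
group, per-sample fold expression E = 2^-ddCt, and per-target group
summaries (fold change, fold regulation, direction).

Because every non-spike-in assay of a sample shares the same loading shift,
the shift cancels in dCt, so the whole chain is invariant to per-sample
loading differences.  Fold regulation is the sign-symmetric effect report:
FC when FC >= 1, otherwise -1/FC, so values in (-1, 1) cannot occur.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

from .containers import CASE, CONTROL, CtMatrix

__all__ = [
    "RelQuantTable",
    "GroupSummary",
    "reference_ct",
    "delta_ct",
    "delta_delta_ct",
    "fold_change",
    "fold_regulation",
    "direction_of",
    "quantify",
    "summarize_groups",
]

FC_BASES = ("mean-ratio", "median-ratio", "ddct-of-means")
CALIBRATORS = ("control-mean", "control-median")


@dataclass
class RelQuantTable:
    """Long-format per-(sample, target) table: dct, ddct, E = 2^-ddct."""

    table: pd.DataFrame  # columns: sample, target, group, dct, ddct, E
    calibrator: str

    def expression(self, target: str, group: str | None = None) -> pd.Series:
        sub = self.table[self.table["target"] == target]
        if group is not None:
            sub = sub[sub["group"] == group]
        return sub.set_index("sample")["E"]


@dataclass
class GroupSummary:
    """Per-target group medians, fold change, fold regulation and direction."""

    table: pd.DataFrame  # index target; median_control, median_case, FC, FR, direction
    fc_basis: str


def reference_ct(ct: CtMatrix | pd.DataFrame, ref_ids: Sequence[str]) -> pd.Series:
    """Per-sample reference Ct: arithmetic mean of the reference genes' Cts.

    On the linear scale this is the geometric mean of expressions, since
    2^-mean(Ct) = geomean(2^-Ct).  Samples missing any reference Ct are
    excluded with a warning.
    """
    data = ct.ct if isinstance(ct, CtMatrix) else ct
    ref_ids = list(ref_ids)
    if not ref_ids:
        raise ValueError("ref_ids must be non-empty")
    missing = [r for r in ref_ids if r not in data.index]
    if missing:
        raise KeyError(f"reference assay(s) {missing} not in Ct matrix")
    sub = data.loc[ref_ids]
    complete = sub.notna().all(axis=0)
    if not complete.all():
        warnings.warn(
            f"samples excluded for missing reference Ct: {list(sub.columns[~complete])}",
            stacklevel=2,
        )
    out = sub.loc[:, complete].mean(axis=0)
    out.name = "refCt"
    return out


def delta_ct(
    ct: CtMatrix | pd.DataFrame, refct: pd.Series, target: str
) -> pd.Series:
    """dCt_j = Ct(target, j) - refCt_j; samples with missing values are omitted."""
    data = ct.ct if isinstance(ct, CtMatrix) else ct
    if target not in data.index:
        raise KeyError(f"target {target!r} not in Ct matrix")
    dct = (data.loc[target] - refct).dropna()
    dct.name = "dct"
    return dct


def delta_delta_ct(
    dct: pd.Series, groups: pd.Series, calibrator: str = "control-mean"
) -> pd.DataFrame:
    """Calibrate dCt against the control group and exponentiate.

    Returns a table (index sample) with dct, ddct and E = 2^-ddct.  With the
    default control-mean calibrator the geometric mean of control E is 1.
    """
    if calibrator not in CALIBRATORS:
        raise ValueError(f"calibrator must be one of {CALIBRATORS}")
    groups = groups.reindex(dct.index)
    ctrl = dct[groups == CONTROL]
    if ctrl.empty:
        raise ValueError("control group is empty")
    c = float(ctrl.mean() if calibrator == "control-mean" else ctrl.median())
    ddct = dct - c
    return pd.DataFrame(
        {"group": groups, "dct": dct, "ddct": ddct, "E": np.exp2(-ddct)}
    )


def fold_change(
    e_case: pd.Series | np.ndarray,
    e_control: pd.Series | np.ndarray,
    basis: str = "mean-ratio",
) -> float:
    """Group fold change from per-sample fold expressions.

    mean-ratio: mean(E case)/mean(E control); median-ratio: ratio of medians;
    ddct-of-means: 2^(mean log2 E case - mean log2 E control).
    """
    e_case = np.asarray(e_case, dtype=float)
    e_control = np.asarray(e_control, dtype=float)
    if e_case.size == 0 or e_control.size == 0:
        raise ValueError("both groups must be non-empty")
    if basis == "mean-ratio":
        return float(e_case.mean() / e_control.mean())
    if basis == "median-ratio":
        return float(np.median(e_case) / np.median(e_control))
    if basis == "ddct-of-means":
        return float(np.exp2(np.mean(np.log2(e_case)) - np.mean(np.log2(e_control))))
    raise ValueError(f"basis must be one of {FC_BASES}")


def fold_regulation(fc: float) -> float:
    """FC if FC >= 1 else -1/FC (FC = 1 maps to 1, direction 'none')."""
    if fc <= 0:
        raise ValueError("fold change must be > 0")
    return float(fc) if fc >= 1 else float(-1.0 / fc)


def direction_of(fc: float) -> str:
    if fc > 1:
        return "upregulated"
    if fc < 1:
        return "downregulated"
    return "none"


def quantify(
    ct: CtMatrix,
    ref_ids: Sequence[str],
    groups: pd.Series,
    targets: Sequence[str] | None = None,
    calibrator: str = "control-mean",
    exclude_samples: Sequence[str] = (),
) -> RelQuantTable:
    """Run the full dCt -> ddCt -> E chain for every target of a cohort.

    ``groups`` maps sample id to case/control.  Reference assays that also
    appear among the targets are quantified too, with a warning (the panel
    may nominate a target as a housekeeping gene).
    """
    targets = list(targets) if targets is not None else ct.targets
    overlap = sorted(set(targets) & set(ref_ids))
    if overlap:
        warnings.warn(
            f"assays used both as target and reference: {overlap}", stacklevel=2
        )
    data = ct.ct.drop(columns=list(exclude_samples), errors="ignore")
    refct = reference_ct(data, ref_ids)
    frames = []
    for target in targets:
        dct = delta_ct(data, refct, target)
        if dct.empty:
            continue
        tab = delta_delta_ct(dct, groups, calibrator)
        tab = tab.reset_index(names="sample")
        tab.insert(1, "target", target)
        frames.append(tab)
    if not frames:
        raise ValueError("no target could be quantified")
    return RelQuantTable(pd.concat(frames, ignore_index=True), calibrator)


def summarize_groups(quant: RelQuantTable, fc_basis: str = "mean-ratio") -> GroupSummary:
    """Per-target medians of E, fold change, fold regulation and direction."""
    rows = {}
    for target, sub in quant.table.groupby("target", sort=False):
        e_case = sub.loc[sub["group"] == CASE, "E"]
        e_ctrl = sub.loc[sub["group"] == CONTROL, "E"]
        fc = fold_change(e_case, e_ctrl, fc_basis)
        rows[target] = {
            "median_control": float(e_ctrl.median()),
            "median_case": float(e_case.median()),
            "FC": fc,
            "FR": fold_regulation(fc),
            "direction": direction_of(fc),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "target"
    return GroupSummary(table, fc_basis)
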