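"""Sample-level quality control for qPCR Ct data.

Three checks, mirroring standard plasma-miRNA practice:

* **Haemolysis**: red blood cells are rich in miR-451a while miR-23a-3p is
  insensitive to haemolysis, so the Ct difference
  ``H = Ct(miR-23a-3p) - Ct(miR-451a)`` rises when red-cell contents leak
  into plasma.  H > 7.0 cycles flags an increased haemolysis risk.  Because
  both assays sit in the same well plate column, H cancels per-sample
  loading shifts.
* **Spike-ins**: synthetic RNAs added at fixed input should amplify at a
  constant Ct; a sample deviating from the plate median by more than
  ``max_dev`` cycles on any spike-in indicates a failed RT or qPCR reaction.
* **No-template controls**: a sample Ct too close to the NTC Ct for the same
  assay cannot be distinguished from background amplification.

Flagging never excludes a sample by itself; exclusion is an explicit
downstream choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import CtMatrix
from .synthetic import HEMOLYSIS_ASSAY, HEMOLYSIS_STABLE_ASSAY

__all__ = ["HemolysisQC", "SpikeInQC", "hemolysis_stat", "spikein_qc", "negative_control_check", "qc_report"]


@dataclass
class HemolysisQC:
    """Per-sample haemolysis statistic H (cycles) with strict-threshold flags."""

    table: pd.DataFrame  # columns: H, flag, evaluable
    threshold: float

    @property
    def flagged(self) -> list[str]:
        return list(self.table.index[self.table["flag"]])


@dataclass
class SpikeInQC:
    """Per-spike-in deviations from plate median and per-sample flags."""

    deviations: pd.DataFrame  # spike-ins x samples, cycles
    flags: pd.Series
    max_dev: float

    @property
    def flagged(self) -> list[str]:
        return list(self.flags.index[self.flags])


def hemolysis_stat(
    ct: CtMatrix,
    stable_assay: str = HEMOLYSIS_STABLE_ASSAY,
    hemolysis_assay: str = HEMOLYSIS_ASSAY,
    threshold: float = 7.0,
) -> HemolysisQC:
    """H_j = Ct(stable, j) - Ct(haemolysis-sensitive, j); flag if H > threshold.

    Samples with either Ct missing get H = NaN, no flag, and
    ``evaluable = False``.
    """
    for assay in (stable_assay, hemolysis_assay):
        if assay not in ct.ct.index:
            raise KeyError(
                f"assay {assay!r} not in Ct matrix; available: {ct.assays}"
            )
    h = ct.ct.loc[stable_assay] - ct.ct.loc[hemolysis_assay]
    evaluable = h.notna()
    flag = evaluable & (h > threshold)  # strictly greater
    table = pd.DataFrame({"H": h, "flag": flag, "evaluable": evaluable})
    table.index.name = "sample"
    return HemolysisQC(table, threshold)


def spikein_qc(ct: CtMatrix, spike_ids: Sequence[str] | None = None, max_dev: float = 1.5) -> SpikeInQC:
    """Deviation of each spike-in Ct from its plate median; flag |dev| > max_dev."""
    spike_ids = list(spike_ids) if spike_ids is not None else ct.spikeins
    if not spike_ids:
        raise ValueError("no spike-in assays given")
    missing = [a for a in spike_ids if a not in ct.ct.index]
    if missing:
        raise KeyError(f"spike-in assay(s) {missing} not in Ct matrix")
    sub = ct.ct.loc[spike_ids]
    dev = sub.sub(sub.median(axis=1, skipna=True), axis=0)
    flags = (dev.abs() > max_dev).any(axis=0)
    dev.index.name = "assay"
    return SpikeInQC(dev, flags, max_dev)


def negative_control_check(
    ct: CtMatrix, ntc_ids: Sequence[str], min_separation: float = 5.0
) -> pd.Series:
    """Per-assay pass/fail against no-template-control wells.

    ``ntc_ids`` are *sample* (column) ids carrying the no-template controls.
    An assay fails when any real sample amplifies within ``min_separation``
    cycles of an NTC Ct for that assay; a missing NTC Ct (no amplification)
    is the ideal outcome and passes.  An empty NTC list passes vacuously.
    """
    ntc_ids = list(ntc_ids)
    missing = [s for s in ntc_ids if s not in ct.ct.columns]
    if missing:
        raise KeyError(f"NTC sample(s) {missing} not in Ct matrix")
    real = [s for s in ct.ct.columns if s not in set(ntc_ids)]
    passed = pd.Series(True, index=ct.ct.index, name="ntc_pass")
    for assay in ct.ct.index:
        ntc_cts = ct.ct.loc[assay, ntc_ids].dropna()
        if ntc_cts.empty:
            continue
        sample_cts = ct.ct.loc[assay, real].dropna()
        if sample_cts.empty:
            continue
        gap = float(ntc_cts.min() - sample_cts.max())
        passed[assay] = gap >= min_separation
    return passed


def qc_report(
    hemo: HemolysisQC, spike: SpikeInQC | None = None
) -> pd.DataFrame:
    """Combined per-sample QC table: H, hemolysis_flag, spikein_flag, evaluable."""
    out = pd.DataFrame(
        {
            "H": hemo.table["H"],
            "hemolysis_flag": hemo.table["flag"],
            "evaluable": hemo.table["evaluable"],
        }
    )
    out["spikein_flag"] = (
        spike.flags.reindex(out.index).fillna(False) if spike is not None else False
    )
    out.index.name = "sample"
    return out
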