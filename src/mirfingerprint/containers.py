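"""Core data containers shared by every pipeline stage.

Two matrices drive the pipeline: a qPCR cycle-threshold matrix (assays x
samples, missing cells allowed) and an NGS miRNA count matrix (genes x
samples, non-negative integers).  Both are thin validated wrappers around
pandas DataFrames so downstream code can rely on their invariants instead of
re-checking them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: valid assay roles for a Ct matrix; roles partition the assay set
ASSAY_ROLES = ("target", "reference-candidate", "spike-in", "negative-control")

CASE = "case"
CONTROL = "control"


@dataclass
class CtMatrix:
    """qPCR cycle-threshold values, assays (rows) x samples (columns).

    Parameters
    ----------
    ct
        Cycle-threshold values in cycles.  ``NaN`` marks a well that did not
        amplify ("Undetermined").  One cycle corresponds to a two-fold change
        in template abundance, so the Ct scale is a (negated) log2 scale.
    roles
        Maps every assay id to one of :data:`ASSAY_ROLES`.
    """

    ct: pd.DataFrame
    roles: pd.Series

    def __post_init__(self) -> None:
        self.ct = self.ct.astype(float)
        if self.ct.index.has_duplicates:
            raise ValueError("duplicate assay ids in Ct matrix")
        if self.ct.columns.has_duplicates:
            raise ValueError("duplicate sample ids in Ct matrix")
        self.roles = self.roles.reindex(self.ct.index)
        if self.roles.isna().any():
            missing = list(self.roles.index[self.roles.isna()])
            raise ValueError(f"assays without a role: {missing}")
        bad = set(self.roles.unique()) - set(ASSAY_ROLES)
        if bad:
            raise ValueError(f"unknown assay roles {sorted(bad)}; expected {ASSAY_ROLES}")
        values = self.ct.to_numpy()
        if np.any(values[np.isfinite(values)] <= 0):
            raise ValueError("Ct values must be positive where present")

    @property
    def samples(self) -> list[str]:
        return list(self.ct.columns)

    @property
    def assays(self) -> list[str]:
        return list(self.ct.index)

    def assays_with_role(self, role: str) -> list[str]:
        return list(self.roles.index[self.roles == role])

    @property
    def targets(self) -> list[str]:
        return self.assays_with_role("target")

    @property
    def reference_candidates(self) -> list[str]:
        return self.assays_with_role("reference-candidate")

    @property
    def spikeins(self) -> list[str]:
        return self.assays_with_role("spike-in")

    def subset(self, assays) -> "CtMatrix":
        return CtMatrix(self.ct.loc[list(assays)], self.roles.loc[list(assays)])


@dataclass
class CountMatrix:
    """UMI-corrected miRNA read counts, genes (rows) x samples (columns)."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count matrix")
        if self.counts.size == 0:
            raise ValueError("empty count matrix")
        arr = self.counts.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValueError("counts must be finite")
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        self.counts = self.counts.round().astype(np.int64)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def library_sizes(self) -> pd.Series:
        """Per-sample total counts N_j (column sums)."""
        return self.counts.sum(axis=0)


@dataclass
class SampleSheet:
    """Assignment of samples to group (case/control) and cohort."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = {"group", "cohort"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"sample sheet needs columns {sorted(required)}")
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sample ids in sample sheet")
        bad = set(self.table["group"].unique()) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}; expected case/control")
        self.table = self.table.copy()
        self.table["cohort"] = self.table["cohort"].astype(str)

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    @property
    def cohorts(self) -> list[str]:
        # stable order of first appearance
        return list(dict.fromkeys(self.table["cohort"]))

    def groups_for(self, samples) -> pd.Series:
        return self.table.loc[list(samples), "group"]

    def cohort_samples(self, cohort: str) -> list[str]:
        return list(self.table.index[self.table["cohort"] == str(cohort)])

    def cases(self, cohort: str | None = None) -> list[str]:
        return self._by_group(CASE, cohort)

    def controls(self, cohort: str | None = None) -> list[str]:
        return self._by_group(CONTROL, cohort)

    def _by_group(self, group: str, cohort: str | None) -> list[str]:
        mask = self.table["group"] == group
        if cohort is not None:
            mask &= self.table["cohort"] == str(cohort)
        return list(self.table.index[mask])

    @classmethod
    def from_records(cls, records) -> "SampleSheet":
        df = pd.DataFrame(records, columns=["sample", "group", "cohort"])
        return cls(df.set_index("sample"))
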