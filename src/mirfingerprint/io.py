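"""Reading and writing of the pipeline's tabular formats.

All tables are TSV by default (CSV accepted on read, chosen by extension);
rows are assays/genes and columns are samples, the common instrument-export
orientation (an ``orientation`` flag transposes on read).  Blank cells and
"Undetermined" parse as missing.  Every written table can carry the run's
effective configuration as ``# key = value`` header comments for
provenance; readers skip ``#`` lines.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .containers import CtMatrix, CountMatrix, SampleSheet
from .synthetic import CountGroundTruth, GroundTruth

__all__ = [
    "read_ct_table",
    "read_count_matrix",
    "read_sample_sheet",
    "read_table",
    "write_table",
    "write_ground_truth",
    "read_ground_truth",
]

NA_STRINGS = ["Undetermined", "undetermined", "UNDETERMINED", "NA", "NaN", ""]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _check_duplicate_header(path: Path, sep: str) -> None:
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#") and line.strip():
                header = [h.strip() for h in line.rstrip("\n").split(sep)]
                seen: set[str] = set()
                dupes = []
                for h in header[1:]:
                    if h in seen:
                        dupes.append(h)
                    seen.add(h)
                if dupes:
                    raise ValueError(
                        f"{path}: duplicate sample column(s) {sorted(set(dupes))}"
                    )
                return


def read_table(path: str | Path, orientation: str = "rows-are-features") -> pd.DataFrame:
    """Generic matrix read: first column ids, header sample ids, '#' comments."""
    path = Path(path)
    sep = _sep_for(path)
    _check_duplicate_header(path, sep)
    df = pd.read_csv(
        path, sep=sep, comment="#", index_col=0,
        na_values=NA_STRINGS, keep_default_na=True,
    )
    if df.index.has_duplicates:
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"{path}: duplicate row id(s) {dupes}")
    if orientation == "rows-are-samples":
        df = df.T
    elif orientation != "rows-are-features":
        raise ValueError(f"unknown orientation {orientation!r}")
    return df


def _to_numeric(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        try:
            out[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: non-numeric value in column {col!r}: {exc}") from exc
    return pd.DataFrame(out, index=df.index)


def read_ct_table(
    path: str | Path, roles_path: str | Path, orientation: str = "rows-are-features"
) -> CtMatrix:
    """Read a Ct matrix (assays x samples) plus an assay-role map.

    The roles file is a two-column table ``assay<TAB>role``.
    """
    path = Path(path)
    df = _to_numeric(read_table(path, orientation), path)
    roles_df = pd.read_csv(
        Path(roles_path), sep=_sep_for(Path(roles_path)), comment="#", index_col=0
    )
    roles = roles_df.iloc[:, 0].astype(str)
    unknown = set(df.index) - set(roles.index)
    if unknown:
        raise ValueError(f"{path}: assays without a role: {sorted(unknown)}")
    return CtMatrix(df, roles)


def read_count_matrix(
    path: str | Path, orientation: str = "rows-are-features"
) -> CountMatrix:
    """Read a count matrix; integer-valued floats are accepted with a warning."""
    path = Path(path)
    df = _to_numeric(read_table(path, orientation), path)
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values are not allowed in a count matrix")
    arr = df.to_numpy()
    if np.any(arr < 0):
        bad = df.columns[(df < 0).any()].tolist()
        raise ValueError(f"{path}: negative counts in column(s) {bad}")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError(f"{path}: non-integer counts")
    if df.dtypes.apply(lambda t: t.kind == "f").any():
        warnings.warn(f"{path}: integer-valued floats parsed as counts", stacklevel=2)
    return CountMatrix(df.round().astype(np.int64))


def read_sample_sheet(path: str | Path) -> SampleSheet:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), comment="#", index_col=0)
    return SampleSheet(df)


def write_table(
    df: pd.DataFrame, path: str | Path, meta: Mapping[str, object] | None = None,
    index: bool = True,
) -> Path:
    """Write a TSV with optional ``# key = value`` provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key} = {value}\n")
        df.to_csv(fh, sep="\t", index=index)
    return path


def write_ground_truth(truth: GroundTruth | CountGroundTruth, path: str | Path) -> Path:
    """Persist simulation ground truth as a flat YAML document."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(truth, GroundTruth):
        doc = {
            "kind": "qpcr",
            "true_fold_change": {
                f"{assay}|{cohort}": float(fc)
                for (assay, cohort), fc in sorted(truth.true_fold_change.items())
            },
            "hemolysed_samples": sorted(truth.hemolysed_samples),
            "sample_load_shift": {
                s: float(v) for s, v in sorted(truth.sample_load_shift.items())
            },
        }
    else:
        doc = {
            "kind": "counts",
            "de_genes": sorted(truth.de_genes),
            "fold_change": float(truth.fold_change),
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return path


def read_ground_truth(path: str | Path) -> GroundTruth | CountGroundTruth:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc.get("kind") == "counts":
        return CountGroundTruth(
            de_genes=set(doc["de_genes"]), fold_change=float(doc["fold_change"])
        )
    tfc = {}
    for key, fc in doc["true_fold_change"].items():
        assay, cohort = key.rsplit("|", 1)
        tfc[(assay, cohort)] = float(fc)
    return GroundTruth(
        true_fold_change=tfc,
        hemolysed_samples=set(doc["hemolysed_samples"]),
        sample_load_shift={s: float(v) for s, v in doc["sample_load_shift"].items()},
    )
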