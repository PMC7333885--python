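"""Two-cohort replication gate and final fingerprint report.

A target joins the biomarker fingerprint only if it is significant (raw
Mann-Whitney p < alpha) in *every* cohort with the *same* direction of
regulation.  Cross-cohort replication, not multiple-testing correction, is
the error control at this stage: under the null the chance a target passes
two independent cohorts at alpha = 0.05 with a coherent direction is about
alpha^2 / 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .screen import bh_fdr

__all__ = ["FingerprintReport", "replicate_intersection", "render_report"]

REPORT_COLUMNS = [
    "experiment", "target", "significance", "Z",
    "median_control", "median_case", "fold_regulation", "direction",
]


@dataclass
class FingerprintReport:
    """Replicated-fingerprint membership with per-cohort evidence.

    ``members``: one row per (target, cohort) for fingerprint members.
    ``excluded``: per non-member target, the first failing criterion
    ('not-significant', 'replication' or 'direction').
    """

    members: pd.DataFrame
    excluded: pd.DataFrame
    alpha: float
    direction_rule: str = "identical-in-all-cohorts"

    @property
    def member_targets(self) -> list[str]:
        return list(dict.fromkeys(self.members["target"])) if len(self.members) else []


def replicate_intersection(
    results: Mapping[str, pd.DataFrame], alpha: float = 0.05, adjust: bool = False
) -> FingerprintReport:
    """Intersect per-cohort differential results into the fingerprint.

    ``results`` maps cohort id to a per-target table with columns p, FR,
    direction (as produced by :func:`mirfingerprint.stats.test_all`).
    ``adjust=True`` applies Benjamini-Hochberg within each cohort before
    thresholding (sensitivity analysis; the primary analysis uses raw p).
    """
    if len(results) < 2:
        raise ValueError("replication needs >= 2 cohorts")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    cohorts = list(results)
    common = set(results[cohorts[0]].index)
    for c in cohorts[1:]:
        common &= set(results[c].index)
    if not common:
        raise ValueError("cohorts share no common targets")
    common = sorted(common)

    pvals = {}
    for c in cohorts:
        p = results[c].loc[common, "p"]
        pvals[c] = pd.Series(bh_fdr(p.to_numpy()), index=common) if adjust else p

    member_rows, excluded_rows = [], []
    for target in common:
        sig = [pvals[c].loc[target] < alpha for c in cohorts]
        dirs = [results[c].loc[target, "direction"] for c in cohorts]
        if all(sig) and len(set(dirs)) == 1 and dirs[0] != "none":
            for c in cohorts:
                row = results[c].loc[target]
                member_rows.append(
                    {
                        "target": target,
                        "cohort": c,
                        "p": float(pvals[c].loc[target]),
                        "FR": float(row["FR"]),
                        "direction": row["direction"],
                    }
                )
        else:
            if not any(sig):
                reason = "not-significant"
            elif not all(sig):
                reason = "replication"
            else:
                reason = "direction"
            excluded_rows.append({"target": target, "reason": reason})

    members = pd.DataFrame(member_rows, columns=["target", "cohort", "p", "FR", "direction"])
    excluded = pd.DataFrame(excluded_rows, columns=["target", "reason"])
    return FingerprintReport(members=members, excluded=excluded, alpha=alpha)


def _significance_label(p: float) -> str:
    for cut in (0.0001, 0.001, 0.01, 0.05):
        if p < cut:
            return f"p < {cut}"
    return "n.s."


def render_report(
    report: FingerprintReport, diff_results: Mapping[str, pd.DataFrame]
) -> pd.DataFrame:
    """Flat per-(member, cohort) table in the classic qPCR-study layout.

    Columns (fixed order): experiment, target, significance, Z,
    median_control, median_case, fold_regulation, direction.  Rows are
    ordered by member target (first-appearance order), then cohort id.
    """
    rows = []
    for target in report.member_targets:
        for cohort in sorted(diff_results):
            res = diff_results[cohort].loc[target]
            rows.append(
                {
                    "experiment": cohort,
                    "target": target,
                    "significance": _significance_label(float(res["p"])),
                    "Z": round(float(res["Z"]), 2),
                    "median_control": round(float(res["median_control"]), 2),
                    "median_case": round(float(res["median_case"]), 2),
                    "fold_regulation": round(float(res["FR"]), 1),
                    "direction": res["direction"],
                }
            )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
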