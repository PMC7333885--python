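"""Reference-gene (housekeeping) selection for qPCR normalization.

Candidate reference assays are ranked by a NormFinder-style stability value
computed on the Ct (log2) scale, and the number of references to combine is
decided by the geNorm stepwise-inclusion rule on pairwise variation of
successive normalization factors.

Stability value.  After removing per-sample effects (each sample's mean Ct
across candidates), gene i in group g has mean ``mu_ig`` and within-group
standard deviation ``s_ig``.  The intergroup bias is
``d_ig = mu_ig - mean_g(mu_ig)`` and the stability value is

    rho_i = mean_g( |d_ig| + s_ig / sqrt(n_g) )

Lower rho = more stable.  With a single group the bias term vanishes and rho
reduces to the standard error of the gene.  This is a deliberately simplified
estimator that preserves the ranking behaviour of the published model-based
approach (which adds shrinkage of the bias term and bias-corrected variance
components) while remaining transparent and exactly testable.

Pairwise variation.  The normalization factor over the top-n genes is the
per-sample mean of their -Ct values (i.e. the log2 of the geometric mean of
linear expressions).  ``V(n, n+1)`` is the standard deviation across samples
of ``NF_n - NF_{n+1}``; when adding gene n+1 barely changes the factor
(V below the threshold, 0.05 by default), n genes suffice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import CtMatrix

__all__ = [
    "StabilityTable",
    "PairwiseVariationSeries",
    "normfinder_stability",
    "genorm_pairwise_variation",
    "select_reference_genes",
]


@dataclass
class StabilityTable:
    """Per-gene stability values, components and ranks (rank 1 = most stable)."""

    table: pd.DataFrame  # columns: rho, intergroup, intragroup, rank

    @property
    def ranked_ids(self) -> list[str]:
        return list(self.table.sort_values("rank").index)


@dataclass
class PairwiseVariationSeries:
    """V(n, n+1) indexed by n, plus samples dropped for missing Ct values."""

    v: pd.Series
    dropped_samples: list[str]

    def __getitem__(self, n: int) -> float:
        return float(self.v.loc[n])


def normfinder_stability(
    ct: CtMatrix | pd.DataFrame, groups: Sequence[str]
) -> StabilityTable:
    """Rank reference candidates by the stability value rho (lower = better).

    ``ct`` is restricted to candidate assays (a CtMatrix uses its
    reference-candidate rows; a bare DataFrame is used as-is).  ``groups``
    aligns with the samples (columns).  Ties in rho break by gene id.
    """
    if isinstance(ct, CtMatrix):
        data = ct.ct.loc[ct.reference_candidates]
    else:
        data = ct
    if data.shape[0] < 3:
        raise ValueError(
            f"need >= 3 reference candidates, got {data.shape[0]}"
        )
    groups = np.asarray(list(groups))
    if groups.shape[0] != data.shape[1]:
        raise ValueError("groups length must match number of samples")
    labels = list(dict.fromkeys(groups))
    for g in labels:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")

    # step 1: remove per-sample effects (loading shifts)
    centered = data - data.mean(axis=0)

    mu = pd.DataFrame(
        {g: centered.loc[:, groups == g].mean(axis=1) for g in labels}
    )
    sd = pd.DataFrame(
        {g: centered.loc[:, groups == g].std(axis=1, ddof=1) for g in labels}
    )
    n_g = pd.Series({g: int((groups == g).sum()) for g in labels})

    d = mu.sub(mu.mean(axis=1), axis=0)  # intergroup bias per gene/group
    se = sd / np.sqrt(n_g)
    intergroup = d.abs().mean(axis=1)
    intragroup = se.mean(axis=1)
    rho = intergroup + intragroup

    table = pd.DataFrame(
        {"rho": rho, "intergroup": intergroup, "intragroup": intragroup}
    )
    order = table.assign(_gene=table.index.astype(str)).sort_values(
        ["rho", "_gene"], kind="stable"
    )
    table["rank"] = pd.Series(np.arange(1, len(order) + 1), index=order.index)
    table.index.name = "gene"
    return StabilityTable(table)


def genorm_pairwise_variation(
    ct: CtMatrix | pd.DataFrame, ranked_ids: Sequence[str]
) -> PairwiseVariationSeries:
    """V(n, n+1) for n = 2..K-1 over genes taken in stability order.

    Samples missing any Ct among the ranked genes are dropped from every V
    and reported.  Constant per-sample shifts cancel in ``NF_n - NF_{n+1}``.
    """
    data = ct.ct if isinstance(ct, CtMatrix) else ct
    ranked_ids = list(ranked_ids)
    if len(ranked_ids) < 3:
        raise ValueError("need >= 3 ranked genes for a pairwise-variation series")
    sub = data.loc[ranked_ids]
    complete = sub.notna().all(axis=0)
    dropped = list(sub.columns[~complete])
    sub = sub.loc[:, complete]
    if sub.shape[1] < 2:
        raise ValueError("fewer than 2 samples with complete reference Cts")

    neg = -sub.to_numpy()
    v = {}
    for n in range(2, len(ranked_ids)):
        nf_n = neg[:n].mean(axis=0)
        nf_n1 = neg[: n + 1].mean(axis=0)
        v[n] = float(np.std(nf_n - nf_n1, ddof=1))
    series = pd.Series(v, name="V")
    series.index.name = "n"
    return PairwiseVariationSeries(series, dropped)


def select_reference_genes(
    stability: StabilityTable,
    ct: CtMatrix | pd.DataFrame,
    v_threshold: float = 0.05,
    start_n: int = 3,
) -> list[str]:
    """Stepwise inclusion: start with the top ``start_n`` genes, add gene n+1
    while V(n, n+1) >= v_threshold and candidates remain."""
    ranked = stability.ranked_ids
    if len(ranked) < start_n:
        raise ValueError(f"need >= {start_n} candidates, got {len(ranked)}")
    n = start_n
    if len(ranked) == start_n:
        return ranked[:n]
    pv = genorm_pairwise_variation(ct, ranked)
    while n < len(ranked) and pv[n] >= v_threshold:
        n += 1
    return ranked[:n]
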