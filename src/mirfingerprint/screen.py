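"""Stage-1 NGS screening of a miRNA count matrix.

Pipeline: tags-per-million abundance filtering, trimmed-mean-of-M-values
(TMM) between-sample normalization, a common-dispersion negative-binomial
exact test per gene, and Benjamini-Hochberg FDR.  Candidates for qPCR
follow-up are the significant genes unioned with a literature whitelist of
detected genes.

TMM follows the Robinson-Oshlack construction: per sample, gene-wise log
ratios (M) and average log abundances (A) against a reference sample are
double-trimmed (30% on M, 5% on A by default) and the surviving M values are
combined with precision weights from the delta-method binomial variance; the
resulting log2 factors are rescaled so their geometric mean is 1.

The exact test conditions on a gene's total pseudo-count after library
equalization: group sums of n i.i.d. NB(mu, phi) samples are NB with mean
n*mu and dispersion phi/n, and the two-sided p-value sums the probabilities
of all splits of the total no more probable than the observed one (at phi=0
this reduces to the conditional binomial test).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .containers import CASE, CONTROL, CountMatrix

__all__ = [
    "tpm_normalize",
    "filter_by_abundance",
    "tmm_factors",
    "estimate_common_dispersion",
    "nb_exact_test",
    "bh_fdr",
    "select_candidates",
    "run_screen",
]


def tpm_normalize(counts: CountMatrix) -> pd.DataFrame:
    """Scale each sample to tags per million: TPM(i,j) = count(i,j)/N_j * 1e6."""
    libs = counts.library_sizes
    zero = libs.index[libs == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero)}")
    return counts.counts / libs * 1e6


def filter_by_abundance(
    tpm: pd.DataFrame, threshold: float, rule: str = "mean"
) -> list[str]:
    """Gene ids whose abundance reaches ``threshold`` TPM.

    ``rule='mean'`` keeps genes with mean TPM across samples >= threshold
    (the default "call rate" reading); ``rule='all-samples'`` requires every
    sample to reach the threshold.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if rule == "mean":
        keep = tpm.mean(axis=1) >= threshold
    elif rule == "all-samples":
        keep = (tpm >= threshold).all(axis=1)
    else:
        raise ValueError(f"unknown rule {rule!r}; use 'mean' or 'all-samples'")
    return list(tpm.index[keep])


def _choose_reference(frac: pd.DataFrame) -> str:
    # sample whose upper-quartile count fraction is closest to the mean UQ
    uq = frac.quantile(0.75, axis=0)
    return str((uq - uq.mean()).abs().idxmin())


def tmm_factors(
    counts: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref_sample: str | None = None,
) -> pd.Series:
    """Per-sample TMM normalization factors (geometric mean 1).

    The factor multiplies the library size: effective library = N_j * f_j.
    """
    df = counts.counts
    if df.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    libs = counts.library_sizes.astype(float)
    if (libs == 0).any():
        raise ValueError("all-zero sample in count matrix")
    frac = df / libs
    if ref_sample is None:
        ref_sample = _choose_reference(frac)
    if ref_sample not in df.columns:
        raise KeyError(f"reference sample {ref_sample!r} not in matrix")

    yr = df[ref_sample].to_numpy(dtype=float)
    nr = float(libs[ref_sample])
    logf = pd.Series(0.0, index=df.columns)
    for sample in df.columns:
        if sample == ref_sample:
            continue
        yj = df[sample].to_numpy(dtype=float)
        nj = float(libs[sample])
        ok = (yj > 0) & (yr > 0)
        if not ok.any():
            raise ValueError(
                f"sample {sample!r} shares no co-expressed genes with reference"
            )
        pj, pr = yj[ok] / nj, yr[ok] / nr
        m = np.log2(pj / pr)
        a = 0.5 * np.log2(pj * pr)
        # delta-method variance of M; weight = inverse variance
        var = (nj - yj[ok]) / (nj * yj[ok]) + (nr - yr[ok]) / (nr * yr[ok])
        keep = _double_trim_mask(m, a, trim_m, trim_a)
        if not keep.any():
            raise ValueError(f"trimming removed all genes for sample {sample!r}")
        w = np.where(var[keep] > 0, 1.0 / var[keep], 0.0)
        if w.sum() == 0:
            w = np.ones(keep.sum())
        logf[sample] = float(np.sum(w * m[keep]) / np.sum(w))
    logf -= logf.mean()  # geometric mean of factors = 1
    return np.exp2(logf)


def _double_trim_mask(
    m: np.ndarray, a: np.ndarray, trim_m: float, trim_a: float
) -> np.ndarray:
    """Keep genes inside both the M-trim and A-trim windows (rank-based)."""
    n = m.size
    lo_m, lo_a = int(np.floor(n * trim_m)), int(np.floor(n * trim_a))
    rank_m = np.argsort(np.argsort(m, kind="stable"), kind="stable")
    rank_a = np.argsort(np.argsort(a, kind="stable"), kind="stable")
    keep_m = (rank_m >= lo_m) & (rank_m < n - lo_m)
    keep_a = (rank_a >= lo_a) & (rank_a < n - lo_a)
    return keep_m & keep_a


def _equalized_counts(
    counts: CountMatrix, factors: pd.Series | None = None
) -> pd.DataFrame:
    """Rescale each sample to the geometric-mean effective library size."""
    libs = counts.library_sizes.astype(float)
    if (libs == 0).any():
        raise ValueError(f"all-zero sample(s): {list(libs.index[libs == 0])}")
    if factors is not None:
        libs = libs * factors.reindex(libs.index)
    common = float(np.exp(np.mean(np.log(libs))))
    return counts.counts * (common / libs)


def _group_masks(groups: Sequence[str], samples: Sequence[str]) -> dict[str, np.ndarray]:
    groups = list(groups)
    if len(groups) != len(samples):
        raise ValueError("groups length must match number of samples")
    labels = list(dict.fromkeys(groups))
    arr = np.asarray(groups)
    return {g: arr == g for g in labels}


def estimate_common_dispersion(
    counts: CountMatrix, groups: Sequence[str], max_dispersion: float = 20.0
) -> float:
    """Common NB dispersion by conditional maximum likelihood.

    Counts are equalized to a common (geometric-mean) library size, and the
    within-group likelihood conditional on each gene's group total is summed
    over genes and maximized over a single dispersion phi.  The conditional
    likelihood is free of the gene means, so one phi is estimable from many
    genes at small n.
    """
    masks = _group_masks(groups, counts.samples)
    pseudo = np.round(_equalized_counts(counts).to_numpy()).astype(np.int64)
    if pseudo.sum() == 0:
        raise ValueError("all-zero count matrix")

    group_data = []
    for mask in masks.values():
        y = pseudo[:, mask]
        if y.shape[1] >= 2:
            z = y.sum(axis=1)
            group_data.append((y[z > 0], z[z > 0], y.shape[1]))
    if not group_data:
        raise ValueError("need at least one group with >= 2 samples")

    def neg_cll(log_phi: float) -> float:
        r = 1.0 / np.exp(log_phi)
        total = 0.0
        for y, z, n in group_data:
            total += float(
                np.sum(gammaln(y + r)) - y.size * gammaln(r)
                + z.size * gammaln(n * r) - np.sum(gammaln(z + n * r))
            )
        return -total

    res = minimize_scalar(
        neg_cll, bounds=(np.log(1e-6), np.log(max_dispersion)), method="bounded",
        options={"xatol": 1e-8},
    )
    phi = float(np.exp(res.x))
    return 0.0 if phi <= 2e-6 else phi


def _conditional_split_logpmf(total: int, n1: int, n2: int, phi: float) -> np.ndarray:
    """Log-probabilities of group-1 sums s = 0..total conditional on the total."""
    s = np.arange(total + 1)
    n = n1 + n2
    if phi == 0:
        # Poisson group sums -> conditional binomial(total, n1/n)
        logp = (
            gammaln(total + 1) - gammaln(s + 1) - gammaln(total - s + 1)
            + s * np.log(n1 / n) + (total - s) * np.log(n2 / n)
        )
        return logp
    mu = total / n
    r1, r2 = n1 / phi, n2 / phi
    mu1, mu2 = n1 * mu, n2 * mu
    logp = _nb_logpmf(s, r1, mu1) + _nb_logpmf(total - s, r2, mu2)
    return logp - logsumexp(logp)


def _nb_logpmf(x: np.ndarray, r: float, mu: float) -> np.ndarray:
    if mu == 0:
        return np.where(x == 0, 0.0, -np.inf)
    logp_success = np.log(mu / (mu + r))
    logp_fail = np.log(r / (mu + r))
    return gammaln(x + r) - gammaln(r) - gammaln(x + 1) + x * logp_success + r * logp_fail


def nb_exact_test(
    counts: CountMatrix,
    groups: Sequence[str],
    dispersion: float,
    factors: pd.Series | None = None,
    method: str = "small-p",
) -> pd.Series:
    """Two-sided exact-test p-value per gene under NB(common dispersion).

    ``method='small-p'`` (default) sums all splits with probability at most
    the observed split's; ``method='doubling'`` doubles the smaller tail
    (capped at 1).
    """
    masks = _group_masks(groups, counts.samples)
    if len(masks) != 2:
        raise ValueError(f"exact test needs exactly 2 groups, got {len(masks)}")
    if method not in ("small-p", "doubling"):
        raise ValueError(f"unknown method {method!r}")
    (g1, m1), (g2, m2) = masks.items()
    pseudo = _equalized_counts(counts, factors)
    s1 = np.round(pseudo.loc[:, m1].sum(axis=1)).astype(np.int64)
    s2 = np.round(pseudo.loc[:, m2].sum(axis=1)).astype(np.int64)
    n1, n2 = int(m1.sum()), int(m2.sum())

    pvals = np.ones(len(s1))
    for i, (a, b) in enumerate(zip(s1.to_numpy(), s2.to_numpy())):
        total = int(a + b)
        if total == 0:
            continue
        logp = _conditional_split_logpmf(total, n1, n2, dispersion)
        obs = logp[int(a)]
        if method == "small-p":
            tail = logp[logp <= obs + 1e-10]
            pvals[i] = min(1.0, float(np.exp(logsumexp(tail))))
        else:
            lower = float(np.exp(logsumexp(logp[: int(a) + 1])))
            upper = float(np.exp(logsumexp(logp[int(a):])))
            pvals[i] = min(1.0, 2.0 * min(lower, upper))
    return pd.Series(pvals, index=counts.genes, name="p")


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    arr = np.asarray(list(p), dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def select_candidates(
    screen: pd.DataFrame, alpha: float = 0.05, whitelist: Sequence[str] = ()
) -> list[str]:
    """Significant genes (p < alpha, ranked by p) unioned with detected whitelist genes.

    The whitelist models literature-nominated miRNAs: they join the candidate
    list only if detected in the screen.  Ordering is stable: significant
    genes by ascending p (ties by gene id), then remaining whitelist genes in
    given order.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    sig = screen[screen["p"] < alpha].sort_values(["p", "gene"], kind="stable")
    out = list(sig["gene"])
    detected = set(screen["gene"])
    for gene in whitelist:
        if gene in detected and gene not in out:
            out.append(gene)
    return out


def run_screen(
    counts: CountMatrix,
    groups: Sequence[str],
    tpm_threshold: float = 1.0,
    abundance_rule: str = "mean",
    alpha: float = 0.05,
    whitelist: Sequence[str] = (),
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """Full stage-1 screen; returns (per-gene result table, candidate list).

    Columns: gene, mean_tpm, log2fc (case vs control on TMM-normalized
    counts-per-million, prior 0.5), p, q.
    """
    tpm = tpm_normalize(counts)
    keep = filter_by_abundance(tpm, tpm_threshold, abundance_rule)
    if not keep:
        raise ValueError("no genes pass the abundance filter")
    sub = CountMatrix(counts.counts.loc[keep])
    factors = tmm_factors(sub, trim_m=trim_m, trim_a=trim_a)
    phi = estimate_common_dispersion(sub, groups)
    p = nb_exact_test(sub, groups, phi, factors)
    q = bh_fdr(p.to_numpy())

    eff = sub.counts.sum(axis=0).astype(float) * factors
    cpm = sub.counts / eff * 1e6
    masks = _group_masks(groups, sub.samples)
    case_mask = masks.get(CASE)
    ctrl_mask = masks.get(CONTROL)
    if case_mask is None or ctrl_mask is None:
        labels = list(masks)
        case_mask, ctrl_mask = masks[labels[0]], masks[labels[1]]
    log2fc = np.log2(
        (cpm.loc[:, case_mask].mean(axis=1) + 0.5)
        / (cpm.loc[:, ctrl_mask].mean(axis=1) + 0.5)
    )
    result = pd.DataFrame(
        {
            "gene": sub.genes,
            "mean_tpm": tpm.loc[keep].mean(axis=1).to_numpy(),
            "log2fc": log2fc.to_numpy(),
            "p": p.to_numpy(),
            "q": q,
        }
    )
    return result, select_candidates(result, alpha, whitelist)
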