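"""Two-tailed Mann-Whitney U comparison of per-sample fold expressions.

The per-target hypothesis is that case and control 2^-ddCt values come from
the same population.  At the study's sample sizes (10 vs 10) the exact null
distribution of U matters: it is computed here by the standard
dynamic-programming count of rank arrangements and used whenever the data
are tie-free and both groups have at most 25 samples; otherwise the
tie-corrected normal approximation (no continuity correction) applies.

Conventions:

* ``U`` counts case-over-control pairs, ``U = #{(i,j): y_j > x_i} + ties/2``
  with x = control, y = case.
* ``Z`` is signed control-minus-case, i.e. built from the control-favoring
  ``U' = n1*n2 - U``, so an *upregulated* target (cases higher) has a
  *negative* Z.
* exact two-tailed p = ``2 * min(P(U <= u), P(U >= u))`` capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .containers import CASE, CONTROL
from .quant import RelQuantTable, direction_of, fold_change, fold_regulation

__all__ = ["MannWhitneyResult", "mann_whitney_u", "exact_u_pmf", "test_all"]


@dataclass
class MannWhitneyResult:
    u: float
    z: float
    p: float
    method: str  # exact | normal-approx | degenerate


@lru_cache(maxsize=64)
def exact_u_pmf(n1: int, n2: int) -> np.ndarray:
    """Exact null pmf of the Mann-Whitney U statistic (no ties).

    ``pmf[u]`` for u = 0..n1*n2, by the classic recurrence counting the
    number of arrangements of n1 + n2 ranks with a given U (equivalently the
    coefficients of the Gaussian binomial); valid only for tie-free data.
    """
    # f_{m,n}(u) = f_{m-1,n}(u - n) + f_{m,n-1}(u), f_{m,0} = f_{0,n} = [u == 0]
    u_max = n1 * n2
    prev = np.zeros((n2 + 1, u_max + 1))  # m = 0 plane
    prev[:, 0] = 1.0
    for _m in range(1, n1 + 1):
        cur = np.zeros_like(prev)
        cur[0, 0] = 1.0
        for n in range(1, n2 + 1):
            cur[n] = cur[n - 1]
            cur[n, n:] += prev[n, :-n]
        prev = cur
    counts = prev[n2]
    return counts / counts.sum()


def _u_and_ties(x: np.ndarray, y: np.ndarray) -> tuple[float, bool, np.ndarray]:
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    # U for y (case) over x (control): rank-sum formula handles ties as halves
    ry = ranks[len(x):].sum()
    u_case = ry - len(y) * (len(y) + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    return float(u_case), bool((tie_counts > 1).any()), tie_counts


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> MannWhitneyResult:
    """Two-tailed Mann-Whitney U test of control values ``x`` vs case values ``y``.

    ``mode='exact'`` requires tie-free data; ``mode='auto'`` picks exact when
    there are no ties and both n <= 25, the tie-corrected normal
    approximation otherwise.  Completely tied data yield p = 1, Z = 0,
    method 'degenerate'.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown mode {mode!r}")
    n1, n2 = x.size, y.size
    u_case, has_ties, tie_counts = _u_and_ties(x, y)
    u_control = n1 * n2 - u_case

    n = n1 + n2
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return MannWhitneyResult(u=u_case, z=0.0, p=1.0, method="degenerate")
    z = (u_control - n1 * n2 / 2.0) / np.sqrt(sigma2)

    use_exact = mode == "exact" or (mode == "auto" and not has_ties and n1 <= 25 and n2 <= 25)
    if use_exact:
        if has_ties:
            raise ValueError("exact mode is invalid with tied values")
        pmf = exact_u_pmf(n1, n2)
        u_int = int(round(u_case))
        lower = float(pmf[: u_int + 1].sum())
        upper = float(pmf[u_int:].sum())
        p = min(1.0, 2.0 * min(lower, upper))
        method = "exact"
    else:
        p = float(2.0 * norm.sf(abs(z)))
        method = "normal-approx"
    return MannWhitneyResult(u=u_case, z=float(z), p=p, method=method)


def test_all(
    quant: RelQuantTable,
    alpha: float = 0.05,
    fc_basis: str = "mean-ratio",
    mode: str = "auto",
) -> pd.DataFrame:
    """Mann-Whitney test per target on per-sample fold expressions.

    Returns one row per target: n_case, n_control, U, Z, p, method, group
    medians of E, FC, FR, direction and the significance flag at ``alpha``.
    """
    rows = []
    for target, sub in quant.table.groupby("target", sort=False):
        e_ctrl = sub.loc[sub["group"] == CONTROL, "E"].to_numpy()
        e_case = sub.loc[sub["group"] == CASE, "E"].to_numpy()
        res = mann_whitney_u(e_ctrl, e_case, mode=mode)
        fc = fold_change(e_case, e_ctrl, fc_basis)
        rows.append(
            {
                "target": target,
                "n_case": e_case.size,
                "n_control": e_ctrl.size,
                "U": res.u,
                "Z": res.z,
                "p": res.p,
                "method": res.method,
                "median_control": float(np.median(e_ctrl)),
                "median_case": float(np.median(e_case)),
                "FC": fc,
                "FR": fold_regulation(fc),
                "direction": direction_of(fc),
                "significant": res.p < alpha,
            }
        )
    return pd.DataFrame(rows).set_index("target")
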