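"""Outage exposure vs social (SVI) and medical (DME) vulnerability.

Quartile contrasts with Wilcoxon rank-sum tests, bivariate local Moran's I
with conditional-permutation inference and Benjamini–Hochberg FDR control,
and Welch t-tests on the 16 SVI components for high-high cluster counties.

The bivariate local Moran at county *i* relates the vulnerability variable
x at *i* to the spatial lag of the outage variable y among its neighbors:

    I_i = z(x)_i * sum_j w_ij z(y)_j

with z-scores taken over the included (non-island) counties using
population (n-denominator) moments and row-standardized contiguity weights
w.  Inference holds x_i and y_i fixed and permutes y over the other n-1
locations (conditional permutation); the two-sided pseudo p-value is the
absolute-exceedance rank (count{|I_perm| >= |I_obs|} + 1)/(m + 1).
Cluster labels come from the quadrant of (z(x)_i, lag_i); only counties
surviving BH at the chosen alpha are labeled.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

EXACT_RANKSUM_MAX_N = 12


# ---------------------------------------------------------------------------
# quartiles and rank tests


def assign_quartiles(values) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Quartile labels 1–4 and the (q1, q2, q3) cut points.

    Cut points use linear-interpolation quantiles.  Intervals are left-open
    / right-closed above Q1 — [min, q1], (q1, q2], (q2, q3], (q3, max] — so
    a value tied with a cut point goes to the lower quartile.
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size < 4:
        raise ValueError("need at least 4 finite values for quartiles")
    cuts = tuple(np.quantile(finite, [0.25, 0.5, 0.75]))
    labels = quartile_of(arr, cuts)
    return labels, cuts


def quartile_of(values, cuts: tuple[float, float, float]) -> np.ndarray:
    """Quartile labels for values given fixed cut points (ties go down)."""
    arr = np.asarray(values, dtype=float)
    return (1 + np.searchsorted(np.asarray(cuts), arr, side="left")).astype(int)


@dataclass
class RankSumResult:
    statistic: float  # rank sum of group a (midranks)
    p_value: float
    method: str  # "exact" | "normal"


def rank_sum_test(a, b) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test with midranks for ties.

    Exact null by full enumeration of rank assignments when the pooled
    sample has at most 12 observations; otherwise the normal approximation
    with tie correction (continuity-corrected).  The exact two-sided p is
    min(1, 2 * min(P(W <= w), P(W >= w))).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w = float(ranks[: a.size].sum())
    n = pooled.size
    if n <= EXACT_RANKSUM_MAX_N:
        sums = np.array(
            [sum(ranks[list(idx)]) for idx in combinations(range(n), a.size)]
        )
        eps = 1e-9
        p_lo = np.mean(sums <= w + eps)
        p_hi = np.mean(sums >= w - eps)
        p = min(1.0, 2.0 * min(p_lo, p_hi))
        return RankSumResult(w, float(p), "exact")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return RankSumResult(w, float(res.pvalue), "normal")


# ---------------------------------------------------------------------------
# spatial weights


class SpatialWeights:
    """Row-standardized contiguity weights over an ordered set of counties.

    Built from symmetric adjacency lists; islands (no neighbors) are
    recorded and excluded from the weight matrix and from LISA inference.
    """

    def __init__(self, adjacency: dict[str, list[str]]):
        for i, nbrs in adjacency.items():
            for j in nbrs:
                if i not in adjacency.get(j, []):
                    raise ValueError(f"asymmetric adjacency: {i} -> {j}")
        self.islands = sorted(i for i, nbrs in adjacency.items() if not nbrs)
        self.ids = sorted(i for i, nbrs in adjacency.items() if nbrs)
        index = {cid: k for k, cid in enumerate(self.ids)}
        self.neighbors = [
            np.array([index[j] for j in adjacency[i] if j in index], dtype=int)
            for i in self.ids
        ]
        rows, cols, vals = [], [], []
        for k, nbrs in enumerate(self.neighbors):
            if nbrs.size == 0:
                continue
            rows.extend([k] * nbrs.size)
            cols.extend(nbrs.tolist())
            vals.extend([1.0 / nbrs.size] * nbrs.size)
        n = len(self.ids)
        self.matrix = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

    @property
    def n(self) -> int:
        return len(self.ids)

    def lag(self, y: np.ndarray) -> np.ndarray:
        """Row-standardized spatial lag W y."""
        return self.matrix @ np.asarray(y, dtype=float)

    def weights_row(self, k: int) -> np.ndarray:
        nbrs = self.neighbors[k]
        return np.full(nbrs.size, 1.0 / nbrs.size)


def build_spatial_weights(adjacency: dict[str, list[str]]) -> SpatialWeights:
    """Row-standardized weights from symmetric adjacency lists."""
    return SpatialWeights(adjacency)


# ---------------------------------------------------------------------------
# bivariate local Moran


def _standardize(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    sd = v.std()  # population moments: the two-county pair example is exact
    if sd == 0:
        raise ValueError(f"degenerate input: {name} has zero variance")
    return (v - v.mean()) / sd


def global_bivariate_moran(x, y, w: SpatialWeights) -> float:
    """Global bivariate Moran's I: z(x)·(W z(y)) / n (row-standardized w)."""
    zx = _standardize(np.asarray(x, dtype=float), "x")
    zy = _standardize(np.asarray(y, dtype=float), "y")
    return float(zx @ w.lag(zy) / w.n)


def _sample_without_replacement(rng, n_pool: int, k: int, m: int) -> np.ndarray:
    """(m, k) index matrix, each row k distinct draws from range(n_pool).

    Rejection sampling: rows with duplicate draws are redrawn until none
    remain — exact uniform ordered sampling, fast for k << n_pool.
    """
    draw = rng.integers(0, n_pool, size=(m, k))
    if k > 1:
        while True:
            srt = np.sort(draw, axis=1)
            bad = (np.diff(srt, axis=1) == 0).any(axis=1)
            if not bad.any():
                break
            draw[bad] = rng.integers(0, n_pool, size=(int(bad.sum()), k))
    return draw


def bivariate_local_moran(
    x,
    y,
    w: SpatialWeights,
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Bivariate local Moran statistics with conditional-permutation p-values.

    ``x`` (vulnerability) and ``y`` (outage burden) are aligned with
    ``w.ids``.  Returns one row per non-island county: ``local_stat``,
    ``lag`` (standardized lag of y), two-sided ``pseudo_p`` and the
    ``quadrant`` label (high-high / low-low / high-low / low-high from the
    signs of z(x)_i and lag_i).  Fixed seed and permutation count give
    bit-identical p-values.

    The mean of ``local_stat`` equals the global bivariate Moran statistic;
    this identity is asserted on every call.
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    zx = _standardize(np.asarray(x, dtype=float), "x")
    zy = _standardize(np.asarray(y, dtype=float), "y")
    if zx.size != w.n or zy.size != w.n:
        raise ValueError("x and y must be defined on all non-island counties")
    lag = w.lag(zy)
    local = zx * lag

    identity_gap = abs(local.mean() - global_bivariate_moran(x, y, w))
    assert identity_gap < 1e-10, f"local/global Moran identity violated ({identity_gap})"

    rng = np.random.default_rng(seed)
    n = w.n
    pseudo_p = np.empty(n)
    abs_obs = np.abs(local)
    for i in range(n):
        nbrs = w.neighbors[i]
        k = nbrs.size
        wts = w.weights_row(i)
        pool = np.delete(zy, i)
        draw = _sample_without_replacement(rng, n - 1, k, n_permutations)
        perm_lag = pool[draw] @ wts
        perm_stat = zx[i] * perm_lag
        exceed = int((np.abs(perm_stat) >= abs_obs[i] - 1e-14).sum())
        pseudo_p[i] = (exceed + 1) / (n_permutations + 1)

    quadrant = np.where(
        zx > 0,
        np.where(lag > 0, "high-high", "high-low"),
        np.where(lag > 0, "low-high", "low-low"),
    )
    return pd.DataFrame(
        {
            "county_id": w.ids,
            "local_stat": local,
            "lag": lag,
            "pseudo_p": pseudo_p,
            "quadrant": quadrant,
        }
    )


def fdr_classify_clusters(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Benjamini–Hochberg step-up over all tested counties; label survivors.

    Adds ``fdr_significant`` and ``cluster_label`` (the quadrant for
    significant counties, ``not-significant`` otherwise).
    """
    out = results.copy()
    reject, _, _, _ = multipletests(
        out["pseudo_p"].to_numpy(), alpha=alpha, method="fdr_bh"
    )
    out["fdr_significant"] = reject
    out["cluster_label"] = np.where(reject, out["quadrant"], "not-significant")
    return out


# ---------------------------------------------------------------------------
# SVI component contrasts


def compare_svi_components(
    vulnerability: pd.DataFrame,
    high_high_ids: set[str] | list[str],
    components: list[str],
) -> pd.DataFrame:
    """Per-component means of high-high vs all other counties, Welch t-tests.

    Components with a group of fewer than 2 counties get NaN p-values and a
    ``testable=False`` flag.
    """
    hh = vulnerability["county_id"].isin(set(high_high_ids))
    if hh.sum() == 0 or (~hh).sum() == 0:
        raise ValueError("both groups must be nonempty")
    rows = []
    for comp in components:
        va = vulnerability.loc[hh, comp].to_numpy(float)
        vb = vulnerability.loc[~hh, comp].to_numpy(float)
        testable = va.size >= 2 and vb.size >= 2
        if testable:
            t, p = stats.ttest_ind(va, vb, equal_var=False)
        else:
            t, p = np.nan, np.nan
        rows.append(
            {
                "component": comp,
                "mean_high_high": va.mean(),
                "mean_other": vb.mean(),
                "difference": va.mean() - vb.mean(),
                "t_statistic": float(t) if testable else np.nan,
                "p_value": float(p) if testable else np.nan,
                "testable": testable,
            }
        )
    return pd.DataFrame(rows)
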