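"""Locus-category comparisons by resampling.

Categories of loci (introgressing vs non-introgressing, autosomal vs
X-linked) are compared statistic by statistic with a permutation test on
the difference of group medians; bootstrap machinery (BCa intervals,
Spearman rank correlation with a case-resampling bootstrap p) covers the
genome-wide summaries.  Monte-Carlo p-values carry the add-one
correction, so the smallest reportable p at B permutations is 1/(B+1);
exhaustive enumeration replaces sampling automatically when the number
of distinct relabelings is small.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

EXHAUSTIVE_LIMIT = 20_000


@dataclass(frozen=True)
class PermutationResult:
    statistic_name: str
    observed: float          # median(A) - median(B) (or mean difference)
    median_a: float
    median_b: float
    p_value: float
    n_permutations: int      # number of relabelings actually evaluated
    seed: int | None
    exhaustive: bool


@dataclass(frozen=True)
class BcaInterval:
    point: float
    lower: float
    upper: float
    alpha: float
    z0: float
    acceleration: float
    n_boot: int
    seed: int
    degenerate: bool = False


def _group_stat(stat: str) -> Callable[[np.ndarray, int], np.ndarray]:
    if stat == "median":
        return lambda arr, axis: np.median(arr, axis=axis)
    if stat == "mean":
        return lambda arr, axis: np.mean(arr, axis=axis)
    raise ValueError(f"unknown statistic {stat!r}")


def permutation_test_median_diff(
    values_a: Sequence[float],
    values_b: Sequence[float],
    n_perm: int = 10_000,
    seed: int | None = None,
    statistic: str = "median",
    alternative: str = "two-sided",
) -> PermutationResult:
    """Permutation test for a difference in group medians.

    Whole loci are reallocated between the two groups; the test
    statistic is median(A) - median(B) (group means optional).  When the
    number of distinct relabelings C(nA+nB, nA) is at most
    ``EXHAUSTIVE_LIMIT`` every relabeling is enumerated and the p-value
    is exact; otherwise ``n_perm`` random reallocations are drawn and
    p = (1 + #extreme) / (n_perm + 1).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in input")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"bad alternative {alternative!r}")
    func = _group_stat(statistic)
    obs = float(func(a, 0) - func(b, 0))
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size

    def extreme(t: np.ndarray) -> np.ndarray:
        if alternative == "two-sided":
            return np.abs(t) >= abs(obs) - 1e-12
        if alternative == "greater":
            return t >= obs - 1e-12
        return t <= obs + 1e-12

    if math.comb(n, na) <= EXHAUSTIVE_LIMIT:
        diffs = np.empty(math.comb(n, na))
        idx_all = np.arange(n)
        for k, comb_idx in enumerate(combinations(range(n), na)):
            sel = np.zeros(n, dtype=bool)
            sel[list(comb_idx)] = True
            diffs[k] = func(pooled[sel], 0) - func(pooled[~sel], 0)
        p = float(extreme(diffs).mean())
        n_eval = diffs.size
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        # one permuted copy of the pool per draw, groups = first na / rest
        perms = rng.permuted(
            np.broadcast_to(pooled, (n_perm, n)).copy(), axis=1
        )
        diffs = func(perms[:, :na], 1) - func(perms[:, na:], 1)
        p = float((1 + extreme(diffs).sum()) / (n_perm + 1))
        n_eval = n_perm
        exhaustive = False
    return PermutationResult(
        statistic_name=statistic,
        observed=obs,
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        p_value=min(p, 1.0),
        n_permutations=n_eval,
        seed=seed,
        exhaustive=exhaustive,
    )


def bca_interval(
    values: Sequence[float],
    statistic: Callable[[np.ndarray], float] = np.median,
    n_boot: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> BcaInterval:
    """Bias-corrected and accelerated bootstrap interval.

    z0 is the normal quantile of the fraction of bootstrap replicates
    below the point estimate; the acceleration a comes from the jackknife
    skewness.  The adjusted quantiles are
    alpha_k = Phi(z0 + (z0 + z_k) / (1 - a (z0 + z_k))).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 8:
        raise ValueError("need at least 8 values for a BCa interval")
    point = float(statistic(x))
    if np.ptp(x) == 0:
        return BcaInterval(point, point, point, alpha, 0.0, 0.0, n_boot, seed,
                           degenerate=True)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    boots = np.apply_along_axis(statistic, 1, x[idx])
    prop = (boots < point).mean()
    if prop == 0.0 or prop == 1.0:
        # all replicates on one side: fall back to percentile with a flag
        lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
        return BcaInterval(point, float(lo), float(hi), alpha, 0.0, 0.0,
                           n_boot, seed, degenerate=True)
    z0 = float(sps.norm.ppf(prop))
    jack = np.array([
        statistic(np.delete(x, i)) for i in range(x.size)
    ])
    jmean = jack.mean()
    denom = ((jack - jmean) ** 2).sum() ** 1.5
    a = 0.0 if denom == 0 else float(((jmean - jack) ** 3).sum() / (6 * denom))
    zlo, zhi = sps.norm.ppf([alpha / 2, 1 - alpha / 2])
    q = [
        float(sps.norm.cdf(z0 + (z0 + z) / (1 - a * (z0 + z))))
        for z in (zlo, zhi)
    ]
    lo, hi = np.quantile(boots, q)
    return BcaInterval(point, float(lo), float(hi), alpha, z0, a, n_boot, seed)


def spearman_bootstrap(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman rho (mid-ranks for ties) with a case-resampling bootstrap p.

    p = 2 * min(P(rho* <= 0), P(rho* >= 0)) over pair resamples, floored
    at 1/(n_boot+1) and capped at 1.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 5:
        raise ValueError("need paired vectors of length >= 5")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("constant vector: Spearman rho undefined")
    rho = float(sps.spearmanr(xa, ya).statistic)
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for k in range(n_boot):
        idx = rng.integers(0, xa.size, size=xa.size)
        xs, ys = xa[idx], ya[idx]
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            reps[k] = 0.0
            continue
        reps[k] = sps.spearmanr(xs, ys).statistic
    p = 2 * min((reps <= 0).mean(), (reps >= 0).mean())
    p = min(max(p, 1 / (n_boot + 1)), 1.0)
    return rho, float(p)


# Contrast definitions: (name, row filter A, row filter B)
def _contrast_masks(df: pd.DataFrame) -> list[tuple[str, pd.Series, pd.Series]]:
    non = df["class"] == "non_introgressing"
    intro = df["class"] == "introgressing"
    auto = df["linkage"] == "autosomal"
    x = df["linkage"] == "X"
    return [
        ("non_introgressing_vs_introgressing", non, intro),
        ("autosomal_vs_X", auto, x),
        ("autosomal_only_non_vs_introgressing", auto & non, auto & intro),
        ("X_only_non_vs_introgressing", x & non, x & intro),
    ]


def compare_categories(
    stats_table: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
    statistics: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-contrast, per-statistic group medians and permutation p-values.

    The machine-readable analogue of a summary table of category
    comparisons: four contrasts (introgression class overall, linkage
    overall, and the class split within each linkage) crossed with Fst,
    Dxy and the per-species pi and Tajima's D columns present in the
    table.  Loci with NaN for a statistic are dropped from that row;
    contrasts with an empty cell are skipped with a warning.
    """
    df = stats_table
    if statistics is None:
        statistics = ["fst", "dxy"] + [
            c for c in df.columns
            if c.startswith(("pi_", "tajimas_d_"))
        ]
    rows = []
    rng = np.random.default_rng(seed)
    for cname, mask_a, mask_b in _contrast_masks(df):
        for stat in statistics:
            va = df.loc[mask_a, stat].dropna().to_numpy()
            vb = df.loc[mask_b, stat].dropna().to_numpy()
            if va.size == 0 or vb.size == 0:
                warnings.warn(f"contrast {cname}/{stat}: empty cell, skipped")
                continue
            child = int(rng.integers(0, 2**31 - 1))
            res = permutation_test_median_diff(va, vb, n_perm=n_perm, seed=child)
            rows.append({
                "contrast": cname,
                "statistic": stat,
                "median_a": res.median_a,
                "median_b": res.median_b,
                "observed_diff": res.observed,
                "n_a": va.size,
                "n_b": vb.size,
                "p_value": res.p_value,
                "n_permutations": res.n_permutations,
                "exhaustive": res.exhaustive,
            })
    return pd.DataFrame(rows)
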