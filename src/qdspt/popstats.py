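"""Population-level heterogeneity statistics on fitted diffusion coefficients.

The fitted D₅ of a membrane species is not one number but a broad,
typically non-Gaussian distribution; the summaries here follow the robust
conventions of the SPT literature: mean ± s.e.m. alongside the median
absolute deviation (MAD, unscaled) for spread, empirical CDFs for display,
and the distribution-free two-sample Kolmogorov–Smirnov test for pairwise
population comparisons at α = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05
#: Sample-size bound below which the exact permutation p-value is used.
EXACT_N_MAX = 10


@dataclass
class PopulationSummary:
    """Mean ± s.e.m., MAD and bookkeeping for one (species, condition)."""

    species: str
    condition: str
    n_traj: int
    mean_steps: float
    mean_D: float
    sem_D: float
    mad_D: float
    n_negative_D: int = 0
    flags: list[str] = field(default_factory=list)


@dataclass
class PairwiseComparison:
    label_1: str
    label_2: str
    ks_statistic: float
    p_value: float
    significant: bool


def mad(values) -> float:
    """Median absolute deviation, median(|x − median(x)|), unscaled.

    No Gaussian-consistency factor is applied; the raw MAD is the literal
    spread statistic reported for D₅ populations (switch on the 1.4826
    factor yourself if you need a robust σ estimate).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("mad of an empty sample")
    return float(np.median(np.abs(values - np.median(values))))


def empirical_cdf(values):
    """Right-continuous ECDF: returns (sorted unique grid, cumulative fractions).

    ``F(grid[i])`` is the fraction of observations ≤ grid[i]; the function
    is 0 below grid[0] and 1 from grid[-1] on.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("ecdf of an empty sample")
    grid, counts = np.unique(values, return_counts=True)
    return grid, np.cumsum(counts) / values.size


def _ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Sup distance between the two empirical CDFs (tie-safe)."""
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(np.sort(a), grid, side="right") / a.size
    cdf_b = np.searchsorted(np.sort(b), grid, side="right") / b.size
    return float(np.max(np.abs(cdf_a - cdf_b)))


def _ks_exact_permutation(a: np.ndarray, b: np.ndarray, observed: float):
    """Exact permutation p-value: fraction of all C(n+m, n) relabelings of
    the pooled sample whose K-S statistic reaches the observed one."""
    pooled = np.concatenate([a, b])
    n = a.size
    idx = range(pooled.size)
    count = 0
    total = 0
    # tolerance guards against float noise in the ECDF arithmetic
    eps = 1e-12
    for comb in combinations(idx, n):
        total += 1
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(comb)] = True
        stat = _ks_statistic(pooled[mask], pooled[~mask])
        if stat >= observed - eps:
            count += 1
    return count / total


def ks_two_sample(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test.

    Returns (statistic, p-value).  For small samples (both n ≤ 10) the
    p-value is the exact permutation probability by exhaustive enumeration
    of all pooled relabelings; otherwise the asymptotic two-sample formula
    is used.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("K-S test requires non-empty samples")
    stat = _ks_statistic(a, b)
    if a.size <= EXACT_N_MAX and b.size <= EXACT_N_MAX:
        p = _ks_exact_permutation(a, b, stat)
    else:
        p = float(stats.ks_2samp(a, b, method="asymp").pvalue)
    return stat, min(p, 1.0)


def lilliefors_normality(values, n_monte_carlo: int = 2000,
                         seed: int = 0) -> tuple[float, float]:
    """One-sample K-S normality check with estimated mean/σ (Lilliefors).

    The null distribution of the statistic is obtained by Monte Carlo,
    since estimating the parameters invalidates the standard K-S table.
    This is the package's interpretation of a "significantly non-Gaussian"
    call on a D₅ population.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations")

    def ks_norm(sample):
        z = (np.sort(sample) - sample.mean()) / sample.std(ddof=1)
        cdf = stats.norm.cdf(z)
        n = sample.size
        up = np.arange(1, n + 1) / n - cdf
        down = cdf - np.arange(0, n) / n
        return max(up.max(), down.max())

    observed = ks_norm(x)
    rng = np.random.default_rng(seed)
    null = np.array([ks_norm(rng.standard_normal(x.size))
                     for _ in range(n_monte_carlo)])
    p = float((np.sum(null >= observed) + 1) / (n_monte_carlo + 1))
    return float(observed), p


def summarize_population(
    D_values, species: str = "", condition: str = "",
    n_steps=None,
) -> PopulationSummary:
    """Mean ± s.e.m., MAD and counts for one population of fitted D₅.

    ``n_steps`` optionally carries per-trajectory displacement counts for
    the <N> column.  A single-value population reports s.e.m. 0 with a flag.
    """
    D = np.asarray(D_values, dtype=float)
    if D.size == 0:
        raise ValueError("cannot summarise an empty population")
    flags = []
    if D.size == 1:
        sem = 0.0
        flags.append("sem_undefined_single_observation")
    else:
        sem = float(D.std(ddof=1) / np.sqrt(D.size))
    mean_steps = float(np.mean(n_steps)) if n_steps is not None else float("nan")
    return PopulationSummary(
        species=species, condition=condition, n_traj=int(D.size),
        mean_steps=mean_steps, mean_D=float(D.mean()), sem_D=sem,
        mad_D=mad(D), n_negative_D=int((D < 0).sum()), flags=flags,
    )


def compare_conditions(
    populations: dict,
    pairs=None,
    alpha: float = ALPHA,
) -> tuple[list[PairwiseComparison], pd.DataFrame]:
    """Pairwise K-S tests and relative-change table across populations.

    ``populations`` maps a label (e.g. ``("CD59", "untreated")`` or a plain
    string) to an array of fitted D₅ values.  ``pairs`` selects the
    comparisons (default: all unordered pairs).  Returns the comparisons
    and a tidy table with the percent change of mean and MAD from the first
    to the second member of each pair.
    """
    labels = list(populations)
    if len(labels) < 2:
        raise ValueError("need at least two populations")
    if pairs is None:
        pairs = list(combinations(labels, 2))
    comparisons = []
    rows = []
    for la, lb in pairs:
        if la not in populations or lb not in populations:
            import warnings
            warnings.warn(f"skipping pair ({la!r}, {lb!r}): missing member",
                          stacklevel=2)
            continue
        a = np.asarray(populations[la], dtype=float)
        b = np.asarray(populations[lb], dtype=float)
        stat, p = ks_two_sample(a, b)
        comparisons.append(PairwiseComparison(
            label_1=str(la), label_2=str(lb), ks_statistic=stat,
            p_value=p, significant=p < alpha))
        mean_a, mean_b = a.mean(), b.mean()
        mad_a, mad_b = mad(a), mad(b)
        rows.append({
            "label_1": str(la), "label_2": str(lb),
            "ks_statistic": stat, "p_value": p,
            "significant": p < alpha,
            "mean_change_pct": 100.0 * (mean_b - mean_a) / mean_a
            if mean_a != 0 else float("nan"),
            "mad_change_pct": 100.0 * (mad_b - mad_a) / mad_a
            if mad_a != 0 else float("nan"),
        })
    return comparisons, pd.DataFrame(rows)


def split_two_components(values) -> tuple[float, float]:
    """Exact 1-D two-class split minimising within-class variance.

    Scans every split point of the sorted sample and returns the two class
    means — a deterministic way to read the component centres off a
    well-separated bimodal population of fitted D₅ values.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("need at least two values to split")
    csum = np.cumsum(x)
    csum2 = np.cumsum(x * x)
    best = (np.inf, 1)
    for k in range(1, n):
        left_ss = csum2[k - 1] - csum[k - 1] ** 2 / k
        right_n = n - k
        right_sum = csum[-1] - csum[k - 1]
        right_ss = (csum2[-1] - csum2[k - 1]) - right_sum**2 / right_n
        total = left_ss + right_ss
        if total < best[0]:
            best = (total, k)
    k = best[1]
    return float(x[:k].mean()), float(x[k:].mean())
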