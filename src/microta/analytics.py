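"""Lineage-space statistics of simulated (or reconstructed) colonies.

The genealogy of a microcolony is treated as the "space" in which
phenotypic correlations live.  The distance between two coexisting cells
is the time since their most recent common ancestor divided; the mutual
information between that distance and the pairwise phenotype difference
quantifies how strongly lineage structures the phenotype.  Sampling one
random pair per independent simulation keeps the pair samples i.i.d.

All entropy / mutual-information estimators here are plug-in estimators on
binned data, in bits; the intended use is the *relative* comparison across
a parameter scan, not bias-corrected absolute values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .population import LineageTree, arrest_cutoff_per_min

__all__ = [
    "PairSample",
    "MIEstimate",
    "ClusterSizeDistribution",
    "sample_pairs",
    "mutual_information",
    "entropy",
    "ensemble_autocorrelation",
    "arrested_clusters",
    "cluster_size_distribution",
    "mann_whitney_lineage",
    "time_since_mrca",
]

N_BOOTSTRAP = 100  # resamples used for the MI uncertainty estimate


@dataclass
class PairSample:
    """One (lineage distance, phenotype difference) draw."""

    d: float    # minutes since the MRCA divided
    phi: float  # absolute phenotype difference

    def __post_init__(self) -> None:
        if self.d < 0 or self.phi < 0:
            raise ValueError("d and phi must be >= 0")


@dataclass
class MIEstimate:
    """Plug-in mutual information with bootstrap uncertainty (bits)."""

    mi_bits: float
    mean_bits: float
    sd_bits: float
    n_samples: int
    n_bins: int


@dataclass
class ClusterSizeDistribution:
    """Pooled arrested-cluster sizes with an exponential fit a*exp(-b*c)."""

    sizes: np.ndarray              # distinct cluster sizes with count > 0
    counts: np.ndarray             # pooled occurrence counts
    frequencies: np.ndarray        # counts normalized to probabilities
    normalized: np.ndarray         # P(c) / P(1)
    fit_a: Optional[float] = None
    fit_b: Optional[float] = None
    fit_r2: Optional[float] = None

    def fitted(self, c: np.ndarray) -> np.ndarray:
        if self.fit_a is None:
            raise ValueError("no exponential fit available")
        return self.fit_a * np.exp(-self.fit_b * np.asarray(c, dtype=float))

    def tail_excess(self, top_fraction: float = 0.5,
                    min_count: int = 5) -> float:
        """Mean log-frequency residual (observed minus fit) over the largest
        ``top_fraction`` of occupied sizes, restricted to sizes observed at
        least ``min_count`` times (ultra-rare sizes near the whole-colony
        bound carry finite-size noise).  Positive values mean large clusters
        are systematically more likely than the exponential fit predicts.
        NaN when no size qualifies."""
        k = max(1, int(np.ceil(len(self.sizes) * top_fraction)))
        tail = np.arange(len(self.sizes) - k, len(self.sizes))
        tail = tail[self.counts[tail] >= min_count]
        if tail.size == 0:
            return float("nan")
        resid = (np.log(self.frequencies[tail])
                 - np.log(self.fitted(self.sizes[tail])))
        return float(np.mean(resid))


# ---------------------------------------------------------------------------
# lineage distance and pair sampling
# ---------------------------------------------------------------------------

def time_since_mrca(parents: dict, birth_times: dict, i, j,
                    at_time: float) -> float:
    """Time since the MRCA's division for cells ``i`` and ``j``.

    Generic helper over a parent map (root's parent absent or negative) and
    per-cell birth times; the MRCA's division time is the birth time of its
    children on the two paths.
    """
    if i == j:
        return 0.0
    path_i = [i]
    while parents.get(path_i[-1], -1) is not None and parents.get(path_i[-1], -1) >= 0:
        path_i.append(parents[path_i[-1]])
    pos = {n: k for k, n in enumerate(path_i)}
    node, prev = j, None
    while node not in pos:
        prev = node
        node = parents[node]
    if pos[node] == 0 or prev is None:
        raise ValueError(f"{i} and {j} are ancestor and descendant")
    return at_time - birth_times[prev]


def sample_pairs(trees: Sequence[LineageTree],
                 phenotype: str = "growth_rate",
                 rng: Optional[np.random.Generator] = None,
                 ) -> List[PairSample]:
    """Draw one uniformly random unordered extant pair per tree.

    ``phenotype`` is ``growth_rate`` or ``toxin_concentration``; ``phi`` is
    the absolute difference at the final time.  Trees with fewer than two
    extant cells are skipped (with a warning).
    """
    if len(trees) == 0:
        raise ValueError("empty ensemble")
    if phenotype not in ("growth_rate", "toxin_concentration"):
        raise ValueError(f"unknown phenotype {phenotype!r}")
    if rng is None:
        rng = np.random.default_rng()
    samples: List[PairSample] = []
    skipped = 0
    for tree in trees:
        extant = tree.extant_nodes()
        if len(extant) < 2:
            skipped += 1
            continue
        i, j = rng.choice(len(extant), size=2, replace=False)
        a, b = extant[int(i)], extant[int(j)]
        d = tree.lineage_distance(a.id, b.id)
        phi = abs(getattr(a, phenotype) - getattr(b, phenotype))
        samples.append(PairSample(d=d, phi=phi))
    if skipped:
        warnings.warn(f"skipped {skipped} trees with < 2 extant cells")
    return samples


# ---------------------------------------------------------------------------
# information estimators
# ---------------------------------------------------------------------------

def _plugin_mi_bits(joint: np.ndarray) -> float:
    """Plug-in mutual information (bits) of a 2-D joint count table."""
    n = joint.sum()
    if n == 0:
        return 0.0
    p = joint / n
    pd_ = p.sum(axis=1, keepdims=True)
    pf_ = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask]
                                          / (pd_ @ pf_)[mask])))


def mutual_information(samples: Sequence[PairSample], n_bins: int = 8,
                       n_bootstrap: int = N_BOOTSTRAP,
                       rng: Optional[np.random.Generator] = None,
                       ) -> MIEstimate:
    """Mutual information between lineage distance and phenotype difference.

    Both coordinates are discretized into ``n_bins`` equal-width bins over
    the pooled sample range (edges fixed from the full sample set); the
    plug-in MI in bits is computed on the empirical joint, and its
    uncertainty from ``n_bootstrap`` bootstrap resamples of the pair set.
    A degenerate axis (all samples in one bin) yields MI = 0 with a warning.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 pair samples")
    if rng is None:
        rng = np.random.default_rng()
    d = np.array([s.d for s in samples])
    phi = np.array([s.phi for s in samples])
    if np.ptp(d) == 0 or np.ptp(phi) == 0:
        warnings.warn("degenerate binning (single occupied bin); MI = 0")
        return MIEstimate(0.0, 0.0, 0.0, len(samples), n_bins)
    d_edges = np.linspace(d.min(), d.max(), n_bins + 1)
    p_edges = np.linspace(phi.min(), phi.max(), n_bins + 1)
    joint, _, _ = np.histogram2d(d, phi, bins=(d_edges, p_edges))
    mi = _plugin_mi_bits(joint)
    boot = np.empty(n_bootstrap)
    n = len(samples)
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        jb, _, _ = np.histogram2d(d[idx], phi[idx], bins=(d_edges, p_edges))
        boot[b] = _plugin_mi_bits(jb)
    return MIEstimate(mi_bits=mi, mean_bits=float(boot.mean()),
                      sd_bits=float(boot.std()), n_samples=n, n_bins=n_bins)


def mutual_information_from_counts(joint: np.ndarray) -> float:
    """Plug-in MI (bits) straight from a joint count table."""
    return _plugin_mi_bits(np.asarray(joint, dtype=float))


def entropy(values: Sequence[float], mode: str = "fine",
            threshold: Optional[float] = None,
            bin_width: Optional[float] = None) -> float:
    """Plug-in entropy (bits) of a population phenotype.

    ``fine`` bins values on a fixed-width grid (``bin_width`` required or
    derived as range/32); ``binary`` splits at ``threshold`` — for growth
    rates the arrest cutoff, for toxin concentrations a configured level.
    """
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("values must be non-empty")
    if mode == "binary":
        if threshold is None:
            threshold = arrest_cutoff_per_min()
        labels = (values > threshold).astype(int)
    elif mode == "fine":
        if bin_width is None:
            span = np.ptp(values)
            bin_width = span / 32 if span > 0 else 1.0
        labels = np.floor(values / bin_width).astype(np.int64)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


# ---------------------------------------------------------------------------
# critical slowing down
# ---------------------------------------------------------------------------

def _autocorr(x: np.ndarray, max_lag: int) -> np.ndarray:
    x = x - x.mean()
    denom = np.dot(x, x)
    acf = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        acf[k] = np.dot(x[:len(x) - k], x[k:]) / denom
    return acf


def count_zero_crossings(y: np.ndarray) -> int:
    """Number of strict sign changes along ``y`` (zeros are transparent)."""
    s = np.sign(y)
    s = s[s != 0]
    return int(np.sum(s[1:] != s[:-1]))


def ensemble_autocorrelation(series: Sequence[np.ndarray], max_lag: int
                             ) -> Tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Replicate-averaged autocorrelation of growing-cell-count series.

    Each replicate series (already restricted to times after toxin onset)
    is mean-subtracted and its normalized autocorrelation computed at lags
    ``0..max_lag``; constant series are excluded with a warning.  Returns
    ``(lags, mean_abs_acf, mean_acf, zero_crossings)`` where the crossing
    count is taken on the replicate-mean (pre-absolute-value)
    autocorrelation — more than two crossings marks the slowly converging
    oscillatory regime.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 replicate series")
    acfs = []
    for k, x in enumerate(series):
        x = np.asarray(x, dtype=float)
        if max_lag >= len(x):
            raise ValueError("max_lag must be shorter than the series")
        if np.ptp(x) == 0:
            warnings.warn(f"replicate {k} has a constant series; excluded")
            continue
        acfs.append(_autocorr(x, max_lag))
    if not acfs:
        raise ValueError("all replicate series were constant")
    acfs = np.array(acfs)
    mean_acf = acfs.mean(axis=0)
    mean_abs = np.abs(acfs).mean(axis=0)
    lags = np.arange(max_lag + 1)
    return lags, mean_abs, mean_acf, count_zero_crossings(mean_acf)


# ---------------------------------------------------------------------------
# arrested clusters
# ---------------------------------------------------------------------------

def arrested_clusters(tree: LineageTree, cutoff: Optional[float] = None
                      ) -> List[int]:
    """Sizes of maximal runs of arrested cells in lineage-neighbor order.

    Extant cells are laid out in the tree's depth-first leaf order (daughter
    order was randomized at division time); consecutive cells with final
    growth rate at or below ``cutoff`` (1/min) form one cluster.  The sizes
    sum exactly to the number of arrested extant cells.
    """
    if cutoff is None:
        cutoff = arrest_cutoff_per_min()
    sizes: List[int] = []
    run = 0
    for leaf in tree.leaves_in_order():
        if leaf.growth_rate <= cutoff:
            run += 1
        elif run:
            sizes.append(run)
            run = 0
    if run:
        sizes.append(run)
    return sizes


def cluster_size_distribution(cluster_sizes: Iterable[Sequence[int]],
                              ) -> ClusterSizeDistribution:
    """Pool per-simulation cluster sizes and fit an exponential decay.

    ``cluster_sizes`` is an iterable of per-simulation size lists (empty
    lists contribute nothing).  Sizes are pooled across simulations — raw
    counts, not per-simulation normalized — and ``a*exp(-b*c)`` is fit by
    least squares on the log-frequencies of occupied sizes.  With fewer
    than 3 distinct sizes the fit is skipped and only the histogram
    returned.
    """
    pooled = np.array([s for sim in cluster_sizes for s in sim],
                      dtype=np.int64)
    if pooled.size == 0:
        empty = np.array([])
        return ClusterSizeDistribution(sizes=empty.astype(int), counts=empty,
                                       frequencies=empty, normalized=empty)
    sizes, counts = np.unique(pooled, return_counts=True)
    freqs = counts / counts.sum()
    p1 = freqs[sizes == 1][0] if (sizes == 1).any() else np.nan
    normalized = freqs / p1
    dist = ClusterSizeDistribution(sizes=sizes, counts=counts,
                                   frequencies=freqs, normalized=normalized)
    if len(sizes) >= 3:
        fit = stats.linregress(sizes, np.log(freqs))
        dist.fit_a = float(np.exp(fit.intercept))
        dist.fit_b = float(-fit.slope)
        dist.fit_r2 = float(fit.rvalue ** 2)
    return dist


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def mann_whitney_lineage(group_a: Sequence[float], group_b: Sequence[float],
                         alternative: str = "less"
                         ) -> Tuple[float, float]:
    """One-tailed Mann-Whitney U comparison of two lineage-distance sets.

    Small samples (both groups at most 10) use the exact null: scipy's
    exact method when there are no ties, and full permutation enumeration
    (which accommodates ties) otherwise.  Larger samples use the
    tie-corrected normal approximation.  Returns ``(U, p)`` with U for
    ``group_a``.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    small = a.size <= 10 and b.size <= 10
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    if small and has_ties:
        return _mann_whitney_tied_exact(a, b, alternative)
    method = "exact" if small else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def _mann_whitney_tied_exact(a: np.ndarray, b: np.ndarray,
                             alternative: str) -> Tuple[float, float]:
    """Exact permutation null of the U statistic in the presence of ties."""
    from itertools import combinations

    def u_stat(x, y):
        x = x[:, None]
        return float(np.sum(x > y) + 0.5 * np.sum(x == y))

    pooled = np.concatenate([a, b])
    n, n_a = len(pooled), len(a)
    u_obs = u_stat(a, b)
    null = np.array([u_stat(pooled[list(idx)],
                            pooled[[i for i in range(n) if i not in idx]])
                     for idx in combinations(range(n), n_a)])
    eps = 1e-9
    if alternative == "less":
        p = np.mean(null <= u_obs + eps)
    elif alternative == "greater":
        p = np.mean(null >= u_obs - eps)
    else:
        lo = min(np.mean(null <= u_obs + eps), np.mean(null >= u_obs - eps))
        p = min(1.0, 2.0 * lo)
    return u_obs, float(p)
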