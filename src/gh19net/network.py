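"""Protein sequence networks and their scale-free statistics.

Centroid sequences are nodes; an undirected edge connects two nodes when
their global percent identity meets the threshold (boundary inclusive), with
the identity as edge weight. From these graphs the package derives the
degree distribution N(n), fitted by a power law N(n) ~ n^-gamma, and the
cluster-size distribution N(s) ~ s^-tau_h over logarithmic size bins; the
Fisher exponent tau is obtained by linear extrapolation of the per-threshold
slopes tau_h to the 100%-identity limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .pairwise import IdentityMatrix

#: logarithmic cluster-size bins (inclusive bounds); singletons are excluded
SIZE_BINS: tuple[tuple[int, int], ...] = ((2, 10), (11, 100), (101, 1000), (1001, 10000))


def build_network(matrix: IdentityMatrix, threshold_pct: float) -> nx.Graph:
    """Threshold graph over centroids: edge iff identity >= threshold.

    All centroids are nodes, including isolated ones; no self-edges.
    """
    g = nx.Graph(threshold_pct=threshold_pct)
    g.add_nodes_from(matrix.ids)
    n = len(matrix.ids)
    for i in range(n):
        for j in range(i + 1, n):
            w = matrix.values[i, j]
            if w >= threshold_pct:
                g.add_edge(matrix.ids[i], matrix.ids[j], weight=float(w))
    return g


def connected_components(network: nx.Graph) -> list[set[str]]:
    """Components sorted by descending size, ties by smallest member id."""
    comps = [set(c) for c in nx.connected_components(network)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


@dataclass
class DegreeDistribution:
    """Counts N(n) of nodes having degree n, including degree 0."""

    counts: dict[int, int]

    @property
    def total_nodes(self) -> int:
        return sum(self.counts.values())


def degree_distribution(network: nx.Graph) -> DegreeDistribution:
    counts: dict[int, int] = {}
    for _, deg in network.degree():
        counts[deg] = counts.get(deg, 0) + 1
    return DegreeDistribution(counts=dict(sorted(counts.items())))


@dataclass
class PowerLawFit:
    """Least-squares line on (log10 x, log10 y); exponent = -slope."""

    exponent: float
    intercept: float
    fit_range: tuple[float, float]
    r2: float


def _loglog_fit(x: np.ndarray, y: np.ndarray, fit_range) -> PowerLawFit:
    lx, ly = np.log10(x), np.log10(y)
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(exponent=-float(slope), intercept=float(intercept),
                       fit_range=tuple(fit_range), r2=r2)


def fit_power_law(distribution: DegreeDistribution,
                  fit_range: tuple[int, int] = (1, 50)) -> PowerLawFit:
    """Fit N(n) ~ n^-gamma over degrees in ``fit_range``.

    Degree-0 nodes never enter the fit (log of zero degree is undefined).
    """
    lo, hi = fit_range
    pts = [(n, c) for n, c in distribution.counts.items() if lo <= n <= hi and n >= 1 and c > 0]
    if len(pts) < 2:
        raise ValueError(f"fewer than 2 usable histogram points in fit range {fit_range}")
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    return _loglog_fit(x, y, fit_range)


@dataclass
class ClusterSizeHistogram:
    """Raw component-size counts plus logarithmic-bin densities.

    Bin densities are counts divided by bin width, placed at the geometric
    midpoint of the bin; size-1 components are excluded (bins start at 2).
    """

    counts: dict[int, int]
    bins: tuple[tuple[int, int], ...] = SIZE_BINS
    bin_counts: list[int] = field(default_factory=list)
    bin_densities: list[float] = field(default_factory=list)
    bin_midpoints: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.bin_counts:
            for lo, hi in self.bins:
                c = sum(v for s, v in self.counts.items() if lo <= s <= hi)
                width = hi - lo + 1
                self.bin_counts.append(c)
                self.bin_densities.append(c / width)
                self.bin_midpoints.append(float(np.sqrt(lo * hi)))

    @property
    def total_size(self) -> int:
        return sum(s * c for s, c in self.counts.items())


def cluster_size_histogram(components: list[set[str]] | list[int],
                           bins=SIZE_BINS) -> ClusterSizeHistogram:
    sizes = [len(c) if not isinstance(c, (int, np.integer)) else int(c)
             for c in components]
    counts: dict[int, int] = {}
    for s in sizes:
        counts[s] = counts.get(s, 0) + 1
    return ClusterSizeHistogram(counts=dict(sorted(counts.items())), bins=tuple(bins))


def fit_tau_h(histogram: ClusterSizeHistogram) -> PowerLawFit:
    """Slope of the logarithmic cluster-size histogram: N(s) ~ s^-tau_h."""
    pts = [(m, d) for m, d in zip(histogram.bin_midpoints, histogram.bin_densities) if d > 0]
    if len(pts) < 2:
        raise ValueError("fewer than 2 nonzero bins; tau_h undefined")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    return _loglog_fit(x, y, (histogram.bins[0][0], histogram.bins[-1][1]))


@dataclass
class FisherExtrapolation:
    """Linear extrapolation of tau_h(threshold) to 100% identity."""

    pairs: list[tuple[float, float]]
    slope: float
    intercept: float
    tau_at_100: float


def fisher_extrapolate(tau_h_by_threshold: dict[float, float] | list[tuple[float, float]]
                       ) -> FisherExtrapolation:
    """Least-squares line tau_h = slope * threshold + intercept, read at 100."""
    pairs = sorted(tau_h_by_threshold.items()) if isinstance(tau_h_by_threshold, dict) \
        else sorted(tau_h_by_threshold)
    if len(pairs) < 2:
        raise ValueError("Fisher extrapolation needs at least 2 (threshold, tau_h) pairs")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    return FisherExtrapolation(pairs=pairs, slope=float(slope), intercept=float(intercept),
                               tau_at_100=float(slope * 100.0 + intercept))


# -- sampling helpers used to validate the fitting machinery ---------------

def sample_power_law_degrees(exponent: float, n_nodes: int, max_degree: int,
                             rng: np.random.Generator) -> DegreeDistribution:
    """Sample node degrees from P(n) ~ n^-exponent on 1..max_degree."""
    support = np.arange(1, max_degree + 1)
    p = support.astype(float) ** (-exponent)
    p /= p.sum()
    degrees = rng.choice(support, size=n_nodes, p=p)
    counts: dict[int, int] = {}
    for d in degrees:
        counts[int(d)] = counts.get(int(d), 0) + 1
    return DegreeDistribution(counts=dict(sorted(counts.items())))


def sample_power_law_sizes(exponent: float, n_components: int, rng: np.random.Generator,
                           min_size: int = 2, max_size: int = 10000) -> list[int]:
    """Sample component sizes from P(s) ~ s^-exponent on [min_size, max_size]."""
    support = np.arange(min_size, max_size + 1)
    p = support.astype(float) ** (-exponent)
    p /= p.sum()
    return [int(s) for s in rng.choice(support, size=n_components, p=p)]
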