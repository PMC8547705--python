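"""Threshold networks, components and power-law statistics."""

import numpy as np
import pytest

from gh19net.network import (ClusterSizeHistogram, DegreeDistribution,
                             build_network, cluster_size_histogram,
                             connected_components, degree_distribution,
                             fisher_extrapolate, fit_power_law, fit_tau_h,
                             sample_power_law_degrees, sample_power_law_sizes)
from gh19net.pairwise import IdentityMatrix
from oracles import closure_components


def _matrix(ids, pairs):
    n = len(ids)
    values = np.full((n, n), 0.0)
    np.fill_diagonal(values, 100.0)
    idx = {i: k for k, i in enumerate(ids)}
    for a, b, w in pairs:
        values[idx[a], idx[b]] = values[idx[b], idx[a]] = w
    return IdentityMatrix(ids=list(ids), values=values)


def test_build_network_thresholding():
    m = _matrix("abc", [("a", "b", 95), ("b", "c", 95), ("a", "c", 50)])
    g = build_network(m, 90)
    assert set(g.edges) == {("a", "b"), ("b", "c")}
    assert g.edges["a", "b"]["weight"] == 95.0

    assert build_network(m, 96).number_of_edges() == 0
    assert build_network(m, 96).number_of_nodes() == 3  # isolated nodes kept
    complete = build_network(_matrix("abcd", [(a, b, 50) for a in "abcd"
                                              for b in "abcd" if a < b]), 1e-9)
    assert complete.number_of_edges() == 6

    boundary = build_network(_matrix("ab", [("a", "b", 90.0)]), 90.0)
    assert boundary.number_of_edges() == 1  # >= threshold is inclusive


def test_connected_components_examples():
    m = _matrix("abcd", [("a", "b", 95), ("b", "c", 95)])
    comps = connected_components(build_network(m, 90))
    assert comps == [{"a", "b", "c"}, {"d"}]
    complete = _matrix("abc", [("a", "b", 95), ("b", "c", 95), ("a", "c", 95)])
    assert len(connected_components(build_network(complete, 90))) == 1


@pytest.mark.parametrize("seed", range(5))
def test_components_match_transitive_closure_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 50))
    ids = [f"n{i}" for i in range(n)]
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)
             if rng.random() < 0.05]
    m = _matrix(ids, [(f"n{i}", f"n{j}", 95.0) for i, j in edges])
    comps = connected_components(build_network(m, 90))
    oracle = [{f"n{i}" for i in c} for c in closure_components(n, edges)]
    assert sorted(map(sorted, comps)) == sorted(map(sorted, oracle))


def test_degree_distribution_examples():
    star = _matrix("hABCDEFG", [("h", x, 95) for x in "ABCDEFG"])
    dd = degree_distribution(build_network(star, 90))
    assert dd.counts == {1: 7, 7: 1}
    edgeless = degree_distribution(build_network(_matrix("abcde", []), 90))
    assert edgeless.counts == {0: 5}
    k4 = _matrix("abcd", [(a, b, 95) for a in "abcd" for b in "abcd" if a < b])
    assert degree_distribution(build_network(k4, 90)).counts == {3: 4}
    assert dd.total_nodes == 8  # mass conservation


@pytest.mark.parametrize("gamma", [2.0, 1.1])
def test_fit_recovers_exact_power_law(gamma):
    counts = {n: 1000.0 * n ** (-gamma) for n in range(1, 51)}
    fit = fit_power_law(DegreeDistribution(counts=counts), fit_range=(1, 50))
    assert fit.exponent == pytest.approx(gamma, abs=1e-9)
    assert fit.r2 == pytest.approx(1.0)


def test_fit_power_law_needs_two_points():
    with pytest.raises(ValueError):
        fit_power_law(DegreeDistribution(counts={3: 10}), fit_range=(1, 50))


def test_degree_exponent_recovered_from_sampled_graphs():
    errors = []
    for seed in range(3):
        rng = np.random.default_rng(seed)
        dd = sample_power_law_degrees(2.0, 2000, 50, rng)
        fit = fit_power_law(dd, fit_range=(1, 10))
        errors.append(abs(fit.exponent - 2.0))
    assert max(errors) < 0.15


def test_cluster_size_histogram_binning():
    h = cluster_size_histogram([3, 3, 7, 40])
    assert h.bin_counts == [3, 1, 0, 0]
    assert h.bin_densities[0] == pytest.approx(3 / 9)
    assert h.bin_midpoints[0] == pytest.approx(np.sqrt(20))
    assert h.total_size == 53

    singletons = cluster_size_histogram([1, 1, 1])
    assert singletons.bin_counts == [0, 0, 0, 0]

    comps = [{"a", "b"}, {"c", "d", "e"}]
    assert cluster_size_histogram(comps).counts == {2: 1, 3: 1}


def test_tau_h_recovered_from_sampled_sizes():
    rng = np.random.default_rng(0)
    sizes = sample_power_law_sizes(1.1, 4000, rng)
    fit = fit_tau_h(cluster_size_histogram(sizes))
    assert fit.exponent == pytest.approx(1.1, abs=0.1)


def test_fisher_extrapolation():
    flat = fisher_extrapolate({60: 0.9, 70: 0.9, 80: 0.9})
    assert flat.tau_at_100 == pytest.approx(0.9)
    exact = fisher_extrapolate([(60, 0.6), (80, 0.8)])
    assert exact.tau_at_100 == pytest.approx(1.0)
    # worked example from published per-threshold slopes (rounded)
    printed = fisher_extrapolate({60: 0.7, 70: 0.7, 80: 0.8, 90: 1.1})
    assert printed.tau_at_100 == pytest.approx(1.15, abs=1e-9)
    with pytest.raises(ValueError):
        fisher_extrapolate({60: 0.7})


def test_histogram_mass_conserves_nodes():
    rng = np.random.default_rng(3)
    sizes = [int(s) for s in rng.integers(1, 30, size=50)]
    h = cluster_size_histogram(sizes)
    assert h.total_size == sum(sizes)
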