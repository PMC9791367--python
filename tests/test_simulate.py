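"""Planted-data generators: degree law, recovery guarantee, error rates,
fitness law and reproducibility."""

import numpy as np
import pytest

from pleionet.errors import ConfigError
from pleionet.network import build_adjacency, select_focal_genes, significance_mask
from pleionet.simulate import (
    SyntheticSpec,
    fitness_noise_for_target_r2,
    generate_compendium,
    generate_dataset,
    generate_fitness,
    generate_planted_network,
    sample_outdegrees,
)
from pleionet.topology import fitness_vs_pleiotropy_regression
from pleionet.pleiotropy import pleiotropy_records


def test_spec_validation():
    with pytest.raises(ConfigError):
        SyntheticSpec(n_genes=10, n_deletions=20)
    with pytest.raises(ConfigError):
        SyntheticSpec(k_max=0)
    with pytest.raises(ConfigError):
        SyntheticSpec(self_effect_m=1.0)
    with pytest.raises(ConfigError):
        SyntheticSpec(false_positive_rate=1.0)


def test_large_gamma_collapses_to_degree_one():
    spec = SyntheticSpec(n_genes=100, n_deletions=80, gamma=20.0, k_max=50, seed=0)
    draws = sample_outdegrees(spec)
    assert np.mean(draws == 1) > 0.99
    assert draws.min() >= 1 and draws.max() <= spec.k_max


def test_outdegree_sampling_deterministic():
    spec = SyntheticSpec(n_genes=100, n_deletions=50, k_max=30, seed=5)
    np.testing.assert_array_equal(sample_outdegrees(spec), sample_outdegrees(spec))


def test_planted_network_row_sums_are_k_plus_one():
    spec = SyntheticSpec(n_genes=150, n_deletions=40, k_max=30, seed=2)
    net = generate_planted_network(spec)
    degrees = sample_outdegrees(spec)  # same stream, same draws
    row_sums = net.A.sum(axis=1)
    np.testing.assert_array_equal(row_sums, degrees + 1)
    for i, d in enumerate(net.deletions):
        assert net.A[i, net.gene_position(d)] == 1  # self edge planted
    assert (net.A.sum(axis=1) >= 2).all()  # at least one non-self target


def test_zero_error_rates_reproduce_planted_adjacency():
    spec = SyntheticSpec(n_genes=300, n_deletions=80, k_max=60, seed=4)
    net, comp, _ = generate_dataset(spec)
    mask = significance_mask(
        comp.M.to_numpy(float), comp.P.to_numpy(float), net.thresholds
    )
    np.testing.assert_array_equal(mask.astype(np.int8), net.A)


def test_false_positive_rate_recovered():
    spec = SyntheticSpec(false_positive_rate=0.01, seed=8)
    net, comp, _ = generate_dataset(spec)
    rebuilt = build_adjacency(comp, net.thresholds)
    non_edges = net.A == 0
    spurious = (rebuilt.A == 1) & non_edges
    rate = spurious.sum() / non_edges.sum()
    assert rate == pytest.approx(0.01, abs=0.003)


def test_false_negative_rate_recovered():
    spec = SyntheticSpec(n_genes=1000, n_deletions=400, k_max=200,
                         false_negative_rate=0.1, seed=8)
    net, comp, _ = generate_dataset(spec)
    rebuilt = build_adjacency(comp, net.thresholds)
    self_cells = np.zeros_like(net.A, dtype=bool)
    for i, d in enumerate(net.deletions):
        self_cells[i, net.gene_position(d)] = True
    true_edges = (net.A == 1) & ~self_cells
    missed = (rebuilt.A == 0) & true_edges
    assert missed.sum() / true_edges.sum() == pytest.approx(0.1, abs=0.01)


def test_self_cells_always_pass_focal_filter():
    spec = SyntheticSpec(n_genes=400, n_deletions=150, k_max=80,
                         false_negative_rate=0.3, seed=6)
    net, comp, _ = generate_dataset(spec)
    rebuilt = select_focal_genes(build_adjacency(comp, net.thresholds), comp)
    assert rebuilt.filter_counts["no_self_decrease"] == 0
    assert rebuilt.filter_counts["not_measured"] == 0


def test_fitness_noiseless_arithmetic():
    spec = SyntheticSpec(n_genes=200, n_deletions=60, k_max=40,
                         fitness_slope=-0.1, fitness_noise_sd=0.0, seed=3)
    net = generate_planted_network(spec)
    fitness = generate_fitness(net, spec)
    k = net.out_degree(include_self=False)
    for gene in net.deletions:
        expected = 1 - 0.1 * np.log10(k[gene] + 1)
        assert fitness.fitness(gene) == pytest.approx(expected)
        if k[gene] == 9:
            assert fitness.fitness(gene) == pytest.approx(0.9)


def test_noiseless_fitness_gives_near_perfect_r2():
    spec = SyntheticSpec(n_genes=400, n_deletions=150, k_max=80,
                         fitness_noise_sd=0.0, seed=3)
    net, comp, fitness = generate_dataset(spec)
    records = pleiotropy_records(net, genes=net.deletions)
    _, _, r2, _ = fitness_vs_pleiotropy_regression(records, fitness)
    # signal is slope*log10(K+1) against predictor log10(K): collinear up
    # to the +1 shift, so r2 is near (not exactly) 1
    assert r2 > 0.98


def test_zero_slope_recovers_null():
    spec = SyntheticSpec(n_genes=500, n_deletions=200, k_max=100,
                         fitness_slope=0.0, fitness_noise_sd=0.05, seed=10)
    net, comp, fitness = generate_dataset(spec)
    records = pleiotropy_records(net, genes=net.deletions)
    slope, _, r2, p = fitness_vs_pleiotropy_regression(records, fitness)
    # standard error of the slope ~ sd_noise / (sd_x * sqrt(n))
    k = net.out_degree(include_self=False).to_numpy(dtype=float)
    se = 0.05 / (np.std(np.log10(k[k > 0])) * np.sqrt((k > 0).sum()))
    assert abs(slope) < 2 * se


def test_noise_helper_hits_target_r2():
    spec = SyntheticSpec(n_genes=1000, n_deletions=400, k_max=200, seed=12)
    net = generate_planted_network(spec)
    k = net.out_degree(include_self=False).to_numpy(dtype=float)
    sd = fitness_noise_for_target_r2(k, slope=-0.1, target_r2=0.3)
    spec2 = SyntheticSpec(n_genes=1000, n_deletions=400, k_max=200,
                          fitness_noise_sd=sd, seed=12)
    fitness = generate_fitness(net, spec2)
    records = pleiotropy_records(net, genes=net.deletions)
    _, _, r2, _ = fitness_vs_pleiotropy_regression(records, fitness)
    assert r2 == pytest.approx(0.3, abs=0.07)


def test_generate_dataset_bit_reproducible():
    spec = SyntheticSpec(n_genes=150, n_deletions=50, k_max=30, seed=99)
    net1, comp1, fit1 = generate_dataset(spec)
    net2, comp2, fit2 = generate_dataset(spec)
    np.testing.assert_array_equal(net1.A, net2.A)
    assert comp1.equals(comp2)
    assert fit1.values.equals(fit2.values)
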