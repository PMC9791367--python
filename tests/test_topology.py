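"""Out-degree histogram, power-law fit and fitness analyses."""

import numpy as np
import pandas as pd
import pytest

from pleionet.errors import ValidationError
from pleionet.io import FitnessTable
from pleionet.network import build_adjacency, select_focal_genes
from pleionet.pleiotropy import PleiotropyRecord
from pleionet.topology import (
    FitnessComparison,
    fit_powerlaw,
    fitness_cost_pairs,
    fitness_vs_pleiotropy_regression,
    outdegree_histogram,
    proportion_cis_cost_greater,
)

from conftest import make_compendium


def _fitness(mapping):
    return FitnessTable(values=pd.Series(mapping, name="fitness"))


# -- histogram --------------------------------------------------------------

def test_t1_outdegree_histogram_includes_self(t1_network):
    assert outdegree_histogram(t1_network) == {1: 1, 2: 1, 3: 1, 5: 1}
    assert outdegree_histogram(t1_network, include_self=False) == {
        0: 1, 1: 1, 2: 1, 4: 1
    }


def test_empty_network_histogram():
    comp = make_compendium(["G1", "G2"], ["G1", "G2"], {})
    net = build_adjacency(comp)
    assert outdegree_histogram(net) == {0: 2}


def test_histogram_total_equals_deletions(t1_network):
    assert sum(outdegree_histogram(t1_network).values()) == len(t1_network.deletions)


# -- power-law fit -----------------------------------------------------------

@pytest.mark.parametrize("gamma, k_top", [(0.75, 100), (2.0, 50)])
def test_fit_recovers_noiseless_exponent(gamma, k_top):
    ks = np.arange(1, k_top + 1)
    weights = ks.astype(float) ** (-gamma)
    # counts proportional to the exact pmf (scaled to large integers)
    hist = {int(k): float(1e9 * w) for k, w in zip(ks, weights)}
    fit = fit_powerlaw(hist)
    assert fit.gamma == pytest.approx(gamma, abs=1e-10)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-10)
    assert fit.n_points == k_top


def test_fit_requires_three_degrees():
    with pytest.raises(ValidationError):
        fit_powerlaw({1: 10, 2: 5})


def test_fit_excludes_zero_degree():
    ks = np.arange(1, 30)
    hist = {int(k): float(1000 * k**-1.5) for k in ks}
    with_zeros = dict(hist)
    with_zeros[0] = 999
    assert fit_powerlaw(with_zeros).gamma == pytest.approx(
        fit_powerlaw(hist).gamma
    )


def test_fit_recovers_exponent_from_multinomial_sample():
    rng = np.random.default_rng(13)
    gamma, k_max, n = 0.75, 500, 10_000
    ks = np.arange(1, k_max + 1)
    p = ks**-gamma / np.sum(ks**-gamma)
    draws = rng.choice(ks, size=n, p=p)
    values, counts = np.unique(draws, return_counts=True)
    fit = fit_powerlaw({int(v): int(c) for v, c in zip(values, counts)})
    assert fit.gamma == pytest.approx(gamma, abs=0.1)


# -- fitness regression -------------------------------------------------------

def _records(counts):
    return [PleiotropyRecord(g, c, float("nan")) for g, c in counts.items()]


def test_regression_exact_on_noiseless_relation():
    counts = {f"g{i}": k for i, k in enumerate([1, 3, 10, 30, 100, 300])}
    fitness = _fitness({g: 1 - 0.1 * np.log10(c) for g, c in counts.items()})
    slope, intercept, r2, _ = fitness_vs_pleiotropy_regression(
        _records(counts), fitness
    )
    assert slope == pytest.approx(-0.1, abs=1e-12)
    assert intercept == pytest.approx(1.0, abs=1e-12)
    assert r2 == pytest.approx(1.0, abs=1e-12)


def test_regression_constant_fitness_has_no_association():
    counts = {f"g{i}": k for i, k in enumerate([1, 2, 5, 50])}
    fitness = _fitness({g: 0.9 for g in counts})
    slope, _, r2, _ = fitness_vs_pleiotropy_regression(_records(counts), fitness)
    assert slope == pytest.approx(0.0, abs=1e-12)
    assert r2 == pytest.approx(0.0, abs=1e-12)


def test_regression_two_point_closed_form():
    counts = {"a": 10, "b": 1000, "c": 10}
    fitness = _fitness({"a": 0.9, "b": 0.5, "c": 0.9})
    slope, intercept, r2, _ = fitness_vs_pleiotropy_regression(
        _records(counts), fitness
    )
    # x = (1, 3, 1), y = (0.9, 0.5, 0.9): slope -0.2, intercept 1.1
    assert slope == pytest.approx(-0.2)
    assert intercept == pytest.approx(1.1)
    assert r2 == pytest.approx(1.0)


def test_regression_excludes_zero_counts_and_needs_overlap():
    counts = {"a": 0, "b": 0, "c": 1}
    fitness = _fitness({"a": 1.0, "b": 1.0, "c": 1.0})
    with pytest.raises(ValidationError):
        fitness_vs_pleiotropy_regression(_records(counts), fitness)


# -- fitness cost pairs --------------------------------------------------------

@pytest.fixture()
def toy_cost_network():
    genes = ["F", "T1", "T2", "X"]
    edges = {"F": {"F", "X"}, "T1": {"T1", "F"}, "T2": {"T2", "F"}}
    comp = make_compendium(genes, ["F", "T1", "T2"], edges)
    return select_focal_genes(build_adjacency(comp), comp)


def test_fitness_cost_pairs_toy(toy_cost_network):
    fitness = _fitness({"F": 0.9, "T1": 0.7, "T2": 0.8})
    comparison = fitness_cost_pairs(toy_cost_network, fitness)
    per_focal = comparison.per_focal.set_index("focal")
    assert per_focal.loc["F", "cis_cost"] == pytest.approx(0.1)
    assert per_focal.loc["F", "median_trans_cost"] == pytest.approx(0.25)
    assert sorted(comparison.pairs["trans_cost"]) == pytest.approx([0.2, 0.3])
    num, den, _ = proportion_cis_cost_greater(comparison, "per_pair")
    assert (num, den) == (0, 2)


def test_neutral_fitness_all_ties(toy_cost_network):
    fitness = _fitness({"F": 1.0, "T1": 1.0, "T2": 1.0})
    comparison = fitness_cost_pairs(toy_cost_network, fitness)
    num, den, prop = proportion_cis_cost_greater(comparison, "per_pair")
    assert (num, prop) == (0, 0.0)
    num, _, _ = proportion_cis_cost_greater(comparison, "per_focal")
    assert num == 0


def test_missing_fitness_entries_dropped(toy_cost_network):
    fitness = _fitness({"F": 0.9, "T1": 0.7})  # T2 absent
    comparison = fitness_cost_pairs(toy_cost_network, fitness)
    assert list(comparison.pairs["trans"]) == ["T1"]
    assert len(comparison.per_focal) == 1


def test_cost_comparison_antisymmetry(toy_cost_network):
    fitness = _fitness({"F": 0.6, "T1": 0.7, "T2": 0.8})
    comparison = fitness_cost_pairs(toy_cost_network, fitness)
    swapped = FitnessComparison(
        pairs=comparison.pairs.rename(
            columns={"cis_cost": "trans_cost", "trans_cost": "cis_cost"}
        ),
        per_focal=comparison.per_focal.rename(
            columns={"cis_cost": "median_trans_cost",
                     "median_trans_cost": "cis_cost"}
        ),
    )
    n_greater, den, _ = proportion_cis_cost_greater(comparison, "per_pair")
    n_swapped, _, _ = proportion_cis_cost_greater(swapped, "per_pair")
    ties = int((comparison.pairs["cis_cost"] == comparison.pairs["trans_cost"]).sum())
    assert n_greater + n_swapped + ties == den
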