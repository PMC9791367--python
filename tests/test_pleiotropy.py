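"""Counts, nested/parallel decomposition and Euclidean distances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pleionet.errors import DomainError
from pleionet.pleiotropy import (
    cis_pleiotropy_count,
    cis_trans_pairs,
    euclidean_pleiotropy,
    focal_decreasing_pairs,
    parallel_pleiotropy_count,
    trans_pair_pleiotropy_count,
)

from conftest import make_compendium, random_network_compendium


# -- counts on T1 --------------------------------------------------------

@pytest.mark.parametrize("focal, expected", [("G1", 2), ("G2", 1), ("G3", 0), ("G4", 4)])
def test_cis_count_t1(t1_network, focal, expected):
    assert cis_pleiotropy_count(t1_network, focal) == expected


def test_cis_count_unknown_deletion(t1_network):
    with pytest.raises(DomainError):
        cis_pleiotropy_count(t1_network, "G5")


@pytest.mark.parametrize(
    "trans, focal, expected",
    [("G4", "G1", 3), ("G2", "G1", 0), ("G1", "G3", 1), ("G4", "G3", 3)],
)
def test_trans_pair_count_t1(t1_network, trans, focal, expected):
    assert trans_pair_pleiotropy_count(t1_network, trans, focal) == expected


def test_trans_pair_requires_an_edge(t1_network):
    with pytest.raises(DomainError):
        trans_pair_pleiotropy_count(t1_network, "G3", "G1")  # G3 only hits itself


@pytest.mark.parametrize(
    "trans, focal, expected",
    [("G4", "G1", 1), ("G4", "G3", 3), ("G4", "G2", 2), ("G1", "G3", 1)],
)
def test_parallel_count_t1(t1_network, trans, focal, expected):
    # (G4,G1): targets {G2,G3,G5}, {G2,G3} nested in del G1 -> only {G5}
    # (G4,G3): del G3 has no other targets, nothing nested
    assert parallel_pleiotropy_count(t1_network, trans, focal) == expected


def test_zero_cis_focal_makes_parallel_equal_trans(t1_network):
    # G3 has cis count 0, so nothing can be nested
    for trans in ("G1", "G4"):
        assert parallel_pleiotropy_count(
            t1_network, trans, "G3"
        ) == trans_pair_pleiotropy_count(t1_network, trans, "G3")


def test_set_conservation_against_brute_force_oracle():
    """parallel + nested = trans count, with every count re-derived from
    explicit target sets on random networks."""
    rng = np.random.default_rng(7)
    checked_pairs = 0
    for _ in range(40):
        net, comp, edges = random_network_compendium(rng)
        targets = {d: set(edges[d]) for d in net.deletions}
        for focal in net.focal_genes:
            for trans in net.deletions:
                if trans == focal or focal not in targets[trans]:
                    continue
                trans_set = targets[trans] - {trans, focal}
                nested = {g for g in trans_set if g in targets[focal]}
                assert trans_pair_pleiotropy_count(net, trans, focal) == len(trans_set)
                par = parallel_pleiotropy_count(net, trans, focal)
                assert par == len(trans_set - nested)
                assert par + len(nested) == len(trans_set)
                checked_pairs += 1
    assert checked_pairs > 50


def test_cis_count_is_rowsum_minus_self(t1_network):
    for i, d in enumerate(t1_network.deletions):
        assert (
            cis_pleiotropy_count(t1_network, d)
            == t1_network.A[i].sum() - t1_network.self_cell(d)
        )


# -- Euclidean distance --------------------------------------------------

def _single_strain_compendium(m_values, genes=None):
    genes = genes or [f"G{i}" for i in range(1, len(m_values) + 1)]
    comp = make_compendium(genes, [genes[0]], {})
    comp.M.iloc[0, :] = m_values
    return comp


def test_euclidean_all_zero_row_is_origin():
    comp = _single_strain_compendium([0.0, 0.0, 0.0])
    assert euclidean_pleiotropy(comp, "G1") == 0.0


def test_euclidean_three_four_five():
    comp = _single_strain_compendium([3.0, 4.0, 0.0, 0.0])
    assert euclidean_pleiotropy(comp, "G1") == pytest.approx(5.0)


def test_euclidean_exclusion_removes_coordinate():
    comp = _single_strain_compendium([-6.0, 0.0, 0.0])
    assert euclidean_pleiotropy(comp, "G1", exclude={"G1"}) == 0.0


def test_euclidean_skips_missing_values():
    comp = _single_strain_compendium([3.0, 4.0, np.nan])
    assert euclidean_pleiotropy(comp, "G1") == pytest.approx(5.0)


def test_euclidean_linear_scale_places_wild_type_at_ones():
    comp = _single_strain_compendium([1.0, 0.0])  # fold changes (2, 1)
    assert euclidean_pleiotropy(comp, "G1", scale="linear") == pytest.approx(1.0)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.floats(-8, 8, allow_nan=False), min_size=2, max_size=12))
def test_euclidean_invariant_under_gene_reordering(values):
    base = euclidean_pleiotropy(_single_strain_compendium(values), "G1")
    perm = np.random.default_rng(0).permutation(len(values))
    shuffled = euclidean_pleiotropy(
        _single_strain_compendium(list(np.asarray(values)[perm])), "G1"
    )
    assert shuffled == pytest.approx(base)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    st.lists(st.floats(0, 8, allow_nan=False), min_size=2, max_size=10),
    st.integers(0, 9),
)
def test_euclidean_monotone_in_magnitudes(values, bump_at):
    bump_at = bump_at % len(values)
    comp_lo = _single_strain_compendium(values)
    hi = list(values)
    hi[bump_at] += 1.0
    comp_hi = _single_strain_compendium(hi)
    assert euclidean_pleiotropy(comp_hi, "G1") >= euclidean_pleiotropy(comp_lo, "G1")


# -- direction-restricted pairs ------------------------------------------

def test_focal_decreasing_pairs_t1(t1_network, t1_compendium):
    # M[G4, G1] = +2 (increase), M[G2, G1] = -2 (decrease)
    pairs = focal_decreasing_pairs(t1_network, t1_compendium)
    g1_pairs = [(p.trans, p.focal) for p in pairs if p.focal == "G1"]
    assert g1_pairs == [("G2", "G1")]
    assert all(p.focal_effect_sign == "decrease" for p in pairs)


def test_all_negative_network_retains_every_pair(t1_network, t1_compendium):
    all_pairs = cis_trans_pairs(t1_network, t1_compendium)
    comp = make_compendium(
        ["G1", "G2", "G3", "G4", "G5"],
        ["G1", "G2", "G3", "G4"],
        {"G1": {"G1", "G2", "G3"}, "G2": {"G2", "G1"}, "G3": {"G3"},
         "G4": {"G4", "G1", "G2", "G3", "G5"}},
    )  # every significant effect negative
    from pleionet.network import build_adjacency, select_focal_genes

    net = select_focal_genes(build_adjacency(comp), comp)
    assert len(focal_decreasing_pairs(net, comp)) == len(
        cis_trans_pairs(net, comp)
    ) == len(all_pairs)


def test_pair_signs_annotated_on_all_pairs(t1_network, t1_compendium):
    pairs = cis_trans_pairs(t1_network, t1_compendium)
    signs = {(p.trans, p.focal): p.focal_effect_sign for p in pairs}
    assert signs[("G4", "G1")] == "increase"
    assert signs[("G2", "G1")] == "decrease"
    assert len(pairs) == 6  # G1:{G2,G4}, G2:{G1,G4}, G3:{G1,G4}
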