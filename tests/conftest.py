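"""Shared fixtures: the five-gene toy network T1 and random-network builders.

T1: genes G1..G5, deletion strains for G1..G4. Significant calls —
del G1 affects {G1 (self, M=-6), G2, G3}; del G2 affects {G2 (self), G1};
del G3 affects {G3 (self)}; del G4 affects {G4 (self), G1, G2, G3, G5}.
All self-effects are significant decreases. Significant non-self cells
carry M = -2 except M[G4, G1] = +2 (an increase), p = 0.001; everything
else M = 0.1, p = 0.9.
"""

import numpy as np
import pandas as pd
import pytest

from pleionet.io import ExpressionCompendium, ExpressionDialect
from pleionet.network import Thresholds, build_adjacency, select_focal_genes

T1_GENES = ["G1", "G2", "G3", "G4", "G5"]
T1_DELETIONS = ["G1", "G2", "G3", "G4"]
T1_EDGES = {
    "G1": {"G1", "G2", "G3"},
    "G2": {"G2", "G1"},
    "G3": {"G3"},
    "G4": {"G4", "G1", "G2", "G3", "G5"},
}
SELF_M = -6.0


def make_compendium(
    genes, deletions, edges, self_m=SELF_M, sig_m=-2.0, overrides=None,
    media=None, dialect=None,
):
    """Build a compendium whose thresholding (fc 1.7, p 0.05) yields ``edges``."""
    dialect = dialect or ExpressionDialect()
    overrides = overrides or {}
    media = media or {}
    n_d, n_g = len(deletions), len(genes)
    M = np.full((n_d, n_g), 0.1)
    P = np.full((n_d, n_g), 0.9)
    gpos = {g: j for j, g in enumerate(genes)}
    for i, d in enumerate(deletions):
        for target in edges.get(d, ()):
            j = gpos[target]
            M[i, j] = self_m if target == d else overrides.get((d, target), sig_m)
            P[i, j] = 1e-6 if target == d else 1e-3
    strain_ids = [
        dialect.strain_header(d, media.get(d, dialect.default_media))
        for d in deletions
    ]
    strains = pd.DataFrame(
        {
            "strain_id": strain_ids,
            "deleted_gene": deletions,
            "media": [media.get(d, dialect.default_media) for d in deletions],
        }
    )
    idx = pd.Index(strain_ids, name="strain_id")
    cols = pd.Index(genes, name="gene")
    return ExpressionCompendium(
        strains=strains,
        M=pd.DataFrame(M, index=idx, columns=cols),
        P=pd.DataFrame(P, index=idx, columns=cols),
    )


@pytest.fixture(scope="session")
def t1_compendium():
    return make_compendium(
        T1_GENES, T1_DELETIONS, T1_EDGES, overrides={("G4", "G1"): 2.0}
    )


@pytest.fixture(scope="session")
def t1_network(t1_compendium):
    net = build_adjacency(t1_compendium, Thresholds())
    return select_focal_genes(net, t1_compendium)


def random_network_compendium(rng, n_genes=None, n_deletions=None):
    """A random small network + matching compendium; self-effects always
    significant decreases so every measured deletion is focal-eligible."""
    n_genes = n_genes or int(rng.integers(5, 30))
    n_deletions = n_deletions or int(rng.integers(2, n_genes + 1))
    genes = [f"G{i}" for i in range(1, n_genes + 1)]
    deletions = genes[:n_deletions]
    edges = {}
    for d in deletions:
        others = [g for g in genes if g != d]
        k = int(rng.integers(0, len(others) + 1))
        chosen = list(rng.choice(others, size=k, replace=False)) if k else []
        edges[d] = {d, *chosen}
    comp = make_compendium(genes, deletions, edges)
    net = select_focal_genes(build_adjacency(comp), comp)
    return net, comp, edges
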