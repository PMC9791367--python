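"""Thresholding the expression compendium into a binary directed
perturbation network, and the focal-gene filters.

An edge runs from a deleted gene to every gene whose expression changes
significantly in that deletion strain: |M| at least log2 of the
fold-change cutoff AND adjusted p at most the p cutoff. Rows of the
adjacency matrix are deletions, columns are measured genes; the row of a
deletion is the full set of its perturbation effects (out-edges), the
column of a gene collects the deletions perturbing it (in-edges, its
trans-regulators).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError, ValidationError
from .io import ExpressionCompendium

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Thresholds:
    """Significance thresholds for calling a perturbation edge.

    ``fold_change_min`` is on the linear scale by default (a 1.7-fold
    change corresponds to |M| >= log2(1.7) ~ 0.766); set
    ``scale="log2"`` to interpret the cutoff directly on the M scale.
    """

    fold_change_min: float = 1.7
    p_max: float = 0.05
    scale: str = "linear"  # or "log2"

    def __post_init__(self):
        if self.scale not in ("linear", "log2"):
            raise ConfigError(f"unknown threshold scale {self.scale!r}")
        if self.scale == "linear" and self.fold_change_min <= 1.0:
            raise ConfigError("linear fold-change cutoff must exceed 1")
        if self.scale == "log2" and self.fold_change_min <= 0.0:
            raise ConfigError("log2 fold-change cutoff must be positive")
        if not (0.0 < self.p_max <= 1.0):
            raise ConfigError("p_max must be in (0, 1]")

    @property
    def m_min(self) -> float:
        """The cutoff on |M| (log2 scale)."""
        if self.scale == "linear":
            return math.log2(self.fold_change_min)
        return self.fold_change_min

    def to_dict(self) -> dict:
        return {
            "fold_change_min": self.fold_change_min,
            "p_max": self.p_max,
            "scale": self.scale,
        }


def is_significant_change(m, p, thresholds: Thresholds) -> bool:
    """True iff |m| >= the fold-change cutoff and p <= p_max.

    Missing (None/NaN) m or p never counts as significant.
    """
    if m is None or p is None:
        return False
    m = float(m)
    p = float(p)
    if math.isnan(m) or math.isnan(p):
        return False
    return abs(m) >= thresholds.m_min and p <= thresholds.p_max


def significance_mask(M: np.ndarray, P: np.ndarray, thresholds: Thresholds) -> np.ndarray:
    """Vectorised form of :func:`is_significant_change` (NaN -> False)."""
    M = np.asarray(M, dtype=float)
    P = np.asarray(P, dtype=float)
    with np.errstate(invalid="ignore"):
        return (np.abs(M) >= thresholds.m_min) & (P <= thresholds.p_max)


@dataclass
class PerturbationNetwork:
    """Binary directed adjacency from deleted genes to affected genes."""

    genes: pd.Index
    deletions: pd.Index
    A: np.ndarray  # shape (n_deletions, n_genes), 0/1
    thresholds: Thresholds
    focal_genes: tuple = ()
    #: deletions passing the measured + self-decrease filters (the pool from
    #: which focal genes are drawn; permutation nulls re-derive only the
    #: trans-regulator requirement from this pool).
    focal_candidates: tuple = ()
    filter_counts: dict = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self):
        self.A = np.asarray(self.A)
        if self.A.shape != (len(self.deletions), len(self.genes)):
            raise ValidationError("adjacency shape disagrees with indexes")
        vals = np.unique(self.A)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValidationError("adjacency must be binary")
        self._d_pos = {d: i for i, d in enumerate(self.deletions)}
        self._g_pos = {g: j for j, g in enumerate(self.genes)}

    # -- indexing helpers ---------------------------------------------
    def deletion_position(self, deletion: str) -> int:
        try:
            return self._d_pos[deletion]
        except KeyError:
            raise DomainError(f"{deletion!r} is not a deletion in this network")

    def gene_position(self, gene: str) -> int:
        try:
            return self._g_pos[gene]
        except KeyError:
            raise DomainError(f"{gene!r} is not measured in this network")

    def has_self_cell(self, deletion: str) -> bool:
        return deletion in self._g_pos

    def self_cell(self, deletion: str) -> int:
        """A[d, d] if d is measured, else 0."""
        if not self.has_self_cell(deletion):
            return 0
        return int(self.A[self.deletion_position(deletion), self._g_pos[deletion]])

    # -- degrees -------------------------------------------------------
    def out_degree(self, include_self: bool = True) -> pd.Series:
        k = self.A.sum(axis=1).astype(int)
        if not include_self:
            self_cells = np.array([self.self_cell(d) for d in self.deletions])
            k = k - self_cells
        return pd.Series(k, index=self.deletions, name="out_degree")

    def in_degree(self) -> pd.Series:
        return pd.Series(
            self.A.sum(axis=0).astype(int), index=self.genes, name="in_degree"
        )

    @property
    def n_edges(self) -> int:
        return int(self.A.sum())


def build_adjacency(
    compendium: ExpressionCompendium,
    thresholds: Optional[Thresholds] = None,
    provenance: str = "",
) -> PerturbationNetwork:
    """Threshold the compendium into a perturbation network.

    Focal-gene filters are *not* applied here; the result has an empty
    focal set (see :func:`select_focal_genes`).
    """
    thresholds = thresholds or Thresholds()
    deleted = compendium.strains["deleted_gene"]
    if deleted.isna().any() or (deleted.astype(str) == "").any():
        raise ValidationError("a strain's deleted gene is unidentifiable")
    if deleted.duplicated().any():
        dupes = deleted[deleted.duplicated()].unique().tolist()
        raise ValidationError(f"multiple strains delete the same gene(s): {dupes[:5]}")
    A = significance_mask(
        compendium.M.to_numpy(float), compendium.P.to_numpy(float), thresholds
    ).astype(np.int8)
    net = PerturbationNetwork(
        genes=compendium.genes,
        deletions=pd.Index(deleted.to_numpy(), name="deletion"),
        A=A,
        thresholds=thresholds,
        provenance=provenance,
    )
    logger.info(
        "built adjacency: %d deletions x %d genes, %d edges",
        len(net.deletions), len(net.genes), net.n_edges,
    )
    return net


def select_focal_genes(
    network: PerturbationNetwork, compendium: ExpressionCompendium
) -> PerturbationNetwork:
    """Apply the three focal-gene filters, logging each removal count.

    Sequentially: (1) remove measured deletions whose own expression does
    not show a significant decrease (correct deletion + expressed in wild
    type); (2) remove deletions not measured on the array; (3) remove
    deletions whose expression no *other* deletion perturbs (no
    trans-regulator, so no cis/trans contrast exists). Idempotent.
    """
    thresholds = network.thresholds
    measured = np.array([network.has_self_cell(d) for d in network.deletions])

    # (1) significant self-decrease, evaluated on measured deletions only
    self_ok = np.zeros(len(network.deletions), dtype=bool)
    for i, d in enumerate(network.deletions):
        if not measured[i]:
            continue
        strain = compendium.strain_for_deletion(d)
        m = compendium.M.at[strain, d]
        p = compendium.P.at[strain, d]
        self_ok[i] = is_significant_change(m, p, thresholds) and m < 0
    n_no_self_decrease = int((measured & ~self_ok).sum())
    survivors = measured & self_ok | ~measured

    # (2) measured on the array
    n_unmeasured = int((survivors & ~measured).sum())
    survivors &= measured

    # (3) at least one trans-regulator (incoming edge from another deletion)
    has_trans = np.zeros(len(network.deletions), dtype=bool)
    for i, d in enumerate(network.deletions):
        if not survivors[i]:
            continue
        col = network.A[:, network.gene_position(d)].copy()
        col[i] = 0
        has_trans[i] = col.any()
    n_no_trans = int((survivors & ~has_trans).sum())
    survivors &= has_trans

    focal = tuple(network.deletions[survivors])
    candidates = tuple(network.deletions[(measured & self_ok)])
    counts = {
        "no_self_decrease": n_no_self_decrease,
        "not_measured": n_unmeasured,
        "no_trans_regulator": n_no_trans,
        "focal": len(focal),
    }
    logger.info(
        "focal filters: %d lacked self-decrease, %d unmeasured, %d without a "
        "trans-regulator; %d focal genes retained",
        n_no_self_decrease, n_unmeasured, n_no_trans, len(focal),
    )
    return replace(
        network,
        focal_genes=focal,
        focal_candidates=candidates,
        filter_counts=counts,
    )


def trans_regulators_of(network: PerturbationNetwork, focal: str) -> set:
    """Deletions (other than the focal gene) that perturb the focal gene."""
    if focal not in network.focal_genes:
        raise DomainError(f"{focal!r} is not a focal gene of this network")
    j = network.gene_position(focal)
    regs = {
        d
        for i, d in enumerate(network.deletions)
        if network.A[i, j] and d != focal
    }
    return regs


# ---------------------------------------------------------------------------
# serialization: edge list + JSON sidecar
# ---------------------------------------------------------------------------

def write_network(network: PerturbationNetwork, prefix) -> tuple[Path, Path]:
    """Write ``<prefix>_edges.tsv`` (source, target) and a JSON sidecar with
    thresholds, focal genes and filter counts."""
    prefix = Path(prefix)
    edges_path = prefix.parent / (prefix.name + "_edges.tsv")
    meta_path = prefix.parent / (prefix.name + "_network.json")
    rows, cols = np.nonzero(network.A)
    frame = pd.DataFrame(
        {
            "source": network.deletions[rows],
            "target": network.genes[cols],
        }
    )
    frame.to_csv(edges_path, sep="\t", index=False)
    meta = {
        "thresholds": network.thresholds.to_dict(),
        "n_deletions": len(network.deletions),
        "n_genes": len(network.genes),
        "n_edges": network.n_edges,
        "focal_genes": list(network.focal_genes),
        "filter_counts": network.filter_counts,
        "provenance": network.provenance,
    }
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return edges_path, meta_path
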