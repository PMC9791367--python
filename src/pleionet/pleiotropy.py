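"""Pleiotropy measures for cis- and trans-regulatory deletions.

Cis pleiotropy of a focal gene is the number of genes differentially
expressed when the focal gene itself is deleted, excluding the focal gene.
Trans pleiotropy of a (trans-regulator, focal) pair is the analogous count
for the trans-regulator's deletion, excluding the regulator itself and the
focal gene. "Parallel" pleiotropy further removes nested effects — genes
also perturbed by the focal gene's own deletion, which may act *through*
the focal gene rather than alongside it. Euclidean pleiotropy drops the
significance cutoff entirely and measures the distance of a deletion's
expression profile from wild type in gene-expression space.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError
from .io import ExpressionCompendium
from .network import PerturbationNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PleiotropyRecord:
    """Per-gene cis pleiotropy: DE-gene count and Euclidean distance."""

    gene: str
    cis_count: int
    cis_euclidean: float


@dataclass(frozen=True)
class CisTransPair:
    """One (trans-regulator -> focal gene) edge and its decompositions."""

    focal: str
    trans: str
    trans_count: int
    parallel_count: int
    focal_effect_sign: str  # "decrease" | "increase"
    trans_euclidean: float

    def __post_init__(self):
        if self.trans == self.focal:
            raise DomainError("trans regulator cannot equal the focal gene")
        if not 0 <= self.parallel_count <= self.trans_count:
            raise DomainError("parallel count must lie in [0, trans_count]")


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def cis_pleiotropy_count(network: PerturbationNetwork, focal: str) -> int:
    """DE genes in the focal gene's own deletion, excluding itself."""
    i = network.deletion_position(focal)
    total = int(network.A[i].sum())
    return total - network.self_cell(focal)


def trans_pair_pleiotropy_count(
    network: PerturbationNetwork, trans: str, focal: str
) -> int:
    """DE genes in the trans deletion, excluding the trans gene and focal."""
    i = network.deletion_position(trans)
    jf = network.gene_position(focal)
    if not network.A[i, jf] or trans == focal:
        raise DomainError(f"({trans!r}, {focal!r}) is not a trans edge")
    total = int(network.A[i].sum())
    return total - network.self_cell(trans) - int(network.A[i, jf])


def parallel_pleiotropy_count(
    network: PerturbationNetwork, trans: str, focal: str
) -> int:
    """Trans pair count after removing effects nested in the focal deletion."""
    it = network.deletion_position(trans)
    if_ = network.deletion_position(focal)
    jf = network.gene_position(focal)
    if not network.A[it, jf] or trans == focal:
        raise DomainError(f"({trans!r}, {focal!r}) is not a trans edge")
    row_t = network.A[it].astype(bool).copy()
    row_f = network.A[if_].astype(bool)
    if network.has_self_cell(trans):
        row_t[network.gene_position(trans)] = False
    row_t[jf] = False
    return int((row_t & ~row_f).sum())


# ---------------------------------------------------------------------------
# Euclidean distance from wild type
# ---------------------------------------------------------------------------

def euclidean_pleiotropy(
    compendium: ExpressionCompendium,
    deletion: str,
    exclude: Optional[Iterable[str]] = None,
    scale: str = "log2",
) -> float:
    """Distance of a deletion's expression profile from wild type.

    Coordinates are per-gene M values (log2 fold-changes), wild type at the
    origin; no fold-change or significance cutoff is applied. With
    ``scale="linear"`` coordinates are linear fold-changes 2**M with wild
    type at the all-ones point. Missing and excluded genes are skipped.
    """
    if scale not in ("log2", "linear"):
        raise ConfigError(f"unknown Euclidean scale {scale!r}")
    try:
        row = compendium.m_row(deletion)
    except Exception as exc:
        raise DomainError(f"unknown deletion {deletion!r}: {exc}") from exc
    values = row.to_numpy(dtype=float)
    mask = ~np.isnan(values)
    if exclude:
        excl = set(exclude)
        mask &= ~row.index.isin(excl)
    coords = values[mask]
    if scale == "linear":
        coords = np.exp2(coords) - 1.0
    return float(np.sqrt(np.sum(coords**2)))


# ---------------------------------------------------------------------------
# table builders
# ---------------------------------------------------------------------------

def pleiotropy_records(
    network: PerturbationNetwork,
    compendium: Optional[ExpressionCompendium] = None,
    genes: Optional[Iterable[str]] = None,
    exclude_self_coordinate: bool = True,
    scale: str = "log2",
) -> list[PleiotropyRecord]:
    """Cis count + Euclidean distance per gene (default: the focal genes).

    The deleted gene's own (extreme) self-coordinate is excluded from the
    cis distance by default so the distance reflects downstream effects.
    Without a compendium only counts are available and the distance is NaN.
    """
    genes = list(genes) if genes is not None else list(network.focal_genes)
    records = []
    for g in genes:
        if compendium is None:
            dist = math.nan
        else:
            exclude = {g} if exclude_self_coordinate else None
            dist = euclidean_pleiotropy(compendium, g, exclude=exclude, scale=scale)
        records.append(
            PleiotropyRecord(
                gene=g,
                cis_count=cis_pleiotropy_count(network, g),
                cis_euclidean=dist,
            )
        )
    return records


def cis_trans_pairs(
    network: PerturbationNetwork,
    compendium: ExpressionCompendium,
    decreasing_only: bool = False,
    scale: str = "log2",
) -> list[CisTransPair]:
    """All (trans-regulator, focal) pairs over the network's focal genes.

    The pair-context Euclidean distance of the trans deletion excludes the
    trans gene's own coordinate and the focal gene's coordinate, mirroring
    the count definition. With ``decreasing_only`` only pairs in which the
    trans deletion *decreases* focal-gene expression are kept.
    """
    pairs: list[CisTransPair] = []
    for focal in network.focal_genes:
        jf = network.gene_position(focal)
        for i, trans in enumerate(network.deletions):
            if trans == focal or not network.A[i, jf]:
                continue
            m_tf = compendium.M.at[compendium.strain_for_deletion(trans), focal]
            sign = "decrease" if m_tf < 0 else "increase"
            if decreasing_only and sign != "decrease":
                continue
            pairs.append(
                CisTransPair(
                    focal=focal,
                    trans=trans,
                    trans_count=trans_pair_pleiotropy_count(network, trans, focal),
                    parallel_count=parallel_pleiotropy_count(network, trans, focal),
                    focal_effect_sign=sign,
                    trans_euclidean=euclidean_pleiotropy(
                        compendium, trans, exclude={trans, focal}, scale=scale
                    ),
                )
            )
    return pairs


def focal_decreasing_pairs(
    network: PerturbationNetwork,
    compendium: ExpressionCompendium,
    scale: str = "log2",
) -> list[CisTransPair]:
    """Pairs restricted to trans deletions that decrease the focal gene."""
    return cis_trans_pairs(network, compendium, decreasing_only=True, scale=scale)


def pairs_to_frame(pairs: Iterable[CisTransPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "focal": p.focal,
                "trans": p.trans,
                "trans_count": p.trans_count,
                "parallel_count": p.parallel_count,
                "focal_effect_sign": p.focal_effect_sign,
                "trans_euclidean": p.trans_euclidean,
            }
            for p in pairs
        ],
        columns=[
            "focal",
            "trans",
            "trans_count",
            "parallel_count",
            "focal_effect_sign",
            "trans_euclidean",
        ],
    )


def records_to_frame(records: Iterable[PleiotropyRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"gene": r.gene, "cis_count": r.cis_count, "cis_euclidean": r.cis_euclidean}
            for r in records
        ],
        columns=["gene", "cis_count", "cis_euclidean"],
    )
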