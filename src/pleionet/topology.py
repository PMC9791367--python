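"""Out-degree topology (power-law fit) and fitness integration.

The scale-free check regresses log p(K) on log K by least squares, where K
is a deletion's out-degree and p(K) its empirical frequency; the negated
slope is the power-law exponent gamma. Fitness analyses relate competitive
fitness (reference strain = 1) to expression pleiotropy, and compare the
fitness cost 1 - w of cis vs trans deletions affecting the same focal gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DomainError, ValidationError
from .io import FitnessTable
from .network import PerturbationNetwork
from .pleiotropy import PleiotropyRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PowerLawFit:
    gamma: float
    r_squared: float
    n_points: int

    def __post_init__(self):
        if self.n_points < 3:
            raise ValidationError("a reported fit needs >= 3 distinct K values")


@dataclass
class FitnessComparison:
    """Pairwise and per-focal cis/trans fitness costs (cost = 1 - fitness)."""

    pairs: pd.DataFrame  # focal, trans, cis_cost, trans_cost
    per_focal: pd.DataFrame  # focal, cis_cost, median_trans_cost


def outdegree_histogram(
    network: PerturbationNetwork, include_self: bool = True
) -> dict[int, int]:
    """Counts of deletions at each out-degree K, including K = 0.

    The self-edge is part of K by default (the fit is over the raw row
    sums of the full network); pass ``include_self=False`` to drop it.
    """
    k = network.out_degree(include_self=include_self).to_numpy()
    values, counts = np.unique(k, return_counts=True)
    return {int(v): int(c) for v, c in zip(values, counts)}


def fit_powerlaw(histogram: Mapping[int, int]) -> PowerLawFit:
    """Least-squares fit of log10 p(K) on log10 K over K > 0.

    p(K) is the empirical frequency among K > 0 deletions (log of zero
    degree is undefined; the number of excluded zero-K nodes is logged).
    gamma is the negated slope; the slope and r-squared are base-invariant.
    """
    ks = np.array(sorted(k for k, c in histogram.items() if k > 0 and c > 0))
    if ks.size < 3:
        raise ValidationError(
            f"need >= 3 distinct positive degrees, got {ks.size}"
        )
    n_zero = histogram.get(0, 0)
    if n_zero:
        logger.info("power-law fit excludes %d zero-out-degree deletions", n_zero)
    counts = np.array([histogram[int(k)] for k in ks], dtype=float)
    p_k = counts / counts.sum()
    res = stats.linregress(np.log10(ks), np.log10(p_k))
    return PowerLawFit(
        gamma=float(-res.slope),
        r_squared=float(res.rvalue**2),
        n_points=int(ks.size),
    )


def fitness_vs_pleiotropy_regression(
    records: Iterable[PleiotropyRecord], fitness: FitnessTable
) -> tuple[float, float, float, float]:
    """OLS of fitness on log10(cis DE-gene count); returns
    (slope, intercept, r_squared, p).

    Restricted to genes in both inputs with a positive count (the log of a
    zero count is undefined; exclusions are logged).
    """
    xs, ys = [], []
    n_zero = n_missing = 0
    for rec in records:
        if rec.gene not in fitness:
            n_missing += 1
            continue
        if rec.cis_count <= 0:
            n_zero += 1
            continue
        xs.append(np.log10(rec.cis_count))
        ys.append(fitness.fitness(rec.gene))
    if len(xs) < 3:
        raise ValidationError(
            f"need >= 3 usable genes; got {len(xs)} "
            f"({n_missing} without fitness, {n_zero} with zero count)"
        )
    logger.info(
        "fitness regression on %d genes (%d lacked fitness, %d had zero count)",
        len(xs), n_missing, n_zero,
    )
    res = stats.linregress(xs, ys)
    r2 = float(res.rvalue**2)
    if np.isnan(r2):  # constant response: no association by definition
        r2 = 0.0
    return float(res.slope), float(res.intercept), r2, float(res.pvalue)


def fitness_cost_pairs(
    network: PerturbationNetwork, fitness: FitnessTable
) -> FitnessComparison:
    """Cis vs trans fitness costs over focal genes with fitness data.

    Keeps focal genes that have fitness themselves and at least one
    trans-regulator with fitness; trans regulators absent from the fitness
    table are dropped with logged counts.
    """
    from .network import trans_regulators_of

    pair_rows, focal_rows = [], []
    n_focal_dropped = n_trans_dropped = 0
    for focal in network.focal_genes:
        if focal not in fitness:
            n_focal_dropped += 1
            continue
        cis_cost = fitness.cost(focal)
        trans_costs = []
        for trans in sorted(trans_regulators_of(network, focal)):
            if trans not in fitness:
                n_trans_dropped += 1
                continue
            cost = fitness.cost(trans)
            trans_costs.append(cost)
            pair_rows.append(
                {"focal": focal, "trans": trans, "cis_cost": cis_cost,
                 "trans_cost": cost}
            )
        if not trans_costs:
            n_focal_dropped += 1
            continue
        focal_rows.append(
            {"focal": focal, "cis_cost": cis_cost,
             "median_trans_cost": float(np.median(trans_costs))}
        )
    logger.info(
        "fitness pairs: %d focal genes kept (%d dropped), %d trans entries "
        "without fitness dropped",
        len(focal_rows), n_focal_dropped, n_trans_dropped,
    )
    return FitnessComparison(
        pairs=pd.DataFrame(
            pair_rows, columns=["focal", "trans", "cis_cost", "trans_cost"]
        ),
        per_focal=pd.DataFrame(
            focal_rows, columns=["focal", "cis_cost", "median_trans_cost"]
        ),
    )


def proportion_cis_cost_greater(
    comparison: FitnessComparison, mode: str = "per_pair"
) -> tuple[int, int, float]:
    """Fraction of pairs (or focal genes) where the cis deletion costs
    strictly more than the trans deletion (or median trans cost)."""
    if mode == "per_pair":
        frame = comparison.pairs
        if frame.empty:
            raise ValidationError("empty comparison")
        num = int((frame["cis_cost"] > frame["trans_cost"]).sum())
        den = len(frame)
    elif mode == "per_focal":
        frame = comparison.per_focal
        if frame.empty:
            raise ValidationError("empty comparison")
        num = int((frame["cis_cost"] > frame["median_trans_cost"]).sum())
        den = len(frame)
    else:
        raise ConfigError(f"unknown mode {mode!r}")
    return num, den, num / den
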