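"""Synthetic deleteome-style data with planted structure.

The generator emulates the statistical features the analysis rests on: a
directed perturbation network whose out-degrees follow a truncated discrete
power law (heavy-tailed, approximately scale-free), an (M, p) expression
matrix whose thresholding recovers the planted network at configurable
false-positive / false-negative rates, a strongly negative self M for every
deletion (the deleted gene's own expression collapses), and deletion
fitness anti-correlated with out-degree with configurable noise. Default
sizes are a desk-scale rendition of the real compendium (~6,100 genes x
~1,480 strains scaled to 2,000 x 600) with the exponent gamma = 0.75
observed for the real network. All generators are bit-reproducible from
``spec.seed``; each one draws from its own named substream so the pieces
can be regenerated independently.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import ExpressionCompendium, ExpressionDialect, FitnessTable
from .network import PerturbationNetwork, Thresholds

logger = logging.getLogger(__name__)

# substream roles, so each generator has an independent reproducible stream
_ROLE_NETWORK = 1
_ROLE_COMPENDIUM = 2
_ROLE_FITNESS = 3


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted data-generating process.

    ``gamma`` and ``k_max`` shape the truncated power law p(K) ~ K^-gamma on
    {1..k_max} for non-self out-degrees; ``self_effect_m`` is the planted
    log2 fold-change of each deleted gene on itself; edge effects have
    magnitude around ``edge_effect_mean`` (log2 units) and are negative with
    probability ``edge_sign_negative_prob``; fitness is
    1 + fitness_slope * log10(K + 1) + N(0, fitness_noise_sd).
    """

    n_genes: int = 2000
    n_deletions: int = 600
    gamma: float = 0.75
    k_max: int = 300
    self_effect_m: float = -6.0
    edge_effect_mean: float = 2.0
    edge_effect_sd: float = 0.5
    edge_sign_negative_prob: float = 0.5
    false_positive_rate: float = 0.0
    false_negative_rate: float = 0.0
    fitness_slope: float = -0.1
    fitness_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_deletions > self.n_genes:
            raise ConfigError("n_deletions must not exceed n_genes")
        if not (0 < self.k_max < self.n_genes):
            raise ConfigError("k_max must be in (0, n_genes)")
        if self.gamma <= 0:
            raise ConfigError("gamma must be positive")
        if self.self_effect_m >= 0:
            raise ConfigError("self_effect_m must be negative")
        for rate in (self.false_positive_rate, self.false_negative_rate):
            if not (0 <= rate < 1):
                raise ConfigError("error rates must be in [0, 1)")
        if self.fitness_noise_sd < 0:
            raise ConfigError("fitness_noise_sd must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(spec: SyntheticSpec, role: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([spec.seed, role])))


def gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def sample_outdegrees(
    spec: SyntheticSpec, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Draw n_deletions out-degrees from p(K) ~ K^-gamma on {1..k_max}."""
    rng = rng if rng is not None else _rng(spec, _ROLE_NETWORK)
    ks = np.arange(1, spec.k_max + 1)
    weights = ks.astype(float) ** (-spec.gamma)
    probs = weights / weights.sum()
    return rng.choice(ks, size=spec.n_deletions, p=probs)


def generate_planted_network(
    spec: SyntheticSpec, rng: Optional[np.random.Generator] = None
) -> PerturbationNetwork:
    """Plant a network: each deletion hits itself plus K_d distinct
    uniformly-chosen non-self targets (no assortativity)."""
    rng = rng if rng is not None else _rng(spec, _ROLE_NETWORK)
    genes = pd.Index(gene_names(spec.n_genes), name="gene")
    deletions = genes[: spec.n_deletions]
    degrees = sample_outdegrees(spec, rng)
    A = np.zeros((spec.n_deletions, spec.n_genes), dtype=np.int8)
    for i, k in enumerate(degrees):
        # uniform sample of k non-self targets: draw in [0, n-2], skip self
        picks = rng.choice(spec.n_genes - 1, size=int(k), replace=False)
        picks = picks + (picks >= i)
        A[i, picks] = 1
        A[i, i] = 1
    return PerturbationNetwork(
        genes=genes,
        deletions=pd.Index(deletions, name="deletion"),
        A=A,
        thresholds=Thresholds(),
        provenance=f"synthetic(seed={spec.seed})",
    )


def generate_compendium(
    network: PerturbationNetwork,
    spec: SyntheticSpec,
    rng: Optional[np.random.Generator] = None,
    dialect: Optional[ExpressionDialect] = None,
) -> ExpressionCompendium:
    """Emit an (M, p) compendium whose thresholding recovers the network.

    Planted edges get |M| safely above the fold-change cutoff and p below
    the significance cutoff; non-edges get sub-threshold M and p above the
    cutoff; every deletion's self cell gets ``self_effect_m`` with a tiny
    p. A ``false_negative_rate`` fraction of non-self edges is pushed
    sub-threshold and a ``false_positive_rate`` fraction of non-edges made
    significant. With both rates zero, thresholding reproduces the planted
    adjacency cell for cell.
    """
    rng = rng if rng is not None else _rng(spec, _ROLE_COMPENDIUM)
    dialect = dialect or ExpressionDialect()
    thr = network.thresholds
    m_min = thr.m_min
    n_d, n_g = network.A.shape
    edge = network.A.astype(bool)

    # background: sub-threshold M, non-significant p
    M = rng.normal(0.0, 0.25 * m_min, size=(n_d, n_g))
    np.clip(M, -0.95 * m_min, 0.95 * m_min, out=M)
    p_low = np.nextafter(thr.p_max, 1.0)
    P = rng.uniform(p_low, 1.0, size=(n_d, n_g))

    # planted non-self edges: clearly significant effects
    nonself_edge = edge.copy()
    self_idx = [
        (i, network.gene_position(d))
        for i, d in enumerate(network.deletions)
        if network.has_self_cell(d)
    ]
    for i, j in self_idx:
        nonself_edge[i, j] = False
    n_edges = int(nonself_edge.sum())
    margin = 1.05 * m_min
    magnitude = margin + np.abs(
        rng.normal(max(spec.edge_effect_mean - margin, 0.0), spec.edge_effect_sd, n_edges)
    )
    signs = np.where(rng.random(n_edges) < spec.edge_sign_negative_prob, -1.0, 1.0)
    M[nonself_edge] = signs * magnitude
    P[nonself_edge] = rng.uniform(0.0, thr.p_max, n_edges)

    # false negatives: push a fraction of true edges below threshold
    if spec.false_negative_rate > 0 and n_edges:
        drop = rng.random(n_edges) < spec.false_negative_rate
        target = np.flatnonzero(nonself_edge.ravel())[drop]
        P.ravel()[target] = rng.uniform(p_low, 1.0, target.size)

    # false positives: promote a fraction of non-edges
    non_edge = ~edge
    n_non = int(non_edge.sum())
    if spec.false_positive_rate > 0 and n_non:
        promote = rng.random(n_non) < spec.false_positive_rate
        target = np.flatnonzero(non_edge.ravel())[promote]
        fp_mag = margin + np.abs(rng.normal(0.0, spec.edge_effect_sd, target.size))
        fp_sign = np.where(rng.random(target.size) < 0.5, -1.0, 1.0)
        M.ravel()[target] = fp_sign * fp_mag
        P.ravel()[target] = rng.uniform(0.0, thr.p_max, target.size)

    # self effects: strong significant decrease, never an error
    for i, j in self_idx:
        M[i, j] = spec.self_effect_m
        P[i, j] = 1e-12

    strain_ids = [
        dialect.strain_header(d, dialect.default_media) for d in network.deletions
    ]
    strains = pd.DataFrame(
        {
            "strain_id": strain_ids,
            "deleted_gene": list(network.deletions),
            "media": dialect.default_media,
        }
    )
    index = pd.Index(strain_ids, name="strain_id")
    return ExpressionCompendium(
        strains=strains,
        M=pd.DataFrame(M, index=index, columns=network.genes),
        P=pd.DataFrame(P, index=index, columns=network.genes),
    )


def generate_fitness(
    network: PerturbationNetwork,
    spec: SyntheticSpec,
    rng: Optional[np.random.Generator] = None,
) -> FitnessTable:
    """Fitness anti-correlated with pleiotropy:
    w(d) = 1 + slope * log10(K_d + 1) + N(0, sd), K_d excluding the self edge."""
    rng = rng if rng is not None else _rng(spec, _ROLE_FITNESS)
    k = network.out_degree(include_self=False).to_numpy(dtype=float)
    noise = rng.normal(0.0, spec.fitness_noise_sd, size=k.size) if spec.fitness_noise_sd else 0.0
    values = 1.0 + spec.fitness_slope * np.log10(k + 1.0) + noise
    return FitnessTable(
        values=pd.Series(values, index=pd.Index(network.deletions, name="gene"))
    )


def fitness_noise_for_target_r2(
    outdegrees: np.ndarray, slope: float, target_r2: float
) -> float:
    """Noise sd such that the fitness-vs-log10(count) regression attains a
    given expected r-squared on this degree sample.

    The regression's predictor is log10(K) over K > 0 while the generative
    signal is slope * log10(K + 1); the sd solves
    r2 = cov(x, s)^2 / (var(x) * (var(s) + sd^2)) for that pairing.
    """
    if not (0 < target_r2 < 1):
        raise ConfigError("target_r2 must be in (0, 1)")
    k = np.asarray(outdegrees, dtype=float)
    k = k[k > 0]
    x = np.log10(k)
    s = slope * np.log10(k + 1.0)
    var_x = float(np.var(x))
    var_s = float(np.var(s))
    cov_xs = float(np.mean((x - x.mean()) * (s - s.mean())))
    sd2 = cov_xs**2 / (var_x * target_r2) - var_s
    if sd2 <= 0:
        raise ConfigError(
            f"target r2={target_r2} unattainable on this degree sample"
        )
    return math.sqrt(sd2)


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[PerturbationNetwork, ExpressionCompendium, FitnessTable]:
    """Network + compendium + fitness from one spec, bit-reproducible."""
    network = generate_planted_network(spec)
    compendium = generate_compendium(network, spec)
    fitness = generate_fitness(network, spec)
    logger.info(
        "synthetic dataset: %d genes, %d deletions, %d planted edges (seed=%d)",
        spec.n_genes, spec.n_deletions, network.n_edges, spec.seed,
    )
    return network, compendium, fitness
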