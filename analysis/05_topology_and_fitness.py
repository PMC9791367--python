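#!/usr/bin/env python
"""Check the scale-free topology and relate pleiotropy to deletion fitness.

Fits p(K) ~ K^-gamma to the out-degree distribution by least squares on
log-log scale, regresses competitive fitness on log10 pleiotropy across
all deletions, and compares the fitness cost (1 - fitness) of cis vs
trans deletions affecting the same focal gene, per pair and per focal
gene. Writes the fitness-cost tables.
"""

import argparse
from pathlib import Path

from pleionet.io import read_expression_compendium, read_fitness_table
from pleionet.network import Thresholds, build_adjacency, select_focal_genes
from pleionet.pleiotropy import pleiotropy_records
from pleionet.topology import (
    fit_powerlaw,
    fitness_cost_pairs,
    fitness_vs_pleiotropy_regression,
    outdegree_histogram,
    proportion_cis_cost_greater,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument(
        "--expression", type=Path, default=Path("results/synthetic/expression.tsv")
    )
    parser.add_argument(
        "--fitness", type=Path, default=Path("results/synthetic/fitness.tsv")
    )
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    compendium = read_expression_compendium(args.expression, drop_nonstandard_media=True)
    network = select_focal_genes(build_adjacency(compendium, Thresholds()), compendium)

    fit = fit_powerlaw(outdegree_histogram(network))
    print(
        f"out-degree power law: gamma = {fit.gamma:.3f}, r2 = {fit.r_squared:.3f} "
        f"over {fit.n_points} distinct degrees"
    )

    fitness = read_fitness_table(args.fitness)
    records = pleiotropy_records(network, genes=network.deletions)
    slope, intercept, r2, p = fitness_vs_pleiotropy_regression(records, fitness)
    print(
        f"fitness ~ log10(DE-gene count): slope = {slope:.4g}, r2 = {r2:.3f}, "
        f"p = {p:.3g}"
    )

    comparison = fitness_cost_pairs(network, fitness)
    args.outdir.mkdir(parents=True, exist_ok=True)
    comparison.pairs.to_csv(
        args.outdir / "fitness_cost_pairs.tsv", sep="\t", index=False,
        float_format="%.10g",
    )
    comparison.per_focal.to_csv(
        args.outdir / "fitness_cost_per_focal.tsv", sep="\t", index=False,
        float_format="%.10g",
    )
    for mode in ("per_pair", "per_focal"):
        n, d, prop = proportion_cis_cost_greater(comparison, mode)
        print(f"cis cost greater ({mode}): {n}/{d} ({100 * prop:.1f}%)")


if __name__ == "__main__":
    main()
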