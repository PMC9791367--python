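"""End-to-end orchestration: data in (files or synthetic spec), network
build, pleiotropy tables, cis/trans comparison, permutation nulls,
topology and fitness analyses, all written to an output directory.

Outputs are deterministic given the config (fixed float formatting, sorted
JSON keys, no timestamps), so a re-run with the same seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .comparison import (
    MEASURES,
    focal_summaries,
    one_sided_difference_test,
    proportion_cis_greater,
    welch_difference_test,
)
from .errors import ConfigError, PipelineStageError
from .io import (
    ExpressionCompendium,
    ExpressionDialect,
    FitnessTable,
    read_expression_compendium,
    read_fitness_table,
)
from .network import Thresholds, build_adjacency, select_focal_genes, write_network
from .permutation import SCHEMES, permutation_study
from .pleiotropy import (
    cis_trans_pairs,
    pairs_to_frame,
    pleiotropy_records,
    records_to_frame,
)
from .simulate import SyntheticSpec, generate_dataset
from .topology import (
    fit_powerlaw,
    fitness_cost_pairs,
    fitness_vs_pleiotropy_regression,
    outdegree_histogram,
    proportion_cis_cost_greater,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    expression_path: Optional[Path] = None
    transformed_expression_path: Optional[Path] = None
    fitness_path: Optional[Path] = None
    synthetic: Optional[SyntheticSpec] = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    measures: Sequence[str] = MEASURES
    schemes: Sequence[str] = SCHEMES
    n_permutations: int = 20
    seed: int = 0
    outdir: Path = Path("results")
    drop_nonstandard_media: bool = True
    dialect: Optional[ExpressionDialect] = None

    def __post_init__(self):
        if (self.expression_path is None) == (self.synthetic is None):
            raise ConfigError(
                "provide exactly one of expression_path or a synthetic spec"
            )
        unknown = set(self.measures) - set(MEASURES)
        if unknown:
            raise ConfigError(f"unknown measures {sorted(unknown)}")
        unknown = set(self.schemes) - set(SCHEMES)
        if unknown:
            raise ConfigError(f"unknown schemes {sorted(unknown)}")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(
                    stage=name, code=type(exc).__name__, message=str(exc)
                ) from exc
        return wrapped
    return deco


@_stage("load")
def _load(config: PipelineConfig):
    if config.synthetic is not None:
        network, compendium, fitness = generate_dataset(config.synthetic)
        if config.thresholds != network.thresholds:
            network = build_adjacency(
                compendium, config.thresholds, provenance=network.provenance
            )
        transformed = None
    else:
        compendium = read_expression_compendium(
            config.expression_path,
            dialect=config.dialect,
            drop_nonstandard_media=config.drop_nonstandard_media,
        )
        network = build_adjacency(
            compendium, config.thresholds, provenance=str(config.expression_path)
        )
        fitness = (
            read_fitness_table(config.fitness_path)
            if config.fitness_path is not None
            else None
        )
        transformed = (
            read_expression_compendium(
                config.transformed_expression_path,
                dialect=config.dialect,
                drop_nonstandard_media=config.drop_nonstandard_media,
            )
            if config.transformed_expression_path is not None
            else None
        )
    return network, compendium, fitness, transformed


def _comparison_block(pairs, records, measures) -> dict:
    block = {}
    for measure in measures:
        summaries = focal_summaries(pairs, records, measure=measure)
        diffs = [s.difference for s in summaries]
        t, df, p = one_sided_difference_test(diffs)
        nf, df_, prop_f = proportion_cis_greater(summaries, mode="per_focal")
        np_, dp, prop_p = proportion_cis_greater(
            pairs, mode="per_pair", measure=measure, records=records
        )
        welch_t, welch_df, welch_p = welch_difference_test(
            [s.cis_value for s in summaries],
            [s.median_trans_value for s in summaries],
        )
        block[measure] = {
            "n_focal": len(summaries),
            "median_difference": float(np.median(diffs)),
            "mean_difference": float(np.mean(diffs)),
            "t_statistic": t,
            "t_df": df,
            "t_p_upper": p,
            "per_focal_cis_greater": [nf, df_, prop_f],
            "per_pair_cis_greater": [np_, dp, prop_p],
            "welch_cis_vs_median_trans": [welch_t, welch_df, welch_p],
        }
    return block


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle under ``outdir``.

    Returns the JSON-serialisable report that is also written to
    ``report.json``. Any stage failure aborts with the stage name and a
    machine-readable error code.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": config.thresholds.to_dict(),
    }
    if config.synthetic is not None:
        report["synthetic_spec"] = config.synthetic.to_dict()

    network, compendium, fitness, transformed = _load(config)

    @_stage("network")
    def stage_network():
        net = select_focal_genes(network, compendium)
        write_network(net, outdir / "perturbation")
        report["network"] = {
            "n_deletions": len(net.deletions),
            "n_genes": len(net.genes),
            "n_edges": net.n_edges,
            "filter_counts": net.filter_counts,
        }
        return net

    network_f = stage_network()

    @_stage("pleiotropy")
    def stage_pleiotropy():
        records = pleiotropy_records(network_f, compendium)
        pairs = cis_trans_pairs(network_f, compendium)
        records_to_frame(records).to_csv(
            outdir / "pleiotropy_records.tsv", sep="\t", index=False,
            float_format="%.10g",
        )
        pairs_to_frame(pairs).to_csv(
            outdir / "cis_trans_pairs.tsv", sep="\t", index=False,
            float_format="%.10g",
        )
        n_decreasing = sum(1 for p in pairs if p.focal_effect_sign == "decrease")
        report["pairs"] = {
            "n_pairs": len(pairs),
            "n_decreasing_pairs": n_decreasing,
        }
        return records, pairs

    records, pairs = stage_pleiotropy()

    @_stage("comparison")
    def stage_comparison():
        report["comparison"] = _comparison_block(pairs, records, config.measures)
        decreasing = [p for p in pairs if p.focal_effect_sign == "decrease"]
        if decreasing:
            n, d, prop = proportion_cis_greater(
                decreasing, mode="per_pair", measure="parallel_count",
                records=records,
            )
            report["comparison"]["decreasing_pairs_parallel_cis_greater"] = [n, d, prop]
        for measure in config.measures:
            frame = pd.DataFrame(
                [
                    {
                        "focal": s.focal,
                        "cis_value": s.cis_value,
                        "median_trans_value": s.median_trans_value,
                        "difference": s.difference,
                        "n_trans": s.n_trans,
                    }
                    for s in focal_summaries(pairs, records, measure=measure)
                ]
            )
            frame.to_csv(
                outdir / f"focal_summaries_{measure}.tsv", sep="\t",
                index=False, float_format="%.10g",
            )

    stage_comparison()

    @_stage("permutation")
    def stage_permutation():
        rows = []
        summary = {}
        for scheme in config.schemes:
            result = permutation_study(
                network_f, scheme, config.n_permutations, seed=config.seed
            )
            meds = np.array(result.per_permutation_median_difference)
            summary[scheme] = {
                "n_permutations": result.n_permutations,
                "min_median": float(meds.min()),
                "max_median": float(meds.max()),
                "mean_median": float(meds.mean()),
                "fraction_positive": float((meds > 0).mean()),
            }
            for rep, (med, nf) in enumerate(
                zip(result.per_permutation_median_difference,
                    result.per_permutation_focal_count)
            ):
                rows.append(
                    {"scheme": scheme, "replicate": rep,
                     "median_difference": med, "n_focal": nf}
                )
        pd.DataFrame(rows).to_csv(
            outdir / "permutations.tsv", sep="\t", index=False,
            float_format="%.10g",
        )
        report["permutation"] = summary

    stage_permutation()

    @_stage("topology")
    def stage_topology():
        hist = outdegree_histogram(network_f)
        fit = fit_powerlaw(hist)
        report["powerlaw"] = {
            "gamma": fit.gamma,
            "r_squared": fit.r_squared,
            "n_points": fit.n_points,
        }

    stage_topology()

    if fitness is not None:

        @_stage("fitness")
        def stage_fitness():
            # regression over every deletion with fitness data, not only
            # focal genes (counts suffice; the distance is not used)
            all_records = pleiotropy_records(
                network_f, genes=network_f.deletions
            )
            slope, intercept, r2, p = fitness_vs_pleiotropy_regression(
                all_records, fitness
            )
            comparison = fitness_cost_pairs(network_f, fitness)
            comparison.pairs.to_csv(
                outdir / "fitness_cost_pairs.tsv", sep="\t", index=False,
                float_format="%.10g",
            )
            comparison.per_focal.to_csv(
                outdir / "fitness_cost_per_focal.tsv", sep="\t", index=False,
                float_format="%.10g",
            )
            n_pp, d_pp, prop_pp = proportion_cis_cost_greater(comparison, "per_pair")
            n_pf, d_pf, prop_pf = proportion_cis_cost_greater(comparison, "per_focal")
            report["fitness"] = {
                "regression": {
                    "slope": slope, "intercept": intercept,
                    "r_squared": r2, "p_value": p,
                },
                "n_focal_with_fitness": int(len(comparison.per_focal)),
                "per_pair_cis_cost_greater": [n_pp, d_pp, prop_pp],
                "per_focal_cis_cost_greater": [n_pf, d_pf, prop_pf],
            }

        stage_fitness()

    if transformed is not None:

        @_stage("transformed")
        def stage_transformed():
            t_records = pleiotropy_records(network_f, transformed)
            t_pairs = cis_trans_pairs(network_f, transformed)
            report["transformed_euclidean"] = _comparison_block(
                t_pairs, t_records, ["euclidean"]
            )["euclidean"]

        stage_transformed()

    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    log_lines = [
        f"pleionet {__version__}",
        f"seed {config.seed}",
        f"thresholds {config.thresholds.to_dict()}",
        f"filter_counts {report['network']['filter_counts']}",
        f"n_edges {report['network']['n_edges']}",
    ]
    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return report


def threshold_sweep(
    compendium: ExpressionCompendium,
    fold_changes: Sequence[float],
    p_maxes: Sequence[float],
) -> pd.DataFrame:
    """Robustness grid: edge counts, focal counts and the per-focal
    cis-greater proportion across cutoff combinations.

    Relaxing either cutoff never removes an edge, so edge counts are
    monotone non-increasing in fold_change_min and non-decreasing in p_max.
    """
    rows = []
    for fc in fold_changes:
        for p_max in p_maxes:
            thr = Thresholds(fold_change_min=fc, p_max=p_max)
            net = select_focal_genes(build_adjacency(compendium, thr), compendium)
            row = {
                "fold_change_min": fc,
                "p_max": p_max,
                "n_edges": net.n_edges,
                "n_focal": len(net.focal_genes),
            }
            if net.focal_genes:
                records = pleiotropy_records(net, compendium)
                pairs = cis_trans_pairs(net, compendium)
                if pairs:
                    summaries = focal_summaries(pairs, records, measure="count")
                    n, d, prop = proportion_cis_greater(summaries, mode="per_focal")
                    row["per_focal_cis_greater"] = prop
            rows.append(row)
    return pd.DataFrame(rows)
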