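#!/usr/bin/env python
"""Threshold the expression compendium into the perturbation network and
apply the focal-gene filters.

An edge runs from a deleted gene to every gene with |M| >= log2(1.7) and
adjusted p <= 0.05 in that deletion strain. Focal genes are deletions that
are measured on the array, knock their own expression down significantly,
and are perturbed by at least one other deletion. Writes the edge list and
a JSON sidecar with thresholds and per-filter removal counts.
"""

import argparse
from pathlib import Path

from pleionet.io import read_expression_compendium
from pleionet.network import Thresholds, build_adjacency, select_focal_genes, write_network


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument(
        "--expression", type=Path, default=Path("results/synthetic/expression.tsv")
    )
    parser.add_argument("--fc", type=float, default=1.7)
    parser.add_argument("--pmax", type=float, default=0.05)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    compendium = read_expression_compendium(
        args.expression, drop_nonstandard_media=True
    )
    network = build_adjacency(
        compendium,
        Thresholds(fold_change_min=args.fc, p_max=args.pmax),
        provenance=str(args.expression),
    )
    network = select_focal_genes(network, compendium)
    args.outdir.mkdir(parents=True, exist_ok=True)
    edges_path, meta_path = write_network(network, args.outdir / "perturbation")
    counts = network.filter_counts
    print(
        f"{network.n_edges} edges over {len(network.deletions)} deletions x "
        f"{len(network.genes)} genes"
    )
    print(
        f"focal filters removed {counts['no_self_decrease']} (no self-decrease), "
        f"{counts['not_measured']} (not on array), "
        f"{counts['no_trans_regulator']} (no trans-regulator); "
        f"{counts['focal']} focal genes remain"
    )
    print(f"wrote {edges_path} and {meta_path}")


if __name__ == "__main__":
    main()
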