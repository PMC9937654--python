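#!/usr/bin/env python
"""Three-bait overlap and ontology-category structure of the control hits.

Builds the 7-region Venn partition of the 2.0-fold hit set (and the 1.5/2.5
alternates), computes the fraction of hits carrying synaptic annotations,
exports the network node list (hits with synaptic annotation), and writes
per-category mean log2 fold changes. Runs on the outputs of scripts 01/02.
"""

from pathlib import Path

import pandas as pd

from ibioid.enrichment import call_hits, read_enrichment
from ibioid.io import write_annotation_table
from ibioid.overlap import (
    annotate_hits,
    category_mean_log2fc,
    network_node_set,
    venn_partition,
    write_node_list,
)
from ibioid.simulate import synthetic_annotation

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out = ROOT / "overlap"
    out.mkdir(parents=True, exist_ok=True)

    result = read_enrichment(ROOT / "enrichment" / "enrichment_CONTROL.tsv")
    truth = pd.read_csv(ROOT / "datasets" / "truth_CONTROL.tsv", sep="\t")
    ann = synthetic_annotation(truth)
    write_annotation_table(ann, out / "annotation.tsv")
    gene_of = result.gene_of().to_dict()

    for t in (1.5, 2.0, 2.5):
        hits, union = call_hits(result, t)
        part = venn_partition(hits, result)
        part.write(out / f"venn_CONTROL_{t:g}.json")
        print(
            f"threshold {t}: union {part.n_union()}, "
            f"multi-bait {part.n_multi_bait()}, all three {part.n_all_three()}"
        )
        subset, n, frac = annotate_hits(union, ann, ("synapse",), gene_of)
        print(f"  synaptic annotation: {n} of {part.n_union()} hits ({frac:.0%})")

    hits, union = call_hits(result, 2.0)
    nodes = network_node_set(union, ann, gene_of)
    write_node_list(nodes, out / "nodes_CONTROL.txt")
    print(f"network node list (hits with synaptic annotation): {len(nodes)} genes")

    for level in (("synapse",), ("synapse", "presynapse"), ("synapse", "presynapse", "active zone")):
        rows = category_mean_log2fc({"CONTROL": result}, ann, level)
        name = "_".join(level).replace(" ", "-")
        rows.to_csv(out / f"category_{name}.tsv", sep="\t", index=False, float_format="%.6g")
        pretty = ", ".join(
            f"{r.bait} {r.mean_log2fc:+.2f}±{r.sem:.2f} (n={r.n})" for r in rows.itertuples()
        )
        print(f"mean log2FC at {'/'.join(level)}: {pretty}")


if __name__ == "__main__":
    main()
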