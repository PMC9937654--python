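"""End-to-end analysis runner, run manifest, and toy fixture generation.

`run_full_analysis` ties the stages together for one or more genotypes:
contaminant filtering → enrichment → hit calling at each threshold → Venn
partitioning → (optional) annotation summaries and panel/node exports. The
output directory receives deterministic files plus a JSON manifest with
sha256 checksums and a JSON-lines run log, so a run is reproducible and
auditable down to each filtered record and imputed session mean.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .io import (
    read_annotation_table,
    read_count_table,
    read_gene_list,
    write_json,
)
from .enrichment import (
    DEFAULT_THRESHOLDS,
    call_hits,
    filter_contaminants,
    run_enrichment,
    summarize,
    write_enrichment,
)
from .overlap import (
    category_mean_log2fc,
    network_node_set,
    panel_report,
    venn_partition,
    write_node_list,
)


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    counts: str
    out_dir: str
    mito: str | None = None
    contaminants: str | None = None
    annotation: str | None = None
    panel: str | None = None
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    genotypes: tuple[str, ...] = ("CONTROL",)
    keep_mito: bool = False
    annotation_level: tuple[str, ...] = ("synapse",)
    seed: int = 0

    def __post_init__(self) -> None:
        ts = tuple(float(t) for t in self.thresholds)
        if sorted(set(ts)) != list(ts):
            raise ValueError("thresholds must be sorted ascending and distinct")
        self.thresholds = ts

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("thresholds", "genotypes", "annotation_level"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.jsonl"
    log_fh = open(log_path, "w")

    def log(stage: str, **fields) -> None:
        rec = {"stage": stage, **fields}
        log_fh.write(json.dumps(rec, sort_keys=True, default=str) + "\n")

    log("start", version=__version__, config=vars(config), time=time.strftime("%F %T"))

    table = read_count_table(config.counts)
    log("read_counts", n_records=len(table), genotypes=table.genotypes())

    mito = read_gene_list(config.mito, "mito") if config.mito else None
    contaminants = (
        read_gene_list(config.contaminants, "contaminants")
        if config.contaminants
        else None
    )
    n_before = len(table)
    table = filter_contaminants(table, mito, contaminants, keep_mito=config.keep_mito)
    log("filter", n_removed_records=n_before - len(table), keep_mito=config.keep_mito)

    ann = read_annotation_table(config.annotation) if config.annotation else None
    panel = read_gene_list(config.panel, "panel") if config.panel else None

    written: list[Path] = []
    results = {}
    for genotype in config.genotypes:
        result = run_enrichment(table, genotype=genotype, thresholds=config.thresholds)
        results[genotype] = result
        log("enrichment", genotype=genotype, **result.provenance)

        p = out / f"enrichment_{genotype}.tsv"
        write_enrichment(result, p)
        written.append(p)

        summary = summarize(result)
        p = out / f"summary_{genotype}.tsv"
        summary.to_csv(p, sep="\t", index=False)
        written.append(p)

        for t in config.thresholds:
            hits, union = call_hits(result, t)
            part = venn_partition(hits, result)
            p = out / f"venn_{genotype}_{t:g}.json"
            part.write(p)
            written.append(p)
            log(
                "venn",
                genotype=genotype,
                threshold=t,
                union=part.n_union(),
                multi_bait=part.n_multi_bait(),
                all_three=part.n_all_three(),
            )
            if ann is not None and t == 2.0:
                nodes = network_node_set(
                    union, ann, result.gene_of().to_dict(), config.annotation_level
                )
                p = out / f"nodes_{genotype}.txt"
                write_node_list(nodes, p)
                written.append(p)
                log("nodes", genotype=genotype, n=len(nodes))

    if ann is not None:
        cats = category_mean_log2fc(results, ann, config.annotation_level)
        p = out / "category_summary.tsv"
        cats.to_csv(p, sep="\t", index=False, float_format="%.10g")
        written.append(p)
        log("categories", level="/".join(config.annotation_level), n_rows=len(cats))

    if panel is not None:
        rep = panel_report(results, panel)
        p = out / "panel_report.tsv"
        rep.to_csv(p, sep="\t", index=False, float_format="%.10g")
        written.append(p)
        log("panel", n_genes=len(panel))

    log_fh.close()
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: list(v) if isinstance(v, tuple) else v for k, v in vars(config).items()},
        "files": {p.name: _sha256(p) for p in sorted(written)},
    }
    write_json(manifest, out / "manifest.json")
    return manifest


def make_fixture_suite(out_dir: str | Path, seed: int = 1) -> dict[str, Path]:
    """Write a small, deterministic fixture set exercising every stage.

    The toy count table is constructed so that exactly three proteins clear
    the 2.0-fold threshold (union over baits), alongside one mitochondrial
    and one hard-contaminant record, a toy annotation table, a removal list,
    a panel list, and one synthetic 3-channel TIFF.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []

    def add(protein, gene, bait, counts_by_session):
        for sess, counts in counts_by_session.items():
            for rep_offset, c in enumerate(counts):
                rows.append(
                    {
                        "protein_id": protein,
                        "gene_symbol": gene,
                        "bait": bait,
                        "genotype": "CONTROL",
                        "session": sess,
                        "repeat": 2 * (sess - 1) + rep_offset + 1,
                        "peptide_count": c,
                    }
                )

    # three planted hits (FC >= 2 in at least one bait), two background
    # proteins, one mito protein and one contaminant
    for prot, gene, bait_counts in [
        ("HIT1", "AAA1", {"RIM_PPCP": (8, 8), "ELKS2B": (2, 2), "CAVB4": (2, 2), "TDTOMATO": (2, 2)}),
        ("HIT2", "BBB2", {"RIM_PPCP": (2, 2), "ELKS2B": (10, 10), "CAVB4": (2, 2), "TDTOMATO": (2, 2)}),
        ("HIT3", "CCC3", {"RIM_PPCP": (6, 6), "ELKS2B": (6, 6), "CAVB4": (6, 6), "TDTOMATO": (2, 2)}),
        ("BG1", "DDD4", {"RIM_PPCP": (3, 3), "ELKS2B": (3, 3), "CAVB4": (3, 3), "TDTOMATO": (3, 3)}),
        ("BG2", "EEE5", {"RIM_PPCP": (1, 1), "ELKS2B": (1, 1), "CAVB4": (1, 1), "TDTOMATO": (2, 2)}),
        ("MITO1", "MTX1", {"RIM_PPCP": (5, 5), "ELKS2B": (5, 5), "CAVB4": (5, 5), "TDTOMATO": (1, 1)}),
        ("CONT1", "PC", {"RIM_PPCP": (9, 9), "ELKS2B": (9, 9), "CAVB4": (9, 9), "TDTOMATO": (9, 9)}),
    ]:
        for bait, counts in bait_counts.items():
            add(prot, gene, bait, {1: counts, 2: counts})

    counts_path = out / "toy_counts.tsv"
    pd.DataFrame(rows).to_csv(counts_path, sep="\t", index=False)

    mito_path = out / "toy_mito.txt"
    mito_path.write_text("MTX1\n")
    cont_path = out / "toy_contaminants.txt"
    cont_path.write_text("PC\nPCCA\nNEUTRAVIDIN\nIGG\n")
    panel_path = out / "toy_panel.txt"
    panel_path.write_text("AAA1\nEEE5\nABSENT9\n")
    ann_path = out / "toy_annotation.tsv"
    ann_path.write_text(
        "gene_symbol\tcategory_path\n"
        "AAA1\tsynapse/presynapse/active zone\n"
        "BBB2\tsynapse/presynapse\n"
        "CCC3\tsynapse/postsynapse\n"
        "DDD4\tsynapse\n"
    )

    from .imaging import generate_synaptosome_image
    import tifffile

    image, _ = generate_synaptosome_image(
        n_particles=30, shape=(128, 128), seed=seed, noise_sd=1.0
    )
    import numpy as np

    stack = np.stack([image.channels[c] for c in ("TH", "BASSOON", "TARGET")])
    tiff_path = out / "toy_image.tif"
    tifffile.imwrite(tiff_path, stack.astype("float32"), photometric="minisblack")

    return {
        "counts": counts_path,
        "mito": mito_path,
        "contaminants": cont_path,
        "panel": panel_path,
        "annotation": ann_path,
        "image": tiff_path,
    }
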