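"""Multi-bait overlap, ontology-category summaries and gene-panel reports.

Hit proteins called per bait are partitioned into the seven exclusive
regions of a three-set Venn diagram; annotated fractions and per-category
mean log2 fold changes summarize what kinds of proteins the baits enrich,
and control-vs-mutant overlap fractions quantify how a genotype reshapes
the proteome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    BAITS,
    BAIT_GENES,
    AnnotationTable,
    GeneList,
    ValidationError,
    normalize_symbol,
    write_json,
)
from .enrichment import EnrichmentResult


def _region_key(baits: Iterable[str]) -> str:
    """Canonical region name: member baits joined '+' in fixed bait order."""
    members = [b for b in BAITS if b in set(baits)]
    if not members:
        raise ValidationError("a Venn region needs at least one bait")
    return "+".join(members)


ALL_REGIONS = tuple(
    _region_key(c)
    for c in (
        ("RIM_PPCP",),
        ("ELKS2B",),
        ("CAVB4",),
        ("RIM_PPCP", "ELKS2B"),
        ("RIM_PPCP", "CAVB4"),
        ("ELKS2B", "CAVB4"),
        ("RIM_PPCP", "ELKS2B", "CAVB4"),
    )
)


@dataclass
class VennPartition:
    """Exclusive 7-region partition of the union hit set.

    ``max_fc``/``argmax_bait`` give, per protein, the largest final FC over
    the baits in which it is a hit and the bait achieving it (the quantity
    the study maps to circle size). Bait-encoding genes are flagged, not
    removed.
    """

    regions: dict[str, set[str]]
    max_fc: dict[str, float]
    argmax_bait: dict[str, str]
    bait_gene_proteins: set[str] = field(default_factory=set)

    def counts(self) -> dict[str, int]:
        return {r: len(m) for r, m in self.regions.items()}

    @property
    def union(self) -> set[str]:
        out: set[str] = set()
        for m in self.regions.values():
            out |= m
        return out

    def n_union(self) -> int:
        return len(self.union)

    def n_multi_bait(self) -> int:
        return sum(len(m) for r, m in self.regions.items() if "+" in r)

    def n_all_three(self) -> int:
        return len(self.regions.get(_region_key(BAITS), set()))

    def to_dict(self) -> dict:
        return {
            "regions": {r: sorted(m) for r, m in self.regions.items()},
            "counts": self.counts(),
            "union": self.n_union(),
            "multi_bait": self.n_multi_bait(),
            "all_three": self.n_all_three(),
            "max_fc": {p: self.max_fc[p] for p in sorted(self.max_fc)},
            "argmax_bait": {p: self.argmax_bait[p] for p in sorted(self.argmax_bait)},
            "bait_gene_proteins": sorted(self.bait_gene_proteins),
        }

    def write(self, path: str | Path) -> None:
        write_json(self.to_dict(), path)


def venn_partition(
    hits: Mapping[str, set[str]], result: EnrichmentResult
) -> VennPartition:
    """Partition per-bait hit sets into exclusive Venn regions.

    ``hits`` must come from a single genotype and threshold (as produced by
    :func:`ibioid.enrichment.call_hits`).
    """
    union: set[str] = set()
    for b in BAITS:
        union |= set(hits.get(b, set()))
    regions: dict[str, set[str]] = {r: set() for r in ALL_REGIONS}
    for p in union:
        members = [b for b in BAITS if p in hits.get(b, set())]
        regions[_region_key(members)].add(p)

    fc = result.df.set_index(["protein_id", "bait"])["mean_fc"]
    max_fc: dict[str, float] = {}
    argmax: dict[str, str] = {}
    for p in union:
        best_bait, best = None, -np.inf
        for b in BAITS:
            if p in hits.get(b, set()):
                v = float(fc.get((p, b), -np.inf))
                if v > best:
                    best, best_bait = v, b
        max_fc[p] = best
        argmax[p] = best_bait

    genes = result.gene_of()
    bait_gene_syms = set(BAIT_GENES.values())
    bait_gene_proteins = {
        p for p in union if genes.get(p, "") in bait_gene_syms
    }
    return VennPartition(regions, max_fc, argmax, bait_gene_proteins)


def annotate_hits(
    hits: set[str],
    ann: AnnotationTable,
    level: Sequence[str],
    gene_of: Mapping[str, str],
    exclude_bait_genes: bool = True,
) -> tuple[set[str], int, float]:
    """Subset of hits annotated at/below a category level, with count and
    fraction of the (bait-gene-excluded) hit set."""
    level_t = tuple(level)
    known = ann.paths()
    if level_t not in known:
        raise ValidationError(
            f"unknown category level {'/'.join(level_t)!r}; known levels: "
            f"{sorted('/'.join(p) for p in known)}"
        )
    pool = set(hits)
    if exclude_bait_genes:
        bait_syms = set(BAIT_GENES.values())
        pool = {p for p in pool if gene_of.get(p, "") not in bait_syms}
    subset = {p for p in pool if ann.annotated_at(gene_of.get(p, ""), level_t)}
    frac = len(subset) / len(pool) if pool else 0.0
    return subset, len(subset), frac


def category_mean_log2fc(
    results: Mapping[str, EnrichmentResult],
    ann: AnnotationTable,
    level: Sequence[str],
    exclude_self_bait: bool = True,
) -> pd.DataFrame:
    """Mean ± SEM of log2 FC over annotated detected proteins.

    One row per (genotype, bait). All detected annotated proteins enter the
    mean (not only hits). With ``exclude_self_bait``, each bait's own gene is
    dropped from that bait's mean only (it is retained for the other baits).
    """
    level_t = tuple(level)
    rows = []
    for genotype, result in results.items():
        genes = result.gene_of()
        annotated = {
            p for p in result.proteins() if ann.annotated_at(genes.get(p, ""), level_t)
        }
        for bait in BAITS:
            sub = result.bait_frame(bait)
            sub = sub[sub["protein_id"].isin(annotated)]
            if exclude_self_bait:
                sub = sub[sub["gene_symbol"] != BAIT_GENES[bait]]
            vals = sub["log2_fc"].to_numpy()
            n = len(vals)
            rows.append(
                {
                    "genotype": genotype,
                    "bait": bait,
                    "category": "/".join(level_t),
                    "mean_log2fc": float(np.mean(vals)) if n else np.nan,
                    "sem": float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
                    "n": n,
                }
            )
    return pd.DataFrame(rows)


def category_observations(
    results: Mapping[str, EnrichmentResult],
    ann: AnnotationTable,
    level: Sequence[str],
    exclude_self_bait: bool = True,
) -> pd.DataFrame:
    """Per-protein log2 FC observations (value, genotype, bait) for a
    category level, as input to the two-way ANOVA."""
    level_t = tuple(level)
    rows = []
    for genotype, result in results.items():
        genes = result.gene_of()
        for bait in BAITS:
            sub = result.bait_frame(bait)
            if exclude_self_bait:
                sub = sub[sub["gene_symbol"] != BAIT_GENES[bait]]
            mask = [ann.annotated_at(g, level_t) for g in sub["gene_symbol"]]
            for _, r in sub[np.asarray(mask, dtype=bool)].iterrows():
                rows.append(
                    {
                        "value": float(r["log2_fc"]),
                        "genotype": genotype,
                        "bait": bait,
                        "protein_id": r["protein_id"],
                    }
                )
    return pd.DataFrame(rows)


def overlap_fraction(control_hits: set[str], mutant_hits: set[str]) -> float:
    """|control ∩ mutant| / |control| — the fraction of control hits that
    survive in a mutant dataset."""
    if not control_hits:
        raise ValidationError("control hit set is empty")
    return len(set(control_hits) & set(mutant_hits)) / len(set(control_hits))


def single_bait_fraction(partition: VennPartition, bait: str) -> tuple[int, float]:
    """Size of the bait-only Venn region and its share of the union."""
    only = partition.regions.get(_region_key([bait]), set())
    union = partition.n_union()
    return len(only), (len(only) / union if union else 0.0)


def panel_report(
    results: Mapping[str, EnrichmentResult],
    panel: GeneList,
    threshold: float = 2.0,
) -> pd.DataFrame:
    """Per-gene enrichment across baits and genotypes for a curated panel.

    Genes absent from a dataset are reported with ``detected=False`` and no
    FC rather than an imputed value.
    """
    rows = []
    for genotype, result in results.items():
        by_gene = result.df.set_index(["gene_symbol", "bait"])
        for gene in sorted(panel.symbols):
            for bait in BAITS:
                key = (gene, bait)
                if key in by_gene.index:
                    rec = by_gene.loc[key]
                    if isinstance(rec, pd.DataFrame):
                        rec = rec.iloc[0]
                    fc = float(rec["mean_fc"])
                    rows.append(
                        {
                            "gene_symbol": gene,
                            "genotype": genotype,
                            "bait": bait,
                            "detected": True,
                            "mean_fc": fc,
                            "log2_fc": float(rec["log2_fc"]),
                            "hit": bool(fc >= threshold),
                        }
                    )
                else:
                    rows.append(
                        {
                            "gene_symbol": gene,
                            "genotype": genotype,
                            "bait": bait,
                            "detected": False,
                            "mean_fc": np.nan,
                            "log2_fc": np.nan,
                            "hit": False,
                        }
                    )
    return pd.DataFrame(rows)


def network_node_set(
    hits: set[str],
    ann: AnnotationTable,
    gene_of: Mapping[str, str],
    level: Sequence[str] = ("synapse",),
) -> set[str]:
    """Gene symbols of hits with a synaptic annotation, for export to an
    external protein-interaction network tool (edges are out of scope)."""
    subset, _, _ = annotate_hits(hits, ann, level, gene_of, exclude_bait_genes=True)
    return {gene_of[p] for p in subset}


def write_node_list(nodes: set[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(nodes)) + "\n")
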