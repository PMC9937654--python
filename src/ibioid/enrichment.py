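"""Spectral-count enrichment over the soluble-axon reference.

The enrichment statistic is computed exactly as in the source study design:

1. Within each mass-spectrometry session, peptide counts are averaged over
   the session's repeats (a protein absent from a condition counts as 0).
2. A session average of exactly 0 is imputed to 0.5 peptides, so every
   ratio and logarithm is defined. A side effect of the 0.5 floor is that a
   single singleton detection, e.g. counts (1, 0), also averages to 0.5 —
   a protein must be seen more than once with a single peptide to rise
   above the floor.
3. The session fold change (FC) of a protein in a bait condition is its
   session-average count divided by the session-average count of the same
   protein in the BirA-tdTomato reference.
4. Session FCs are averaged (unweighted) across sessions into the final FC;
   with a single session the session FC is the final FC.
5. log2(FC) is taken after the averaging; proteins with final FC ≥ t are
   "hits" at threshold t (inclusive; default thresholds 1.5, 2.0, 2.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    BAITS,
    REFERENCE,
    CountTable,
    GeneList,
    ValidationError,
    logger,
)

PSEUDOCOUNT = 0.5
DEFAULT_THRESHOLDS = (1.5, 2.0, 2.5)


def filter_contaminants(
    table: CountTable,
    mito: GeneList | None = None,
    contaminants: GeneList | None = None,
    keep_mito: bool = False,
) -> CountTable:
    """Drop records whose gene symbol is on a removal list.

    Mitochondrial proteins (MitoCarta-style list) are a stereotypical BioID
    background and are removed unless ``keep_mito``; hard contaminants
    (endogenously biotinylated carboxylases PC/PCCA, neutravidin, IgG) are
    always removed. Both lists must be normalized with the same rule as the
    table's symbols.
    """
    df = table.df
    drop = pd.Series(False, index=df.index)
    removed: dict[str, int] = {}
    lists: list[GeneList] = []
    if contaminants is not None:
        lists.append(contaminants)
    if mito is not None and not keep_mito:
        lists.append(mito)
    for gl in lists:
        hit = df["gene_symbol"].isin(gl.symbols)
        for sym, n in df.loc[hit, "gene_symbol"].value_counts().items():
            removed[sym] = removed.get(sym, 0) + int(n)
        drop |= hit
    if removed:
        logger.info(
            "filter_contaminants removed %d records across %d symbols: %s",
            int(drop.sum()),
            len(removed),
            dict(sorted(removed.items())),
        )
    return CountTable(df.loc[~drop].reset_index(drop=True), require_reference=False)


def session_mean(counts: Sequence[float]) -> float:
    """Average peptide count over a session's repeats, with the 0.5 floor.

    Returns the arithmetic mean of the repeat counts; a mean of exactly zero
    is assigned the pseudocount 0.5.
    """
    counts = list(counts)
    if not counts:
        raise ValidationError("session_mean requires at least one repeat")
    m = float(np.mean(counts))
    return PSEUDOCOUNT if m == 0.0 else m


def session_fold_change(bait_mean: float, reference_mean: float) -> float:
    """Per-session FC: bait session mean over reference session mean."""
    if bait_mean <= 0 or reference_mean <= 0:
        raise ValidationError(
            "session means must be positive (imputation was skipped upstream): "
            f"bait={bait_mean}, reference={reference_mean}"
        )
    return bait_mean / reference_mean


def combine_sessions(session_fcs: Sequence[float]) -> float:
    """Final FC: unweighted mean of the session FCs (identity for one)."""
    fcs = list(session_fcs)
    if not fcs:
        raise ValidationError("combine_sessions requires at least one session FC")
    return float(np.mean(fcs))


@dataclass
class EnrichmentResult:
    """Per protein × bait enrichment for one genotype.

    ``df`` is tidy with one row per (protein, bait): columns ``protein_id,
    gene_symbol, bait, mean_fc, log2_fc, detected_in_bait`` plus one
    ``fc_session_<s>`` column per session. Only proteins detected (≥1
    peptide) in at least one of the four conditions are present.
    """

    genotype: str
    df: pd.DataFrame
    sessions: list[int]
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    provenance: dict = field(default_factory=dict)

    def session_fc_columns(self) -> list[str]:
        return [f"fc_session_{s}" for s in self.sessions]

    def proteins(self) -> list[str]:
        return sorted(set(self.df["protein_id"]))

    def bait_frame(self, bait: str) -> pd.DataFrame:
        return self.df[self.df["bait"] == bait]

    def gene_of(self) -> pd.Series:
        return self.df.drop_duplicates("protein_id").set_index("protein_id")["gene_symbol"]


def run_enrichment(
    table: CountTable,
    genotype: str = "CONTROL",
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    pseudocount: float = PSEUDOCOUNT,
) -> EnrichmentResult:
    """Compute session FCs, final FC and log2 FC for every detected protein.

    The protein universe is every protein with ≥1 peptide in ≥1 condition of
    the genotype; a protein absent from a (bait, session, repeat) cell is
    counted as zero there. The number of repeats in a session is taken from
    the distinct repeat identifiers observed in that (bait, session) block.
    """
    df = table.df[table.df["genotype"] == genotype]
    if df.empty:
        raise ValidationError(f"no records for genotype {genotype}")
    if REFERENCE not in set(df["bait"]):
        raise ValidationError(f"genotype {genotype} lacks the {REFERENCE} reference")

    detected = df[df["peptide_count"] > 0]
    proteins = sorted(set(detected["protein_id"]))
    gene_of = detected.drop_duplicates("protein_id").set_index("protein_id")["gene_symbol"]
    sessions = sorted(set(df["session"]))

    # repeats per (bait, session) block, from observed repeat identifiers
    n_repeats = (
        df.groupby(["bait", "session"])["repeat"].nunique().to_dict()
    )

    # session sums per protein × bait × session → session means with floor
    sums = (
        df.groupby(["protein_id", "bait", "session"])["peptide_count"]
        .sum()
        .unstack(["bait", "session"], fill_value=0)
    )
    sums = sums.reindex(proteins, fill_value=0)

    means: dict[tuple[str, int], pd.Series] = {}
    n_imputed = 0
    for bait_s in sums.columns:
        bait, sess = bait_s
        m = sums[bait_s] / n_repeats[(bait, sess)]
        n_imputed += int((m == 0.0).sum())
        means[(bait, sess)] = m.mask(m == 0.0, pseudocount)

    rows = []
    for bait in BAITS:
        if not any(b == bait for b, _ in means):
            continue
        fc_by_session = {}
        for sess in sessions:
            if (bait, sess) not in means or (REFERENCE, sess) not in means:
                continue
            fc_by_session[sess] = means[(bait, sess)] / means[(REFERENCE, sess)]
        if not fc_by_session:
            continue
        fc_frame = pd.DataFrame(fc_by_session)
        mean_fc = fc_frame.mean(axis=1)
        bait_total = sum(
            sums[(bait, s)] for s in sessions if (bait, s) in sums.columns
        )
        frame = pd.DataFrame(
            {
                "protein_id": proteins,
                "gene_symbol": gene_of.reindex(proteins).values,
                "bait": bait,
                "mean_fc": mean_fc.values,
                "log2_fc": np.log2(mean_fc.values),
                "detected_in_bait": (bait_total > 0).values,
            }
        )
        for sess in fc_by_session:
            frame[f"fc_session_{sess}"] = fc_frame[sess].values
        rows.append(frame)

    out = pd.concat(rows, ignore_index=True)
    out = out.sort_values(["bait", "protein_id"], kind="mergesort").reset_index(drop=True)
    result = EnrichmentResult(
        genotype=genotype,
        df=out,
        sessions=sessions,
        thresholds=tuple(thresholds),
        provenance={
            "pseudocount": pseudocount,
            "thresholds": list(thresholds),
            "n_sessions": len(sessions),
            "n_imputed_session_means": n_imputed,
            "n_proteins": len(proteins),
        },
    )
    logger.info(
        "run_enrichment(%s): %d proteins, %d sessions, %d imputed session means",
        genotype,
        len(proteins),
        len(sessions),
        n_imputed,
    )
    return result


def call_hits(
    result: EnrichmentResult, threshold: float
) -> tuple[dict[str, set[str]], set[str]]:
    """Hit sets per bait at an inclusive FC threshold, plus their union."""
    if threshold <= 0:
        raise ValidationError("hit threshold must be positive")
    per_bait: dict[str, set[str]] = {}
    for bait in BAITS:
        sub = result.bait_frame(bait)
        per_bait[bait] = set(sub.loc[sub["mean_fc"] >= threshold, "protein_id"])
    union = set().union(*per_bait.values()) if per_bait else set()
    return per_bait, union


def summarize(result: EnrichmentResult) -> pd.DataFrame:
    """Per-bait identified / log2FC>0 / hit counts (Fig-legend style).

    "Identified" here means detected (≥1 peptide across repeats) in that
    bait condition; "positive" is log2 FC > 0; "hits" is final FC ≥ 2.
    """
    rows = []
    for bait in BAITS:
        sub = result.bait_frame(bait)
        sub = sub[sub["detected_in_bait"]]
        rows.append(
            {
                "bait": bait,
                "n_identified": len(sub),
                "n_positive": int((sub["log2_fc"] > 0).sum()),
                "n_hits": int((sub["mean_fc"] >= 2.0).sum()),
            }
        )
    return pd.DataFrame(rows)


def write_enrichment(result: EnrichmentResult, path: str | Path) -> None:
    """Export to TSV with explicit hit-flag columns per threshold."""
    df = result.df.copy()
    for t in result.thresholds:
        df[f"hit_{t:g}"] = (df["mean_fc"] >= t).astype(int)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_enrichment(path: str | Path, genotype: str = "CONTROL") -> EnrichmentResult:
    """Re-read an exported enrichment TSV (round trip of write_enrichment)."""
    df = pd.read_csv(path, sep="\t")
    sessions = sorted(
        int(c.rsplit("_", 1)[1]) for c in df.columns if c.startswith("fc_session_")
    )
    thresholds = tuple(
        float(c.split("_", 1)[1]) for c in df.columns if c.startswith("hit_")
    )
    keep = [c for c in df.columns if not c.startswith("hit_")]
    return EnrichmentResult(
        genotype=genotype,
        df=df[keep],
        sessions=sessions,
        thresholds=thresholds or DEFAULT_THRESHOLDS,
    )
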