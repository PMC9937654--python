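"""Data model and file IO for peptide-count tables, gene lists and annotations.

The raw input of the analysis is a long-format table of spectral (peptide)
counts: one row per protein × BirA condition × genotype × mass-spectrometry
session × biological repeat. Proteins that a mass spectrometer did not detect
are simply absent from such tables; absence is treated as a count of zero
everywhere downstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("ibioid")

# Canonical condition names. Three release-site baits plus the soluble-axon
# reference (BirA fused to tdTomato) used as the fold-change denominator.
BAITS = ("RIM_PPCP", "ELKS2B", "CAVB4")
REFERENCE = "TDTOMATO"
CONDITIONS = BAITS + (REFERENCE,)

GENOTYPES = ("CONTROL", "RIM_CKO", "SYT1_CKO")

#: Gene encoding each bait fusion, used for self-bait exclusion rules.
BAIT_GENES = {"RIM_PPCP": "RIMS1", "ELKS2B": "ERC2", "CAVB4": "CACNB4"}

COUNT_COLUMNS = [
    "protein_id",
    "gene_symbol",
    "bait",
    "genotype",
    "session",
    "repeat",
    "peptide_count",
]

KEY_COLUMNS = ["protein_id", "bait", "genotype", "session", "repeat"]


class SchemaError(ValueError):
    """A required column is missing or mis-mapped."""


class ValidationError(ValueError):
    """Row-level contract violation (negative count, duplicate key, ...)."""


def normalize_symbol(symbol: str, synonyms: Mapping[str, str] | None = None) -> str:
    """Case-normalize a gene symbol (uppercase, stripped), then apply an
    optional synonym map. The synonym map is applied after case folding so
    its keys are matched case-insensitively."""
    s = str(symbol).strip().upper()
    if synonyms:
        s = synonyms.get(s, s)
    return s


@dataclass(frozen=True)
class GeneList:
    """A named set of case-normalized gene symbols (removal or panel list)."""

    name: str
    symbols: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("GeneList requires a non-empty name")

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.symbols

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class AnnotationTable:
    """Hierarchical cellular-component annotations per gene.

    Each gene maps to a set of category paths (tuples of labels, e.g.
    ``("synapse", "presynapse", "active zone")``). Paths are not mutually
    exclusive and a gene annotated to a child path counts at every ancestor
    level, so membership tests use prefix matching.
    """

    entries: Mapping[str, frozenset[tuple[str, ...]]]

    def paths(self) -> set[tuple[str, ...]]:
        """All distinct paths, including every ancestor prefix."""
        out: set[tuple[str, ...]] = set()
        for ps in self.entries.values():
            for p in ps:
                for i in range(1, len(p) + 1):
                    out.add(p[:i])
        return out

    def annotated_at(self, gene_symbol: str, level: Sequence[str]) -> bool:
        """True if the gene carries any annotation at or below ``level``."""
        level_t = tuple(level)
        ps = self.entries.get(normalize_symbol(gene_symbol))
        if not ps:
            return False
        k = len(level_t)
        return any(p[:k] == level_t for p in ps)

    def genes_at(self, level: Sequence[str]) -> set[str]:
        level_t = tuple(level)
        k = len(level_t)
        return {g for g, ps in self.entries.items() if any(p[:k] == level_t for p in ps)}


@dataclass
class CountTable:
    """Validated long-format peptide counts.

    Wraps a :class:`pandas.DataFrame` with columns ``protein_id,
    gene_symbol, bait, genotype, session, repeat, peptide_count``. On
    construction the table is validated (non-negative integer counts, unique
    (protein, bait, genotype, session, repeat) keys, reference condition
    present in every genotype × session block) and sorted canonically so
    ingestion is row-order invariant.
    """

    df: pd.DataFrame
    require_reference: bool = True

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = [c for c in COUNT_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"count table missing required column(s): {missing}")
        df = df[COUNT_COLUMNS]

        counts = pd.to_numeric(df["peptide_count"], errors="coerce")
        bad = counts.isna() | (counts < 0) | (counts != counts.round())
        if bad.any():
            row = int(bad.idxmax())
            raise ValidationError(
                f"peptide_count must be a non-negative integer; offending row "
                f"index {row}: {df.loc[row].to_dict()}"
            )
        df["peptide_count"] = counts.astype(int)

        df["protein_id"] = df["protein_id"].astype(str)
        df["gene_symbol"] = [normalize_symbol(s) for s in df["gene_symbol"]]
        df["bait"] = df["bait"].astype(str).str.upper()
        unknown = set(df["bait"]) - set(CONDITIONS)
        if unknown:
            raise ValidationError(f"unknown bait condition(s): {sorted(unknown)}")
        df["genotype"] = df["genotype"].astype(str).str.upper()
        unknown = set(df["genotype"]) - set(GENOTYPES)
        if unknown:
            raise ValidationError(f"unknown genotype(s): {sorted(unknown)}")
        df["session"] = pd.to_numeric(df["session"]).astype(int)
        df["repeat"] = pd.to_numeric(df["repeat"]).astype(int)

        dup = df.duplicated(subset=KEY_COLUMNS, keep=False)
        if dup.any():
            first = df.loc[dup, KEY_COLUMNS].iloc[0].to_dict()
            raise ValidationError(f"duplicate (protein,bait,genotype,session,repeat) key: {first}")

        if self.require_reference:
            for (gt, sess), block in df.groupby(["genotype", "session"]):
                if REFERENCE not in set(block["bait"]):
                    raise ValidationError(
                        f"genotype {gt} session {sess} has no {REFERENCE} reference condition"
                    )

        df = df.sort_values(KEY_COLUMNS, kind="mergesort").reset_index(drop=True)
        self.df = df

    # -- convenience accessors -------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def genotypes(self) -> list[str]:
        return sorted(set(self.df["genotype"]))

    def sessions(self, genotype: str | None = None) -> list[int]:
        df = self.df if genotype is None else self.df[self.df["genotype"] == genotype]
        return sorted(set(df["session"]))

    def gene_of(self) -> pd.Series:
        """protein_id → gene_symbol (first occurrence)."""
        return self.df.drop_duplicates("protein_id").set_index("protein_id")["gene_symbol"]

    def subset(self, **kwargs) -> "CountTable":
        df = self.df
        for col, val in kwargs.items():
            df = df[df[col] == val]
        return CountTable(df.reset_index(drop=True), require_reference=False)


DEFAULT_SCHEMA = {c: c for c in COUNT_COLUMNS}


def read_count_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    sep: str = "\t",
    require_reference: bool = True,
) -> CountTable:
    """Read a delimited peptide-count file into a validated :class:`CountTable`.

    Parameters
    ----------
    path:
        Delimited text file with a header row.
    schema:
        Mapping from canonical column name to the column name used in the
        file; canonical names missing from the mapping are assumed to be
        spelled literally.
    sep:
        Field delimiter ('\\t' by default; pass ',' for CSV exports).
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    raw = pd.read_csv(path, sep=sep)
    missing = [schema[c] for c in COUNT_COLUMNS if schema[c] not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; header is {list(raw.columns)}")
    df = raw.rename(columns={schema[c]: c for c in COUNT_COLUMNS})
    return CountTable(df, require_reference=require_reference)


def write_count_table(table: CountTable, path: str | Path, sep: str = "\t") -> None:
    table.df.to_csv(path, sep=sep, index=False)


def read_gene_list(
    path: str | Path,
    name: str,
    synonyms: Mapping[str, str] | None = None,
) -> GeneList:
    """Read a one-symbol-per-line gene list; blank lines and ``#`` comments
    are ignored and symbols are normalized. An empty effective list is legal
    but logged as a warning."""
    symbols: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            symbols.add(normalize_symbol(line, synonyms))
    if not symbols:
        logger.warning("gene list %r read from %s is empty", name, path)
    return GeneList(name=name, symbols=frozenset(symbols))


def read_synonym_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (alias → canonical symbol), both case-normalized."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise SchemaError(f"synonym map line needs exactly 2 columns: {line!r}")
        out[normalize_symbol(parts[0])] = normalize_symbol(parts[1])
    return out


def read_annotation_table(path: str | Path, sep: str = "\t") -> AnnotationTable:
    """Read a gene ↔ category-path table (one slash-delimited path per row)."""
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    try:
        gcol, pcol = cols["gene_symbol"], cols["category_path"]
    except KeyError as exc:
        raise SchemaError(
            f"{path}: annotation table needs columns gene_symbol, category_path"
        ) from exc
    entries: dict[str, set[tuple[str, ...]]] = {}
    for g, p in zip(df[gcol], df[pcol]):
        path_t = tuple(part.strip() for part in str(p).split("/") if part.strip())
        if path_t:
            entries.setdefault(normalize_symbol(g), set()).add(path_t)
    return AnnotationTable({g: frozenset(ps) for g, ps in entries.items()})


def write_annotation_table(ann: AnnotationTable, path: str | Path) -> None:
    rows = [
        {"gene_symbol": g, "category_path": "/".join(p)}
        for g, ps in sorted(ann.entries.items())
        for p in sorted(ps)
    ]
    pd.DataFrame(rows, columns=["gene_symbol", "category_path"]).to_csv(
        path, sep="\t", index=False
    )


def write_json(obj, path: str | Path) -> None:
    """Deterministic JSON export (sorted keys, trailing newline)."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
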