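"""Synthetic peptide-count datasets with known ground truth.

The generator emulates the structure of a multi-bait proximity-labeling
(BioID) experiment in dopamine axons: four conditions (three release-site
baits plus a soluble BirA-tdTomato reference), repeats grouped into one or
two mass-spectrometry sessions, overdispersed spectral counts, a planted
release-site protein subset enriched in the bait conditions, strong
self-biotinylation of each bait's own gene, a mitochondrial/contaminant
background, per-record detection dropout, and genotype effects that collapse
the enrichment for some baits while sparing others.

Counts are negative-binomial (Gamma–Poisson): spectral counts are
overdispersed relative to Poisson, and a single global dispersion parameter
is the minimal model of that. The mean of protein p in condition b is

    mu[p, b] = baseline[p] * effective_enrichment[p, b] * session_factor

where effective_enrichment is 1 for the reference and for background
proteins, ``1 + (enrichment_factor - 1) * genotype_multiplier`` for planted
release-site proteins in bait conditions, and additionally multiplied by
``self_bait_factor`` for a bait's own gene in its own condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .io import BAITS, BAIT_GENES, CONDITIONS, REFERENCE, CountTable

#: Contaminant symbols always present in the background (endogenously
#: biotinylated carboxylases and purification reagents).
CONTAMINANT_GENES = ("PC", "PCCA", "NEUTRAVIDIN", "IGG")


class ConfigError(ValueError):
    """A SimConfig field is out of its legal range."""


def _default_genotype_effect() -> dict[str, dict[str, float]]:
    # RIM knockout collapses release-site enrichment for the ELKS and CaVbeta4
    # baits while the re-expressed RIM fragment bait partially restores it;
    # Syt-1 knockout leaves enrichment intact.
    return {
        "CONTROL": {b: 1.0 for b in BAITS},
        "RIM_CKO": {"RIM_PPCP": 0.15, "ELKS2B": 0.02, "CAVB4": 0.02},
        "SYT1_CKO": {b: 1.0 for b in BAITS},
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    Defaults emulate the scale of the real study: ~1500 detectable proteins
    of which ~15% are mitochondrial background and 5% are planted
    release-site proteins, 2 sessions × 2 repeats for a control-style
    dataset, ~8-fold planted enrichment and a 20-fold self-bait spike.
    """

    n_proteins: int = 1500
    frac_release_site: float = 0.05
    frac_mito: float = 0.15
    baseline_log_mean: float = 3.7
    baseline_log_sd: float = 0.45
    dispersion: float = 0.01
    enrichment_factor: float = 8.0
    self_bait_factor: float = 20.0
    dropout_prob: float = 0.005
    genotype_effect: dict = field(default_factory=_default_genotype_effect)
    n_sessions: int = 2
    repeats_per_session: int = 2
    session_effect_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 10:
            raise ConfigError("n_proteins must be >= 10")
        for name in ("frac_release_site", "frac_mito", "dropout_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        for name in ("enrichment_factor", "self_bait_factor"):
            if getattr(self, name) < 1.0:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("baseline_log_sd", "dispersion"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.session_effect_sd < 0:
            raise ConfigError("session_effect_sd must be >= 0")
        if self.n_sessions not in (1, 2):
            raise ConfigError("n_sessions must be 1 or 2")
        if self.repeats_per_session < 1:
            raise ConfigError("repeats_per_session must be >= 1")
        for gt, eff in self.genotype_effect.items():
            for bait, m in eff.items():
                if not 0.0 <= m <= 1.0:
                    raise ConfigError(
                        f"genotype_effect[{gt}][{bait}] must lie in [0, 1], got {m}"
                    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown SimConfig field(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _truth_frame(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Protein universe with flags, baselines and per-bait enrichment."""
    n = config.n_proteins
    ids = [f"P{i:05d}" for i in range(n)]
    genes = [f"GENE{i:05d}" for i in range(n)]

    # Reserve the first proteins for bait genes and fixed contaminants so
    # self-bait and removal-list behavior is always exercised.
    special = list(BAIT_GENES.values()) + list(CONTAMINANT_GENES)
    for i, sym in enumerate(special):
        genes[i] = sym
    n_special = len(special)

    is_contaminant = np.zeros(n, dtype=bool)
    is_contaminant[len(BAIT_GENES) : n_special] = True

    free = np.arange(n_special, n)
    n_mito = int(round(config.frac_mito * n))
    n_rs = int(round(config.frac_release_site * n))
    chosen = rng.choice(free, size=min(n_mito + n_rs, len(free)), replace=False)
    mito_idx = chosen[:n_mito]
    rs_idx = chosen[n_mito : n_mito + n_rs]

    is_mito = np.zeros(n, dtype=bool)
    is_mito[mito_idx] = True
    for i in mito_idx:
        genes[i] = f"MITO{i:05d}"
    is_release_site = np.zeros(n, dtype=bool)
    is_release_site[rs_idx] = True
    # bait genes are themselves release-site proteins
    is_release_site[: len(BAIT_GENES)] = True

    baseline = np.exp(
        rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n)
    )
    # contaminants ride in at high abundance regardless of bait
    baseline[is_contaminant] *= 10.0

    truth = pd.DataFrame(
        {
            "protein_id": ids,
            "gene_symbol": genes,
            "is_release_site": is_release_site,
            "is_mito": is_mito,
            "is_contaminant": is_contaminant,
            "baseline_mean": baseline,
        }
    )
    return truth


def _effective_enrichment(
    truth: pd.DataFrame, config: SimConfig, genotype: str
) -> pd.DataFrame:
    """Per protein × condition multiplier on the baseline mean."""
    eff = config.genotype_effect.get(genotype)
    if eff is None or any(b not in eff for b in BAITS):
        raise ConfigError(f"genotype_effect must define all baits for {genotype!r}")
    out = pd.DataFrame(1.0, index=truth.index, columns=list(CONDITIONS))
    for bait in BAITS:
        factor = 1.0 + (config.enrichment_factor - 1.0) * eff[bait]
        out.loc[truth["is_release_site"].values, bait] = factor
        own = truth["gene_symbol"] == BAIT_GENES[bait]
        out.loc[own.values, bait] *= config.self_bait_factor
    out[REFERENCE] = 1.0
    return out


def simulate_dataset(
    config: SimConfig,
    genotype: str = "CONTROL",
    sub_seed: int = 0,
) -> tuple[CountTable, pd.DataFrame]:
    """Draw one dataset for one genotype.

    Returns a validated :class:`CountTable` (only detected records, i.e.
    count > 0, mirroring real mass-spec output) and the ground-truth frame
    (one row per protein with flags, baseline mean, and the per-condition
    effective enrichment columns ``eff_<condition>``).

    Identical ``(config, genotype, sub_seed)`` yields an identical table.
    """
    config.validate()
    # string hash via crc32: stable across processes, unlike builtin hash()
    import zlib

    gt_key = zlib.crc32(genotype.encode()) % (2**31)
    rng = np.random.default_rng((config.seed, gt_key, sub_seed))
    truth = _truth_frame(config, np.random.default_rng((config.seed, 7)))
    eff = _effective_enrichment(truth, config, genotype)

    n = config.n_proteins
    records = []
    repeat_id = 0
    for sess in range(1, config.n_sessions + 1):
        sess_factor = (
            float(np.exp(rng.normal(0.0, config.session_effect_sd)))
            if config.session_effect_sd > 0
            else 1.0
        )
        for _ in range(config.repeats_per_session):
            repeat_id += 1
            for cond in CONDITIONS:
                mu = truth["baseline_mean"].values * eff[cond].values * sess_factor
                # Gamma-Poisson mixture: var = mu + dispersion * mu^2
                shape = 1.0 / config.dispersion
                lam = rng.gamma(shape, mu / shape)
                counts = rng.poisson(lam)
                if config.dropout_prob > 0:
                    drop = rng.random(n) < config.dropout_prob
                    counts = np.where(drop, 0, counts)
                keep = counts > 0
                records.append(
                    pd.DataFrame(
                        {
                            "protein_id": truth.loc[keep, "protein_id"].values,
                            "gene_symbol": truth.loc[keep, "gene_symbol"].values,
                            "bait": cond,
                            "genotype": genotype,
                            "session": sess,
                            "repeat": repeat_id,
                            "peptide_count": counts[keep],
                        }
                    )
                )

    table = CountTable(pd.concat(records, ignore_index=True))
    truth_out = truth.copy()
    for cond in CONDITIONS:
        truth_out[f"eff_{cond}"] = eff[cond].values
    return table, truth_out


def simulate_genotype_panel(
    config: SimConfig,
) -> dict[str, tuple[CountTable, pd.DataFrame]]:
    """One dataset per genotype over a shared protein universe.

    The control genotype uses the configured session/repeat design; the
    mutants use a single session (with ``repeats_per_session`` repeats), the
    design under which the real mutant datasets were acquired.
    """
    config.validate()
    for gt in ("CONTROL", "RIM_CKO", "SYT1_CKO"):
        if gt not in config.genotype_effect:
            raise ConfigError(f"genotype_effect missing genotype {gt}")
    panel: dict[str, tuple[CountTable, pd.DataFrame]] = {}
    for i, gt in enumerate(("CONTROL", "RIM_CKO", "SYT1_CKO")):
        cfg = SimConfig(**{**asdict(config)})
        if gt != "CONTROL":
            cfg.n_sessions = 1
        panel[gt] = simulate_dataset(cfg, genotype=gt, sub_seed=i)
    return panel


def synthetic_annotation(truth: pd.DataFrame, seed: int = 0):
    """Hierarchical cellular-component annotations consistent with the truth.

    Planted release-site genes receive presynaptic paths (half of them down
    to the active zone); a fifth of the non-planted, non-mito background is
    annotated postsynaptic, mimicking that ontology coverage is partial and
    not specific to the planted signal.
    """
    from .io import AnnotationTable

    rng = np.random.default_rng((seed, 99))
    entries: dict[str, frozenset] = {}
    for _, row in truth.iterrows():
        g = row["gene_symbol"]
        if row["is_contaminant"] or row["is_mito"]:
            continue
        if row["is_release_site"]:
            if rng.random() < 0.5:
                entries[g] = frozenset({("synapse", "presynapse", "active zone")})
            else:
                entries[g] = frozenset({("synapse", "presynapse")})
        elif rng.random() < 0.2:
            entries[g] = frozenset({("synapse", "postsynapse")})
    return AnnotationTable(entries)


def mito_gene_list(truth: pd.DataFrame):
    """Removal list of the simulated mitochondrial symbols (MitoCarta stand-in)."""
    from .io import GeneList

    return GeneList(
        name="sim_mito",
        symbols=frozenset(truth.loc[truth["is_mito"], "gene_symbol"]),
    )


def contaminant_gene_list():
    """Fixed contaminant removal list (PC/PCCA/neutravidin/IgG)."""
    from .io import GeneList

    return GeneList(name="contaminants", symbols=frozenset(CONTAMINANT_GENES))
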