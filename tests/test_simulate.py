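"""Generator contracts: determinism, mean model, planted-effect recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ibioid.enrichment import call_hits, filter_contaminants, run_enrichment
from ibioid.simulate import (
    ConfigError,
    SimConfig,
    contaminant_gene_list,
    mito_gene_list,
    simulate_dataset,
    simulate_genotype_panel,
)


class TestConfig:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_proteins", 5),
            ("frac_release_site", 1.5),
            ("dropout_prob", -0.1),
            ("enrichment_factor", 0.5),
            ("dispersion", 0.0),
            ("n_sessions", 3),
            ("repeats_per_session", 0),
        ],
    )
    def test_invalid_fields_named(self, field, value):
        cfg = SimConfig(**{field: value})
        with pytest.raises(ConfigError, match=field.split("_")[0]):
            cfg.validate()

    def test_genotype_multiplier_range(self):
        cfg = SimConfig(genotype_effect={"CONTROL": {"RIM_PPCP": 2.0, "ELKS2B": 1, "CAVB4": 1}})
        with pytest.raises(ConfigError, match="genotype_effect"):
            cfg.validate()

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimConfig(n_proteins=123, seed=9)
        p = tmp_path / "sim.yaml"
        cfg.to_yaml(p)
        assert SimConfig.from_yaml(p) == cfg

    def test_unknown_yaml_field_rejected(self, tmp_path):
        p = tmp_path / "sim.yaml"
        p.write_text("n_protein: 100\n")
        with pytest.raises(ConfigError, match="n_protein"):
            SimConfig.from_yaml(p)


class TestDeterminism:
    def test_same_seed_same_table(self):
        cfg = SimConfig(n_proteins=200, seed=1)
        t1, truth1 = simulate_dataset(cfg)
        t2, truth2 = simulate_dataset(cfg)
        pd.testing.assert_frame_equal(t1.df, t2.df)
        pd.testing.assert_frame_equal(truth1, truth2)

    def test_different_seed_different_table(self):
        a, _ = simulate_dataset(SimConfig(n_proteins=200, seed=1))
        b, _ = simulate_dataset(SimConfig(n_proteins=200, seed=2))
        assert not a.df.equals(b.df)

    def test_bookkeeping_sessions_and_repeats(self):
        cfg = SimConfig(n_proteins=50, n_sessions=1, repeats_per_session=2, seed=3)
        table, _ = simulate_dataset(cfg, genotype="SYT1_CKO")
        assert set(table.df["session"]) == {1}
        assert set(table.df["repeat"]) == {1, 2}
        assert set(table.df["genotype"]) == {"SYT1_CKO"}


class TestMeanModel:
    def test_null_generator_bait_equals_reference(self):
        """With no planted enrichment and no dropout, per-protein mean counts
        in a bait match the reference (paired t-test, alpha=0.01)."""
        cfg = SimConfig(
            n_proteins=2000,
            frac_release_site=0.0,
            frac_mito=0.0,
            enrichment_factor=1.0,
            self_bait_factor=1.0,
            dropout_prob=0.0,
            seed=5,
        )
        table, _ = simulate_dataset(cfg)
        mean_by = table.df.groupby(["protein_id", "bait"])["peptide_count"].sum().unstack(fill_value=0) / 4.0
        t, p = stats.ttest_rel(mean_by["ELKS2B"], mean_by["TDTOMATO"])
        assert p > 0.01

    def test_empirical_means_converge_to_configured(self):
        """With dropout off, per-protein empirical means over 200 repeats are
        within 5% of baseline * effective enrichment for sampled proteins."""
        cfg = SimConfig(
            n_proteins=40,
            repeats_per_session=200,
            n_sessions=1,
            dropout_prob=0.0,
            seed=7,
        )
        table, truth = simulate_dataset(cfg)
        truth = truth.set_index("protein_id")
        df = table.df[table.df["bait"] == "TDTOMATO"]
        sums = df.groupby("protein_id")["peptide_count"].sum() / 200.0
        rng = np.random.default_rng(0)
        sample = rng.choice(truth.index.to_numpy(), size=20, replace=False)
        for p in sample:
            expected = truth.loc[p, "baseline_mean"]
            assert sums.get(p, 0.0) == pytest.approx(expected, rel=0.05)

    def test_self_bait_spike(self):
        cfg = SimConfig(n_proteins=100, dropout_prob=0.0, seed=2)
        table, truth = simulate_dataset(cfg)
        result = run_enrichment(table)
        own = result.df[
            (result.df.gene_symbol == "RIMS1") & (result.df.bait == "RIM_PPCP")
        ].iloc[0]
        other = result.df[
            (result.df.gene_symbol == "RIMS1") & (result.df.bait == "ELKS2B")
        ].iloc[0]
        assert own["mean_fc"] > 4 * other["mean_fc"]


class TestRecovery:
    def test_planted_sensitivity_and_fdp(self):
        """Core generator/pipeline property: at 8-fold planted enrichment the
        2.0-threshold hit union recovers >=90% of release-site proteins with
        <=10% false discoveries (mean over seeds 1-10)."""
        sens, fdp = [], []
        for seed in range(1, 11):
            cfg = SimConfig(n_proteins=1000, frac_release_site=0.05, seed=seed)
            table, truth = simulate_dataset(cfg)
            table = filter_contaminants(
                table, mito_gene_list(truth), contaminant_gene_list()
            )
            result = run_enrichment(table)
            _, union = call_hits(result, 2.0)
            planted = set(
                truth.loc[
                    truth.is_release_site & ~truth.is_contaminant, "protein_id"
                ]
            )
            tp = len(union & planted)
            sens.append(tp / len(planted))
            fdp.append((len(union) - tp) / max(len(union), 1))
        assert np.mean(sens) >= 0.9
        assert np.mean(fdp) <= 0.1


class TestGenotypePanel:
    def test_hit_count_ordering_across_genotypes(self):
        """RIM knockout collapses the hit count; Syt-1 knockout does not."""
        ok = 0
        for seed in range(1, 6):
            counts = {}
            panel = simulate_genotype_panel(SimConfig(n_proteins=600, seed=seed))
            for gt, (table, truth) in panel.items():
                table = filter_contaminants(
                    table, mito_gene_list(truth), contaminant_gene_list()
                )
                _, union = call_hits(run_enrichment(table, genotype=gt), 2.0)
                counts[gt] = len(union)
            if (
                counts["RIM_CKO"] < counts["SYT1_CKO"]
                and counts["RIM_CKO"] < counts["CONTROL"]
            ):
                ok += 1
        assert ok >= 4

    def test_null_genotype_effect_is_exchangeable(self):
        """With all multipliers 1 the three genotypes have hit counts within
        binomial noise of each other."""
        ge = {gt: {b: 1.0 for b in ("RIM_PPCP", "ELKS2B", "CAVB4")} for gt in ("CONTROL", "RIM_CKO", "SYT1_CKO")}
        counts = []
        panel = simulate_genotype_panel(
            SimConfig(n_proteins=600, seed=4, genotype_effect=ge, n_sessions=1)
        )
        for gt, (table, truth) in panel.items():
            table = filter_contaminants(
                table, mito_gene_list(truth), contaminant_gene_list()
            )
            _, union = call_hits(run_enrichment(table, genotype=gt), 2.0)
            counts.append(len(union))
        # ~30 planted hits per genotype; 6 sigma of binomial noise
        assert max(counts) - min(counts) <= 6 * np.sqrt(np.mean(counts))

    def test_mutants_are_single_session(self):
        panel = simulate_genotype_panel(SimConfig(n_proteins=60, seed=1))
        assert panel["CONTROL"][0].sessions() == [1, 2]
        assert panel["RIM_CKO"][0].sessions() == [1]
        assert panel["SYT1_CKO"][0].sessions() == [1]

    def test_missing_genotype_effect_rejected(self):
        cfg = SimConfig(genotype_effect={"CONTROL": {b: 1.0 for b in ("RIM_PPCP", "ELKS2B", "CAVB4")}})
        with pytest.raises(ConfigError, match="RIM_CKO"):
            simulate_genotype_panel(cfg)

    def test_shared_protein_universe(self):
        panel = simulate_genotype_panel(SimConfig(n_proteins=80, seed=6))
        truths = [t.set_index("protein_id") for _, t in panel.values()]
        for t in truths[1:]:
            assert (t["gene_symbol"] == truths[0]["gene_symbol"]).all()
            assert (t["baseline_mean"] == truths[0]["baseline_mean"]).all()
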