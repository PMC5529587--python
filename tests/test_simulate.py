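"""The synthetic-data generator: determinism, planted effects, read noise."""

import json

import numpy as np
import pandas as pd
import pytest

from sparrowmhc.simulate import (
    FAEffects,
    SimConfig,
    simulate_population,
    simulate_reads,
    write_fixtures,
)


class TestConfigValidation:
    def test_bad_distribution_rejected(self):
        cfg = SimConfig(clutches_per_female={1: 0.5, 2: 0.4})
        with pytest.raises(ValueError, match="probability"):
            cfg.validate()

    def test_clutch_support_rejected(self):
        cfg = SimConfig(clutches_per_female={5: 1.0})
        with pytest.raises(ValueError, match="1-4"):
            cfg.validate()

    def test_coverage_below_threshold_rejected(self):
        cfg = SimConfig()
        cfg.read_sim.mean_coverage = 50
        with pytest.raises(ValueError, match="104"):
            cfg.validate()


class TestPopulation:
    def test_determinism_under_fixed_seed(self):
        a = simulate_population(SimConfig(seed=5))
        b = simulate_population(SimConfig(seed=5))
        pd.testing.assert_frame_equal(a.individuals, b.individuals)
        assert a.allele_sets == b.allele_sets
        assert a.pool.sequences == b.pool.sequences

    def test_study_shape(self, default_pop):
        off = default_pop.individuals[default_pop.individuals["role"] == "offspring"]
        assert 230 <= len(off) <= 360            # around 293 embryos
        assert default_pop.individuals["aviary"].nunique() == 14
        assert 56 <= len(default_pop.pairs) <= 70
        assert set(off["clutch_order"]) <= {1, 2, 3, 4}
        sizes = [len(default_pop.allele_sets[i]) for i in off["individual"]]
        assert 1 <= min(sizes) and max(sizes) <= 8

    def test_survival_monotone_and_phenotype_missingness(self, default_pop):
        off = default_pop.individuals[default_pop.individuals["role"] == "offspring"]
        assert (off["survived_day6"] <= off["survived_day1"]).all()
        assert (off["survived_day12"] <= off["survived_day6"]).all()
        dead6 = off[off["survived_day6"] == 0]
        assert dead6["mass_day6"].isna().all()
        dead12 = off[off["survived_day12"] == 0]
        assert dead12["tarsus_day12"].isna().all()

    def test_offspring_alleles_from_parents(self, default_pop):
        off = default_pop.individuals[default_pop.individuals["role"] == "offspring"]
        for _, row in off.head(50).iterrows():
            child = default_pop.allele_sets[row["individual"]]
            parents = (default_pop.allele_sets[row["mother"]]
                       | default_pop.allele_sets[row["father"]])
            assert child <= parents

    def test_null_effects_all_survive(self):
        cfg = SimConfig(seed=3, effects={}, sharing_effect=0.0,
                        sex_effect_day6=0.0, clutch_order_effect_day1=0.0,
                        clutch_size_effect_day12=0.0,
                        surv_intercepts={"day1": np.inf, "day6": np.inf,
                                         "day12": np.inf},
                        mass6_clutch_size=0.0, tarsus6_clutch_order=0.0,
                        mass12_clutch_order=0.0, tarsus12_clutch_order=0.0)
        pop = simulate_population(cfg)
        off = pop.individuals[pop.individuals["role"] == "offspring"]
        assert (off["survived_day12"] == 1).all()
        # phenotype = intercept + noise
        assert off["mass_day6"].mean() == pytest.approx(cfg.mass6_intercept,
                                                        abs=4 * cfg.mass6_sd
                                                        / np.sqrt(len(off)))

    def test_planted_survival_effect_recovered_by_logistic_fit(self):
        """At ~2,000 offspring a logistic regression of day-6 survival on
        carrier status recovers the planted -1.0 logit within 2 SE."""
        import statsmodels.api as sm

        cfg = SimConfig(seed=9, n_aviaries=100,
                        effects={"FA25259": FAEffects(survival_logit_day6=-1.0)},
                        sharing_effect=0.0, sex_effect_day6=0.0)
        pop = simulate_population(cfg)
        off = pop.individuals[(pop.individuals["role"] == "offspring")
                              & (pop.individuals["survived_day1"] == 1)]
        assert len(off) >= 1500
        carrier = np.array([("FA25259" in pop.fa_sets[i])
                            for i in off["individual"]], dtype=float)
        X = sm.add_constant(carrier)
        fit = sm.GLM(off["survived_day6"].to_numpy(), X,
                     family=sm.families.Binomial()).fit()
        beta, se = fit.params[1], fit.bse[1]
        assert abs(beta - (-1.0)) < 2 * se

    def test_nonnatural_death_rate(self):
        pops = [simulate_population(SimConfig(seed=40 + r)) for r in range(6)]
        deaths = excl = 0
        for pop in pops:
            off = pop.individuals[pop.individuals["role"] == "offspring"]
            d = off[(off["survived_day1"] == 1) & (off["survived_day6"] == 0)]
            deaths += len(d)
            excl += int(d["nonnatural_death"].sum())
        rate = excl / deaths
        assert abs(rate - 11 / 49) < 3 * np.sqrt((11 / 49) * (38 / 49) / deaths)


class TestReads:
    def test_noiseless_variants_are_true_alleles(self, noiseless_config):
        pop = simulate_population(noiseless_config)
        mats, _ = simulate_reads(pop, noiseless_config)
        truth = set(pop.pool.sequences.values())
        for mat in mats:
            for sample in mat.counts.index:
                row = mat.counts.loc[sample]
                ind = sample.removesuffix(".rep")
                true_seqs = {pop.pool.sequences[a] for a in pop.allele_sets[ind]}
                observed = {mat.sequences[v] for v in row.index[row > 0]}
                assert observed <= true_seqs
                assert observed <= truth

    def test_mean_coverage(self, default_pop):
        mats, _ = simulate_reads(default_pop, default_pop.config)
        totals = np.concatenate([m.counts.sum(axis=1).to_numpy() for m in mats])
        assert len(totals) >= 100
        se = totals.std() / np.sqrt(len(totals))
        assert abs(totals.mean() - 300) < 3 * se

    def test_chimeras_are_single_breakpoint_recombinants(self):
        cfg = SimConfig(seed=13)
        cfg.read_sim.error_rate = 0.0
        cfg.read_sim.chimera_rate = 0.05
        pop = simulate_population(cfg)
        mats, _ = simulate_reads(pop, cfg)
        truth = set(pop.pool.sequences.values())
        seqs = pop.pool.sequences
        checked = 0
        for mat in mats:
            for sample in mat.counts.index:
                ind = sample.removesuffix(".rep")
                alleles = sorted(pop.allele_sets[ind])
                row = mat.counts.loc[sample]
                for v in row.index[row > 0]:
                    s = mat.sequences[v]
                    if s in truth:
                        continue
                    ok = any(
                        s == seqs[a][:k] + seqs[b][k:]
                        for a in alleles for b in alleles if a != b
                        for k in range(1, len(s)))
                    assert ok, "emitted variant is not a single-breakpoint chimera"
                    checked += 1
            if checked > 50:
                break
        assert checked > 0

    def test_replicates_linked_and_resimulated(self, default_pop):
        mats, tags = simulate_reads(default_pop, default_pop.config)
        for mat in mats:
            for ind, rep in mat.replicate_links:
                assert rep in mat.counts.index and ind in mat.counts.index
                assert not mat.counts.loc[ind].equals(mat.counts.loc[rep])


class TestFixtures:
    def test_roundtrip_and_manifest(self, tmp_path, noiseless_config):
        pop = simulate_population(noiseless_config)
        mats, tags = simulate_reads(pop, noiseless_config)
        manifest = write_fixtures(pop, tmp_path / "fx", matrices=mats, tag_map=tags)

        back = pd.read_csv(tmp_path / "fx" / "pedigree_phenotypes.tsv", sep="\t")
        assert len(back) == len(pop.individuals)

        from Bio import SeqIO
        recs = list(SeqIO.parse(str(tmp_path / "fx" / "alleles.fasta"), "fasta"))
        assert len(recs) == len(pop.pool.sequences)

        stored = json.loads((tmp_path / "fx" / "manifest.json").read_text())
        assert stored["files"] == manifest["files"]

    def test_fixed_seed_byte_identical(self, tmp_path, noiseless_config):
        pop1 = simulate_population(noiseless_config)
        pop2 = simulate_population(noiseless_config)
        m1 = write_fixtures(pop1, tmp_path / "a")
        m2 = write_fixtures(pop2, tmp_path / "b")
        assert m1["files"] == m2["files"]

    def test_manifest_changes_iff_file_changes(self, tmp_path, noiseless_config):
        pop = simulate_population(noiseless_config)
        write_fixtures(pop, tmp_path / "fx")
        before = json.loads((tmp_path / "fx" / "manifest.json").read_text())["files"]
        path = tmp_path / "fx" / "pairs.tsv"
        path.write_text(path.read_text() + "# touched\n")
        write_fixtures(pop, tmp_path / "fx2")
        import hashlib
        new_digest = hashlib.sha256(path.read_bytes()).hexdigest()
        assert new_digest != before["pairs.tsv"]
        unchanged = tmp_path / "fx" / "alleles.fasta"
        assert (hashlib.sha256(unchanged.read_bytes()).hexdigest()
                == before["alleles.fasta"])
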