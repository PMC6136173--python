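"""Tests of the synthetic community, read and omics generators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from viromescope import ecology, quant, stats, synthetic
from viromescope.synthetic import (
    CommunityEffectSpec,
    PlantedEffect,
    SimulationConfig,
)


class TestReferenceDb:
    def test_rejects_empty_and_bad_proportions(self):
        with pytest.raises(ValueError):
            synthetic.generate_reference_db(0)
        with pytest.raises(ValueError):
            synthetic.generate_reference_db(
                5, taxonomy_spec={"Proteobacteria": (0.6, ("Neisseria",))}
            )

    def test_deterministic_under_fixed_seed(self, tmp_path):
        a = synthetic.generate_reference_db(10, rng_seed=7)
        b = synthetic.generate_reference_db(10, rng_seed=7)
        pa, pb = tmp_path / "a.fasta", tmp_path / "b.fasta"
        synthetic.write_fasta(a.sequences(), pa)
        synthetic.write_fasta(b.sequences(), pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_phylum_proportions_within_binomial_bounds(self):
        # phage host phyla should follow the configured proportions
        ref = synthetic.generate_reference_db(1000, eukaryotic_fraction=0.0, rng_seed=3)
        counts = ref.taxonomy_table()["host_phylum"].value_counts()
        for phylum, (prop, _) in synthetic.DEFAULT_HOST_TAXONOMY.items():
            lo, hi = sps.binom.ppf([0.005, 0.995], 1000, prop)
            assert lo <= counts.get(phylum, 0) <= hi, phylum

    def test_invariants_on_records(self, small_reference):
        ids = small_reference.genome_ids
        assert len(set(ids)) == len(ids)
        for rec in small_reference:
            assert len(rec.sequence) >= 1000
            assert set(rec.sequence) <= set("ACGT")
            if rec.virus_type == "phage":
                assert rec.host_genus and rec.host_phylum


class TestCommunityDesign:
    def test_rows_sum_to_one(self, small_design):
        np.testing.assert_allclose(
            small_design.true_abundance.sum(axis=1).to_numpy(), 1.0
        )

    def test_fold_change_below_one_rejected(self, small_reference):
        with pytest.raises(ValueError):
            PlantedEffect("Lactobacillus", 0.5, "nonsmoker")

    def test_unknown_planted_target_rejected(self, small_reference):
        spec = CommunityEffectSpec(planted=[PlantedEffect("NoSuchGenus", 2.0, "smoker")])
        with pytest.raises(ValueError, match="matches no genome"):
            synthetic.design_communities(small_reference, group_sizes=(3, 3), effect_spec=spec)

    def test_low_diversity_group_has_fewer_taxa(self):
        ref = synthetic.generate_reference_db(100, rng_seed=5)
        des = synthetic.design_communities(ref, rng_seed=6)
        rich = (des.true_abundance > 0).sum(axis=1)
        by_group = rich.groupby(des.groups).mean()
        assert by_group["smoker"] < by_group["nonsmoker"]

    def test_planted_fold_change_realized_on_small_genus(self):
        # one planted genus with a small share of community mass, so the
        # compositional closure barely suppresses the realized ratio
        ratios = []
        for s in range(10):
            ref = synthetic.generate_reference_db(200, rng_seed=100 + s)
            spec = CommunityEffectSpec(
                planted=[PlantedEffect("Prevotella", 10.0, "nonsmoker")],
                richness_deflation=1.0,
                evenness_sigma_factor=1.0,
            )
            des = synthetic.design_communities(ref, effect_spec=spec, rng_seed=200 + s)
            genus = quant.aggregate_by_host(des.true_abundance, ref.taxonomy("genus"))
            g = des.groups
            ratios.append(
                genus.loc[g[g == "nonsmoker"].index, "Prevotella"].mean()
                / genus.loc[g[g == "smoker"].index, "Prevotella"].mean()
            )
        assert 5.0 <= np.mean(ratios) <= 20.0

    def test_null_design_groups_exchangeable(self):
        """With no planted effects, a label-permutation test on the group mean
        difference should be non-significant for the vast majority of seeds."""
        n_sig = 0
        n_seeds = 100
        for s in range(n_seeds):
            ref = synthetic.generate_reference_db(50, rng_seed=500 + s)
            des = synthetic.design_communities(
                ref, group_sizes=(8, 5), effect_spec=CommunityEffectSpec.null(),
                base_richness=15, rng_seed=600 + s,
            )
            X = des.true_abundance.to_numpy()
            labels = (des.groups == "smoker").to_numpy()
            obs = np.linalg.norm(X[labels].mean(0) - X[~labels].mean(0))
            rng = np.random.default_rng(s)
            extreme = 0
            for _ in range(199):
                pm = rng.permutation(labels)
                if np.linalg.norm(X[pm].mean(0) - X[~pm].mean(0)) >= obs:
                    extreme += 1
            n_sig += (1 + extreme) / 200 <= 0.05
        assert n_sig <= 0.10 * n_seeds


class TestSimulateReads:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(duplicate_rate=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(reads_per_sample=0)

    def test_error_free_reads_are_exact_substrings(self, small_reference):
        ref = small_reference
        gid = ref.genome_ids[0]
        design = _single_genome_design(ref, gid)
        cfg = SimulationConfig(
            reads_per_sample=200, substitution_error_rate=0.0,
            host_contamination_fraction=0.0, duplicate_rate=0.0, rng_seed=1,
        )
        reads_by_sample, truth = synthetic.simulate_reads(ref, design, None, cfg)
        genome = ref[gid].sequence
        from viromescope.reads import revcomp

        for r in reads_by_sample["s_01"]:
            assert r.sequence in genome or revcomp(r.sequence) in genome
        assert set(truth["origin"]) == {gid}

    def test_zero_abundance_genome_gets_no_reads(self, small_reference, small_design, host_genome):
        cfg = SimulationConfig(reads_per_sample=2000, rng_seed=4)
        _, truth = synthetic.simulate_reads(small_reference, small_design, host_genome, cfg)
        zero = set(small_design.true_abundance.columns[
            (small_design.true_abundance == 0).all(axis=0)
        ])
        assert zero.isdisjoint(set(truth["origin"]))

    def test_duplicate_fraction_within_binomial_bounds(self, small_reference, host_genome):
        design = _single_genome_design(small_reference, small_reference.genome_ids[0])
        cfg = SimulationConfig(reads_per_sample=10_000, duplicate_rate=0.1, rng_seed=5)
        _, truth = synthetic.simulate_reads(small_reference, design, host_genome, cfg)
        frac = truth["is_duplicate"].mean()
        assert 0.08 <= frac <= 0.12

    def test_byte_identical_fastq_under_fixed_seed(self, small_reference, small_design, host_genome, tmp_path):
        cfg = SimulationConfig(reads_per_sample=500, rng_seed=6)
        outs = []
        for tag in ("x", "y"):
            rb, _ = synthetic.simulate_reads(small_reference, small_design, host_genome, cfg)
            p = tmp_path / f"{tag}.fastq"
            synthetic.write_fastq(rb[small_design.sample_ids[0]], p)
            outs.append(p.read_bytes())
        assert outs[0] == outs[1]

    def test_truth_counts_track_true_abundance(self, small_reference, host_genome):
        # read counts per genome / genome length should rank like abundances
        des = synthetic.design_communities(
            small_reference, group_sizes=(2, 2), base_richness=12, rng_seed=11
        )
        cfg = SimulationConfig(reads_per_sample=50_000, rng_seed=12)
        _, truth = synthetic.simulate_reads(small_reference, des, host_genome, cfg)
        sid = des.sample_ids[0]
        sub = truth[(truth["sample_id"] == sid) & (truth["origin"] != "host")]
        counts = sub.groupby("origin").size()
        lengths = small_reference.lengths()
        true = des.true_abundance.loc[sid]
        present = true[true > 0].index
        est = pd.Series({g: counts.get(g, 0) / lengths[g] for g in present})
        rho = sps.spearmanr(est, true[present]).statistic
        assert rho >= 0.95


def _single_genome_design(reference, gid):
    samples = ["s_01", "s_02", "s_03", "s_04"]
    mat = pd.DataFrame(
        0.0, index=samples, columns=reference.genome_ids
    )
    mat[gid] = 1.0
    return synthetic.CommunityDesign(
        sample_ids=samples,
        groups=pd.Series(["a", "a", "b", "b"], index=samples),
        true_abundance=mat,
        planted=[],
        richness_per_group={"a": 1, "b": 1},
    )


class TestSimulateOmics:
    def test_dimension_validation(self, small_design):
        with pytest.raises(ValueError):
            synthetic.simulate_omics(small_design, n_metabolites=0)

    def test_shapes_and_bacteriome_composition(self, small_design):
        om = synthetic.simulate_omics(small_design, rng_seed=1)
        assert om["metabolites"].shape == (10, 83)
        assert om["cytokines"].shape == (10, 39)
        np.testing.assert_allclose(om["bacteriome"].sum(axis=1).to_numpy(), 1.0)

    def test_null_shift_type_one_error_near_alpha(self):
        ref = synthetic.generate_reference_db(10, rng_seed=20)
        des = synthetic.design_communities(ref, effect_spec=CommunityEffectSpec.null(), rng_seed=21)
        spec = synthetic.OmicsEffectSpec(metabolite_shift=0.0, cytokine_shift=0.0, metabolite_dropout=0.0)
        om = synthetic.simulate_omics(des, n_metabolites=200, effect_spec=spec, rng_seed=22)
        g = des.groups
        sm, ns = g[g == "smoker"].index, g[g == "nonsmoker"].index
        met = om["metabolites"]
        rej = np.mean([
            stats.mann_whitney(met.loc[sm, c], met.loc[ns, c]).p_raw < 0.05
            for c in met.columns
        ])
        se = np.sqrt(0.05 * 0.95 / 200)
        assert abs(rej - 0.05) <= 2 * se + 1e-12

    def test_planted_metabolite_shift_detectable_after_bonferroni(self):
        ref = synthetic.generate_reference_db(10, rng_seed=30)
        des = synthetic.design_communities(
            ref, effect_spec=CommunityEffectSpec.null(), rng_seed=31
        )  # 20 vs 10
        spec = synthetic.OmicsEffectSpec(metabolite_dropout=0.0)  # default planted shift
        om = synthetic.simulate_omics(des, n_metabolites=100, effect_spec=spec, rng_seed=32)
        g = des.groups
        sm, ns = g[g == "smoker"].index, g[g == "nonsmoker"].index
        met = om["metabolites"]
        p = np.array([
            stats.mann_whitney(met.loc[sm, c], met.loc[ns, c]).p_raw for c in met.columns
        ])
        detected = (stats.bonferroni(p) < 0.05).mean()
        assert detected >= 0.80

    def test_high_dropout_features_fail_presence_filter(self):
        # with detection probability 0.4 per entry, most features fall below
        # 50% presence at n=30 and are excluded by the reporting filter
        ref = synthetic.generate_reference_db(10, rng_seed=41)
        des = synthetic.design_communities(ref, effect_spec=CommunityEffectSpec.null(), rng_seed=42)
        spec = synthetic.OmicsEffectSpec(metabolite_dropout=0.6)
        om = synthetic.simulate_omics(des, n_metabolites=100, effect_spec=spec, rng_seed=40)
        kept = ecology.presence_filter(om["metabolites"], min_fraction=0.5)
        assert kept.shape[1] < 35
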