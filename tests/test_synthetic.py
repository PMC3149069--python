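import numpy as np
import pandas as pd
import pytest

import cnastats as cna


def _tumor_only(n, gain_rate, loss_rate=0.0):
    return (cna.GroupSpec("t", "tumor", "early", n, gain_rate, loss_rate),)


class TestProbeMapAndGenes:
    def test_target_in_gene_fraction_realized(self):
        cfg = cna.SimulationConfig(seed=1, n_probes=20000, gene_fraction=0.4064)
        pm, genes = cna.simulate_probe_map_and_genes(cfg)
        frac = cna.in_gene_mask(pm, genes, cfg.flank).mean()
        assert 0.3964 <= frac <= 0.4164

    def test_full_coverage_limit(self):
        cfg = cna.SimulationConfig(
            seed=1, n_probes=500, n_chromosomes=2, gene_fraction=1.0
        )
        pm, genes = cna.simulate_probe_map_and_genes(cfg)
        assert cna.in_gene_mask(pm, genes, cfg.flank).mean() == 1.0

    def test_seed_determinism(self):
        cfg = cna.SimulationConfig(seed=9, n_probes=2000, n_chromosomes=3)
        pm1, g1 = cna.simulate_probe_map_and_genes(cfg)
        pm2, g2 = cna.simulate_probe_map_and_genes(cfg)
        assert pm1 == pm2 and g1 == g2

    def test_unreachable_fraction_rejected(self):
        with pytest.raises(ValueError, match="unreachable"):
            cfg = cna.SimulationConfig(
                seed=1, n_probes=100, probe_spacing=1000, flank=2000
            )
            cna.simulate_probe_map_and_genes(cfg)

    def test_probes_evenly_spaced_per_chromosome(self):
        cfg = cna.SimulationConfig(seed=1, n_probes=100, n_chromosomes=3)
        pm, _ = cna.simulate_probe_map_and_genes(cfg)
        for chrom, sl in pm.chromosome_slices().items():
            diffs = np.diff(pm.positions[sl])
            assert (diffs == cfg.probe_spacing).all()


class TestSimulateCohort:
    def test_zero_rates_zero_noise_all_diploid(self):
        cfg = cna.SimulationConfig(
            seed=2, n_probes=400, n_chromosomes=2, noise_sd=0.0,
            group_specs=(cna.GroupSpec("g", "blood", "none", 4, 0.0, 0.0),),
        )
        pm, genes = cna.simulate_probe_map_and_genes(cfg)
        cn, design = cna.simulate_cohort(cfg, pm, genes)
        np.testing.assert_array_equal(cn.values, 2.0)
        assert len(design) == 4

    def test_seed_determinism(self):
        cfg = cna.SimulationConfig(
            seed=5, n_probes=600, n_chromosomes=2,
            group_specs=_tumor_only(5, 4.0, 2.0),
        )
        pm, genes = cna.simulate_probe_map_and_genes(cfg)
        cn1, d1 = cna.simulate_cohort(cfg, pm, genes)
        cn2, d2 = cna.simulate_cohort(cfg, pm, genes)
        np.testing.assert_array_equal(cn1.values, cn2.values)
        assert d1 == d2

    def test_neutral_selection_matches_gene_fraction(self):
        """With selection_strength=1 and no hotspots, the fraction of event
        probes inside genes tracks the configured gene fraction."""
        cfg = cna.SimulationConfig(
            seed=6, n_probes=5000, n_chromosomes=2, noise_sd=0.0,
            selection_strength=1.0, segment_length_mean=20,
            group_specs=_tumor_only(15, 15.0),
        )
        pm, genes = cna.simulate_probe_map_and_genes(cfg)
        cn, design, truth = cna.simulate_cohort(cfg, pm, genes, return_truth=True)
        mask = cna.in_gene_mask(pm, genes, cfg.flank)
        events = truth.calls == 1
        frac = events[:, mask].sum() / events.sum()
        assert frac == pytest.approx(cfg.gene_fraction, abs=0.04)

    def test_gt_ratio_monotone_decreasing_in_selection_strength(self):
        fracs = []
        for s in (1.0, 2.0, 4.0):
            cfg = cna.SimulationConfig(
                seed=30, n_probes=5000, n_chromosomes=2, noise_sd=0.0,
                selection_strength=s, segment_length_mean=20,
                gene_block_period=150,
                group_specs=_tumor_only(20, 15.0),
            )
            pm, genes = cna.simulate_probe_map_and_genes(cfg)
            _, _, truth = cna.simulate_cohort(cfg, pm, genes, return_truth=True)
            mask = cna.in_gene_mask(pm, genes, cfg.flank)
            events = truth.calls == 1
            fracs.append(events[:, mask].sum() / events.sum())
        assert fracs[0] > fracs[1] > fracs[2]
        assert fracs[1] < 0.4064  # strictly below the neutral expectation

    def test_rate_contrast_between_groups(self):
        """A 10x late-vs-germline rate difference shows up as a mean CNA
        probe-count ratio in the same order of magnitude."""
        cfg = cna.SimulationConfig(
            seed=8, n_probes=3000, n_chromosomes=2, noise_sd=0.0,
            segment_length_mean=20,
            group_specs=(
                cna.GroupSpec("germ", "blood", "none", 30, 2.0, 0.0),
                cna.GroupSpec("late", "tumor", "late", 30, 20.0, 0.0),
            ),
        )
        pm, genes = cna.simulate_probe_map_and_genes(cfg)
        _, design, truth = cna.simulate_cohort(cfg, pm, genes, return_truth=True)
        events = truth.calls == 1
        rows_g = truth.sample_indexer(design.select(tissue="blood"))
        rows_t = truth.sample_indexer(design.select(tissue="tumor"))
        ratio = events[rows_t].sum(1).mean() / events[rows_g].sum(1).mean()
        assert 5 <= ratio <= 20

    def test_segments_truncate_at_chromosome_end(self):
        # put essentially all segment starts at the very end of chr1 with
        # lengths far longer than the remaining probes: chr2 must stay
        # untouched because segments never cross chromosome boundaries
        cfg = cna.SimulationConfig(
            seed=10, n_probes=200, n_chromosomes=2, noise_sd=0.0,
            segment_length_mean=500, selection_strength=0.0,
            hotspot_loci=(("1", 99, 1e9),),
            group_specs=_tumor_only(10, 5.0),
        )
        pm, genes = cna.simulate_probe_map_and_genes(cfg)
        _, _, truth = cna.simulate_cohort(cfg, pm, genes, return_truth=True)
        sl = pm.chromosome_slices()
        assert (truth.calls[:, sl["1"]] == 1).any()
        assert (truth.calls[:, sl["2"]] == 0).all()

    def test_design_structure(self):
        cfg = cna.SimulationConfig(seed=3, n_probes=300, n_chromosomes=2)
        pm, genes = cna.simulate_probe_map_and_genes(cfg)
        cn, design = cna.simulate_cohort(cfg, pm, genes)
        df = design.table
        assert len(df) == 63 + 50 + 246 + 25
        assert (df.loc[df["tissue"] != "tumor", "stage"] == "none").all()
        # references are paired to tumor patients
        blood = df[df["tissue"] == "blood"]
        tumor_pids = set(df.loc[df["tissue"] == "tumor", "patient_id"])
        assert set(blood["patient_id"]) <= tumor_pids


class TestPlantGeneSetEnrichment:
    def _setup(self, seed=20, boost=0.3):
        cfg = cna.SimulationConfig(
            seed=seed, n_probes=3000, n_chromosomes=2, noise_sd=0.0,
            segment_length_mean=30,
            group_specs=_tumor_only(40, 5.0),
        )
        pm, genes = cna.simulate_probe_map_and_genes(cfg)
        cn, design = cna.simulate_cohort(cfg, pm, genes)
        calls = cna.call_cnas(cn)
        return cfg, pm, genes, design, calls

    def test_zero_boost_leaves_calls_unchanged(self):
        _, pm, genes, design, calls = self._setup()
        planted = (cna.PlantedSet("S", 10, 0.0),)
        new_calls, coll = cna.plant_gene_set_enrichment(
            calls, genes, planted, seed=1, sample_subset=design.tumors
        )
        np.testing.assert_array_equal(new_calls.calls, calls.calls)
        assert "S" in coll.sets and any(n.startswith("decoy_") for n in coll)

    def test_boost_raises_member_prevalence_by_boost(self):
        _, pm, genes, design, calls = self._setup()
        planted = (cna.PlantedSet("S", 20, 0.3),)
        new_calls, coll = cna.plant_gene_set_enrichment(
            calls, genes, planted, seed=2, sample_subset=design.tumors
        )
        assignment = cna.probes_by_gene(pm, genes)
        rows = calls.sample_indexer(design.tumors)

        def gene_prev(cm, gene):
            ev = cm.calls[np.ix_(rows, assignment[gene])] == 1
            return ev.any(axis=1).mean()

        members = coll["S"]
        others = [g for g in assignment if g not in set(members)]
        delta_members = np.mean(
            [gene_prev(new_calls, g) - gene_prev(calls, g) for g in members]
        )
        delta_others = np.mean(
            [gene_prev(new_calls, g) - gene_prev(calls, g) for g in others]
        )
        assert delta_members == pytest.approx(0.3, abs=0.05)
        assert delta_others == 0.0

    def test_excessive_boost_rejected(self):
        _, pm, genes, design, calls = self._setup()
        with pytest.raises(ValueError, match="past 1"):
            cna.plant_gene_set_enrichment(
                calls, genes, (cna.PlantedSet("S", 5, 0.999),), seed=3,
                sample_subset=design.tumors,
            )
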