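import math

import numpy as np
import pytest

from ftcooc.formats_io import read_bed, read_chrom_sizes, read_cut_track, read_tss_table
from ftcooc.motifscan import information_content
from ftcooc.synthetic_cortex import (
    SyntheticConfig,
    design_truth,
    emit_dataset,
    generate,
    simulate_cut_track,
)


class TestConfig:
    def test_defaults_valid(self):
        cfg = SyntheticConfig()
        assert cfg.footprint_depletion < 1 < cfg.flank_boost
        assert len(cfg.tf_names) == 12

    def test_duplicate_tf_names_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(focal_tf="X", partner_tf="X")

    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(co_subset_frac=1.5)

    def test_depletion_boost_ordering_enforced(self):
        with pytest.raises(ValueError):
            SyntheticConfig(footprint_depletion=1.2)

    def test_chromosome_too_short_rejected(self):
        with pytest.raises(ValueError, match="chromosome too short"):
            design_truth(SyntheticConfig(n_genes=100, chrom_length=100_000))

    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text(
            "n_genes: 10\nchrom_length: 300000\nseed: 3\n"
            "ages: [P0, adult]\nbackground_tfs: [B1, B2]\n"
        )
        cfg = SyntheticConfig.from_yaml(p)
        assert cfg.n_genes == 10 and cfg.background_tfs == ("B1", "B2")


class TestDesignTruth:
    def test_deterministic(self, small_config):
        t1 = design_truth(small_config)
        t2 = design_truth(small_config)
        assert [s.interval for s in t1.sites] == [s.interval for s in t2.sites]
        assert [s.bound for s in t1.sites] == [s.bound for s in t2.sites]
        assert t1.growth_relevant == t2.growth_relevant

    def test_regions_disjoint(self, small_truth):
        ivs = sorted(
            (r.interval.start, r.interval.end) for r in small_truth.regions
        )
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 <= s2

    def test_promoter_width(self, small_truth):
        cfg = small_truth.config
        for r in small_truth.regions:
            if r.kind == "promoter":
                assert len(r.interval) == cfg.promoter_up + cfg.promoter_down

    def test_every_site_inside_exactly_one_region(self, small_truth):
        regions = {r.region_id: r.interval for r in small_truth.regions}
        for s in small_truth.sites:
            host = regions[s.region_id]
            assert host.contains(s.interval)
            n_hosting = sum(1 for iv in regions.values() if iv.contains(s.interval))
            assert n_hosting == 1

    def test_pwms_are_specific(self, small_truth):
        for pwm in small_truth.pwms.values():
            assert information_content(pwm)[0] >= 8.0

    def test_degenerate_probabilities(self):
        """marginal 1 everywhere and rho 1: every region with sites for both
        TFs is co-occupied."""
        cfg = SyntheticConfig(
            n_genes=60,
            chrom_length=1_500_000,
            focal_bind_prob=1.0,
            partner_bind_prob=1.0,
            background_bind_prob=1.0,
            rho_co=1.0,
            seed=5,
        )
        truth = design_truth(cfg)
        age = cfg.ages[0]
        assert all(s.bound[age] for s in truth.sites)
        occ = truth.region_occupancy(age)
        focal_sited = {s.region_id for s in truth.sites_for(cfg.focal_tf)}
        partner_sited = {s.region_id for s in truth.sites_for(cfg.partner_tf)}
        co = {r for r, tfs in occ.items() if cfg.focal_tf in tfs and cfg.partner_tf in tfs}
        assert co == focal_sited & partner_sited

    def test_null_rho_matches_background_cooccupancy(self):
        """With rho_co at the partner marginal, focal-partner co-occupancy
        matches focal-background co-occupancy within binomial error over
        >= 2000 regions (law of large numbers against the generator)."""
        cfg = SyntheticConfig(
            n_genes=2000,
            n_enhancers=0,
            promoter_up=150,
            promoter_down=50,
            chrom_length=2_000_000,
            site_margin=0,
            partner_bind_prob=0.1,
            background_bind_prob=0.1,
            rho_co=0.1,
            seed=11,
        )
        truth = design_truth(cfg)
        age = cfg.ages[0]
        occ = truth.region_occupancy(age)
        focal = {r for r, tfs in occ.items() if cfg.focal_tf in tfs}
        n = len(focal)
        partner_rate = sum(1 for r in focal if cfg.partner_tf in occ[r]) / n
        bg_rates = [
            sum(1 for r in focal if tf in occ[r]) / n for tf in cfg.background_tfs
        ]
        p = np.mean(bg_rates)
        # three binomial sigmas over the focal-region count
        sigma = math.sqrt(p * (1 - p) / n)
        assert abs(partner_rate - p) < 3 * sigma + 1e-9


class TestSimulateCutTrack:
    def test_zero_rate_gives_zero_track(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config, background_cut_rate=0.0)
        truth = design_truth(cfg)
        track = simulate_cut_track(truth, cfg, cfg.ages[0])
        assert track[cfg.chrom].sum() == 0

    def test_bound_cores_depleted_vs_unbound(self, small_dataset):
        truth, tracks = small_dataset
        cfg = truth.config
        age = cfg.ages[0]
        vec = tracks[age][cfg.chrom]
        bound_means, unbound_means = [], []
        for s in truth.sites:
            core = vec[s.interval.start : s.interval.end].mean()
            (bound_means if s.bound[age] else unbound_means).append(core)
        assert len(bound_means) >= 200 or len(unbound_means) >= 200
        assert np.mean(bound_means) < np.mean(unbound_means)

    def test_peak_fold_moment_check(self, small_dataset):
        truth, tracks = small_dataset
        cfg = truth.config
        vec = tracks[cfg.ages[0]][cfg.chrom]
        in_region = np.zeros(cfg.chrom_length, dtype=bool)
        for r in truth.regions:
            in_region[r.interval.start : r.interval.end] = True
        ratio = vec[in_region].mean() / vec[~in_region].mean()
        assert ratio == pytest.approx(cfg.peak_fold, rel=0.10)

    def test_deterministic(self, small_config):
        truth = design_truth(small_config)
        t1 = simulate_cut_track(truth, small_config, "P0")
        t2 = simulate_cut_track(truth, small_config, "P0")
        assert t1 == t2

    def test_ages_differ(self, small_dataset):
        truth, tracks = small_dataset
        cfg = truth.config
        assert not (tracks["P0"] == tracks["adult"])

    def test_unknown_age_rejected(self, small_config):
        truth = design_truth(small_config)
        with pytest.raises(ValueError):
            simulate_cut_track(truth, small_config, "nope")


class TestEmitDataset:
    def test_round_trip_and_conservation(self, tmp_path, small_dataset):
        truth, tracks = small_dataset
        cfg = truth.config
        paths = emit_dataset(truth, tracks, tmp_path / "d")
        sizes = read_chrom_sizes(paths["chrom_sizes"])
        assert sizes == {cfg.chrom: cfg.chrom_length}

        tss = read_tss_table(paths["tss"])
        assert tss == truth.tss

        enh = read_bed(paths["enhancers"])
        expected = [r.interval for r in truth.regions if r.kind == "enhancer"]
        assert [(e.chrom, e.start, e.end) for e in enh] == [
            (e.chrom, e.start, e.end) for e in expected
        ]

        for age in cfg.ages:
            back = read_cut_track(paths[f"cuts_{age}"], sizes)
            assert back == tracks[age]

        n_rows = len(paths["truth_sites"].read_text().splitlines()) - 1
        assert n_rows == len(truth.sites)

    def test_byte_identical_regeneration(self, tmp_path, small_config):
        outs = []
        for sub in ("a", "b"):
            truth, tracks = generate(small_config)
            paths = emit_dataset(truth, tracks, tmp_path / sub, with_fasta=True)
            outs.append(paths)
        for key in outs[0]:
            assert outs[0][key].read_bytes() == outs[1][key].read_bytes(), key

    def test_fasta_contains_planted_consensus(self, tmp_path, small_dataset):
        from ftcooc.formats_io import read_fasta
        from ftcooc.motifscan import reverse_complement

        truth, tracks = small_dataset
        paths = emit_dataset(truth, tracks, tmp_path / "f", with_fasta=True)
        genome = read_fasta(paths["genome"])
        seq = genome[truth.config.chrom]
        checked = 0
        for s in truth.sites[:50]:
            window = seq[s.interval.start : s.interval.end]
            consensus = truth.pwms[s.tf_name].consensus
            if s.interval.strand == "-":
                consensus = reverse_complement(consensus)
            # overlapping sites of different TFs may overwrite each other
            if window == consensus:
                checked += 1
        assert checked >= 40
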