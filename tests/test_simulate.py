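"""Synthetic-data generator: determinism, geometry and rate recovery."""

import numpy as np
import pandas as pd
import pytest

from nucmeth import simulate
from nucmeth.errors import InvalidConfigError
from nucmeth.simulate import ContextRates, SimulationConfig


class TestConfigValidation:
    def test_rejects_zero_chromosomes(self):
        config = SimulationConfig(seed=1, chrom_sizes={})
        with pytest.raises(InvalidConfigError, match="chromosome"):
            simulate.generate_layout(config)

    def test_rejects_short_chromosome(self):
        config = SimulationConfig(seed=1, chrom_sizes={"chr1": 5_000})
        with pytest.raises(InvalidConfigError, match="10 kb"):
            simulate.generate_layout(config)

    @pytest.mark.parametrize("kwargs", [
        {"feature_fractions": {"het_TE": 0.7, "gene": 0.5}},
        {"positioning_sd": {"het_TE": -1.0}},
        {"context_probs": {"CG": 0.5, "CHG": 0.2, "CHH": 0.2}},
        {"rotational_period": 0.0},
    ])
    def test_rejects_invalid_values(self, kwargs):
        with pytest.raises(InvalidConfigError):
            SimulationConfig(seed=1, **kwargs)

    def test_rotational_amplitude_bounded_by_core_rate(self):
        with pytest.raises(InvalidConfigError, match="amplitude"):
            ContextRates(0.95, 0.9, rotational_amplitude=0.1).validate()


class TestLayout:
    def test_seeded_determinism(self):
        config = SimulationConfig(seed=1, chrom_sizes={"chr1": 50_000})
        first = simulate.generate_layout(config)
        second = simulate.generate_layout(config)
        pd.testing.assert_frame_equal(first.features, second.features)
        pd.testing.assert_frame_equal(first.gene_parts, second.gene_parts)

    def test_zero_gene_fraction_yields_no_genes(self):
        config = SimulationConfig(
            seed=1, chrom_sizes={"chr1": 50_000},
            feature_fractions={"het_TE": 0.4, "eu_TE": 0.1, "gene": 0.0},
        )
        layout = simulate.generate_layout(config)
        assert not (layout.features["feature_class"] == "gene").any()
        assert layout.gene_parts.empty

    def test_all_classes_present_by_default(self, small_layout):
        assert set(small_layout.features["feature_class"]) == {
            "het_TE", "eu_TE", "gene"}

    def test_features_within_chromosome_bounds(self, small_layout):
        size = small_layout.chrom_sizes["chr1"]
        assert (small_layout.features["start"] >= 0).all()
        assert (small_layout.features["end"] <= size).all()

    def test_exons_and_introns_tile_each_gene(self, small_layout):
        # interval-union oracle: sorted parts must chain start-to-end
        genes = small_layout.features[
            small_layout.features["feature_class"] == "gene"]
        for gene in genes.itertuples(index=False):
            parts = small_layout.gene_parts[
                small_layout.gene_parts["gene_id"] == gene.feature_id
            ].sort_values("start")
            assert parts.iloc[0]["start"] == gene.start
            assert parts.iloc[-1]["end"] == gene.end
            assert (parts["end"].iloc[:-1].to_numpy()
                    == parts["start"].iloc[1:].to_numpy()).all()
            kinds = parts["kind"].tolist()
            assert kinds[::2] == ["exon"] * len(kinds[::2])
            assert kinds[1::2] == ["intron"] * len(kinds[1::2])


class TestTrueNucleosomes:
    def test_zero_linker_noise_gives_exact_spacing(self):
        config = SimulationConfig(seed=1, chrom_sizes={"chr1": 50_000},
                                  linker_length_mean=30, linker_length_sd=0)
        layout = simulate.generate_layout(config)
        nmap = simulate.simulate_true_nucleosomes(layout, config)
        spacing = np.diff(nmap.for_chrom("chr1"))
        assert (spacing == 177).all()

    def test_dyad_count_matches_tiling(self):
        config = SimulationConfig(seed=2, chrom_sizes={"chr1": 50_000},
                                  linker_length_mean=30, linker_length_sd=0)
        layout = simulate.generate_layout(config)
        nmap = simulate.simulate_true_nucleosomes(layout, config)
        assert abs(len(nmap.dyads) - 50_000 // 177) <= 2

    def test_spacing_at_least_core_length(self, small_nmap):
        spacing = np.diff(small_nmap.for_chrom("chr1"))
        assert (spacing >= 147).all()

    def test_seeded_determinism(self, small_config, small_layout):
        first = simulate.simulate_true_nucleosomes(small_layout, small_config)
        second = simulate.simulate_true_nucleosomes(small_layout, small_config)
        pd.testing.assert_frame_equal(first.dyads, second.dyads)

    def test_nonpositive_linker_mean_rejected(self, small_layout):
        config = SimulationConfig(seed=1, chrom_sizes={"chr1": 50_000},
                                  linker_length_mean=-200)
        with pytest.raises(InvalidConfigError, match="linker"):
            simulate.simulate_true_nucleosomes(small_layout, config)


class TestFragments:
    def test_zero_noise_midpoints_hit_dyads(self, small_layout):
        config = SimulationConfig(
            seed=1, chrom_sizes={"chr1": 60_000},
            positioning_sd={"het_TE": 0, "eu_TE": 0, "gene": 0,
                            "intergenic": 0},
            fragment_length_dist={147: 1.0},
        )
        nmap = simulate.simulate_true_nucleosomes(small_layout, config)
        frags = simulate.simulate_fragments(nmap, config, 1)[0]
        mids = ((frags["start"] + frags["end"]) // 2).to_numpy()
        assert np.isin(mids, nmap.dyads["dyad"].to_numpy()).all()

    def test_replicates_are_independent(self, small_fragments):
        rep1, rep2 = small_fragments
        assert not rep1.equals(rep2)

    def test_replicates_deterministic(self, small_config, small_nmap):
        again = simulate.simulate_fragments(small_nmap, small_config, 2)
        for a, b in zip(again, [*again]):
            pd.testing.assert_frame_equal(a, b)

    def test_midpoint_jitter_matches_configured_sd(self):
        # Monte-Carlo check against the Normal positioning model
        config = SimulationConfig(seed=3, chrom_sizes={"chr1": 50_000},
                                  positioning_sd={"intergenic": 5.0},
                                  coverage_mean=10_000.0)
        nmap = simulate.TrueNucleosomeMap(
            pd.DataFrame({"chrom": ["chr1"], "dyad": [25_000],
                          "feature_class": ["intergenic"]}))
        frags = simulate.simulate_fragments(nmap, config, 1)[0]
        mids = ((frags["start"] + frags["end"]) // 2).to_numpy()
        assert abs(mids.std() - 5.0) < 0.2

    def test_empty_map_gives_empty_output(self, small_config):
        empty = simulate.TrueNucleosomeMap(
            pd.DataFrame(columns=["chrom", "dyad", "feature_class"]))
        frags = simulate.simulate_fragments(empty, small_config, 1)[0]
        assert frags.empty


class TestMethylome:
    def test_unknown_genotype_names_available(self, small_config,
                                              small_layout, small_nmap):
        with pytest.raises(InvalidConfigError, match="h1ddm1"):
            simulate.simulate_methylome(small_layout, small_nmap, "met1",
                                        small_config)

    def test_zero_coverage_gives_empty_records(self, small_layout,
                                               small_nmap):
        config = SimulationConfig(seed=1, chrom_sizes={"chr1": 60_000},
                                  coverage_mean=0.0)
        records = simulate.simulate_methylome(small_layout, small_nmap, "WT",
                                              config)
        assert records.empty

    def test_context_partition(self, wt_records):
        assert set(wt_records["context"]) <= {"CG", "CHG", "CHH"}
        assert (wt_records["count_meth"]
                <= wt_records["count_total"]).all()
        assert (wt_records["count_total"] > 0).all()

    def test_sites_shared_across_genotypes(self, wt_records, h1ddm1_records):
        key = ["chrom", "pos", "strand"]
        merged = wt_records.merge(h1ddm1_records, on=key, how="inner")
        # contexts are a property of the site, not the genotype
        assert (merged["context_x"] == merged["context_y"]).all()

    def test_seeded_determinism(self, small_config, small_layout,
                                small_nmap, wt_records):
        again = simulate.simulate_methylome(small_layout, small_nmap, "WT",
                                            small_config)
        pd.testing.assert_frame_equal(wt_records, again)

    def test_core_and_linker_rate_recovery(self):
        # law-of-large-numbers recovery of configured rates
        params = {"WT": {
            "CG": ContextRates(0.2, 0.8, 0.0),
            "CHG": ContextRates(0.2, 0.8, 0.0),
            "CHH": ContextRates(0.2, 0.8, 0.0),
        }}
        config = SimulationConfig(seed=4, chrom_sizes={"chr1": 300_000},
                                  genotype_params=params)
        layout = simulate.generate_layout(config)
        nmap = simulate.simulate_true_nucleosomes(layout, config)
        records = simulate.simulate_methylome(layout, nmap, "WT", config)
        cg = records[records["context"] == "CG"]
        dyads = nmap.for_chrom("chr1")
        offsets = simulate._nearest_dyad_offset(cg["pos"].to_numpy(), dyads)
        core = np.abs(offsets) <= 73
        core_rate = cg[core]["count_meth"].sum() / cg[core]["count_total"].sum()
        link_rate = (cg[~core]["count_meth"].sum()
                     / cg[~core]["count_total"].sum())
        assert abs(core_rate - 0.2) < 0.02
        assert abs(link_rate - 0.8) < 0.02

    def test_rate_recovery_tightens_with_coverage(self):
        # empirical error at high coverage <= error at low coverage (+ slack)
        errors = {}
        for cov in (2.0, 50.0):
            config = SimulationConfig(seed=5, chrom_sizes={"chr1": 100_000},
                                      coverage_mean=cov)
            layout = simulate.generate_layout(config)
            nmap = simulate.simulate_true_nucleosomes(layout, config)
            records = simulate.simulate_methylome(layout, nmap, "ddm1",
                                                  config)
            cg = records[records["context"] == "CG"]
            offs = simulate._nearest_dyad_offset(cg["pos"].to_numpy(),
                                                 nmap.for_chrom("chr1"))
            core = cg[np.abs(offs) <= 73]
            rate = core["count_meth"].sum() / core["count_total"].sum()
            errors[cov] = abs(rate - 0.25)
        assert errors[50.0] <= errors[2.0] + 0.005


class TestDmrStudyGenerator:
    def test_regions_are_grid_aligned_and_disjoint(self):
        study = simulate.simulate_dmr_study(seed=1, n_planted=10, n_decoys=10)
        regions = pd.concat([study.planted, study.decoys]).sort_values("start")
        assert (regions["start"] % 50 == 0).all()
        assert (regions["start"].iloc[1:].to_numpy()
                >= regions["end"].iloc[:-1].to_numpy()).all()
        assert len(study.planted) == 10 and len(study.decoys) == 10

    def test_planted_loss_is_focal_only(self):
        study = simulate.simulate_dmr_study(seed=1, n_planted=10, n_decoys=10)

        def region_fraction(records, regions):
            mask = np.zeros(len(records), bool)
            pos = records["pos"].to_numpy()
            for row in regions.itertuples(index=False):
                mask |= (pos >= row.start) & (pos < row.end)
            sub = records[mask]
            return sub["count_meth"].sum() / sub["count_total"].sum()

        wt = region_fraction(study.records["WT"], study.planted)
        mut = region_fraction(study.records["cmt2"], study.planted)
        other = region_fraction(study.records["drm1drm2"], study.planted)
        assert abs(wt - 0.25) < 0.03
        assert abs(mut - 0.05) < 0.03
        assert abs(other - 0.25) < 0.03

    def test_decoys_lose_in_both_mutants(self):
        study = simulate.simulate_dmr_study(seed=1, n_planted=10, n_decoys=10)
        for genotype in ("cmt2", "drm1drm2"):
            records = study.records[genotype]
            mask = np.zeros(len(records), bool)
            pos = records["pos"].to_numpy()
            for row in study.decoys.itertuples(index=False):
                mask |= (pos >= row.start) & (pos < row.end)
            sub = records[mask]
            frac = sub["count_meth"].sum() / sub["count_total"].sum()
            assert abs(frac - 0.05) < 0.03


class TestTeScores:
    def test_het_tes_score_high(self, small_config, small_layout):
        tes = simulate.simulate_te_scores(small_layout, small_config)
        het = tes[tes["feature_class"] == "het_TE"]
        eu = tes[tes["feature_class"] == "eu_TE"]
        assert het["h3k9me2"].min() > eu["h3k9me2"].max()
        assert (het["mcg"] > 0.05).all()
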