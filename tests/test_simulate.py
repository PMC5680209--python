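"""Synthetic-data generators: expectation models, count identities,
Monte-Carlo calibration and reproducibility."""

import numpy as np
import pytest

from panelvar import (
    SimulationConfig, dilute_in_silico, downsample_site, expected_somatic_vaf,
    simulate_exon_depth_matrix, simulate_mixture_vafs, simulate_normal_cohort,
    simulate_snp_pileups, simulate_split_reads, simulate_tumor_pileups,
)
from conftest import make_site


class TestExpectedSomaticVaf:
    @pytest.mark.parametrize("purity,c,X,Y,expected", [
        (1.0, 1.0, 2, 1, 0.5),    # pure tumor, clonal het
        (0.5, 1.0, 2, 1, 0.25),   # half purity halves the het VAF
        (0.0, 1.0, 2, 1, 0.0),    # no tumor, no variant reads
        (0.8, 0.5, 2, 1, 0.2),    # subclone at half the cancer cells
    ])
    def test_allele_accounting(self, purity, c, X, Y, expected):
        assert expected_somatic_vaf(purity, c, X, Y) == pytest.approx(expected)


class TestTumorPileups:
    def test_count_identities_hold_for_every_site(self):
        config = SimulationConfig(n_sites=300, depth_mean=800, seed=3,
                                  purity=0.6, copy_states=((2, 1), (2, 0)))
        for s in simulate_tumor_pileups(config):
            assert 0 <= s.alt_count <= s.depth
            assert s.alt_fwd + s.alt_rev == s.alt_count
            assert s.ref_fwd + s.ref_rev == s.depth - s.alt_count
            assert len(s.alt_read_offsets) == s.alt_count

    def test_mean_vaf_tracks_purity_expectation(self):
        config = SimulationConfig(n_sites=2000, depth_mean=1000, seed=5,
                                  purity=0.5)
        sites = simulate_tumor_pileups(config)
        vafs = np.array([s.vaf for s in sites])
        se = vafs.std(ddof=1) / np.sqrt(len(vafs))
        # eps/3 error contribution shifts the expectation slightly upward
        expected = 0.25 * (1 - 0.001) + 0.75 * 0.001 / 3
        assert abs(vafs.mean() - expected) < 3 * se

    def test_non_variant_sites_accumulate_only_error_reads(self):
        config = SimulationConfig(n_sites=2000, depth_mean=1000, seed=9,
                                  copy_states=((2, 0),))
        sites = simulate_tumor_pileups(config)
        total_alt = sum(s.alt_count for s in sites)
        total_depth = sum(s.depth for s in sites)
        rate = total_alt / total_depth
        se = np.sqrt(rate * (1 - rate) / total_depth)
        assert abs(rate - 0.001 / 3) < 4 * se + 1e-6

    def test_bit_reproducible_given_config(self):
        config = SimulationConfig(n_sites=50, seed=42)
        assert simulate_tumor_pileups(config) == simulate_tumor_pileups(config)

    @pytest.mark.parametrize("kwargs", [
        {"n_sites": 0}, {"depth_mean": -5.0}, {"base_error_rate": 0.5},
        {"purity": 1.5}, {"dedup_fraction": 0.0}, {"clone_fractions": (0.0,)},
        {"copy_states": ((2, 3),)}, {"depth_mean": float("nan")},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**{"n_sites": 10, **kwargs})


class TestDilution:
    def test_conversion_probability_is_one_minus_ratio(self):
        # VAF 0.50 diluted to 0.02: each alt read survives w.p. 0.04
        sites = [make_site(1000, 500, pos=p) for p in range(1, 2001)]
        diluted = dilute_in_silico(sites, 0.02, seed=8)
        kept = np.array([s.alt_count for s in diluted])
        expected = 500 * 0.04
        se = np.sqrt(500 * 0.04 * 0.96) / np.sqrt(len(sites))
        assert abs(kept.mean() - expected) < 3 * se

    def test_target_equal_to_observed_leaves_site_unchanged(self):
        site = make_site(1000, 500)
        (out,) = dilute_in_silico([site], 0.5, seed=1)
        assert (out.alt_count, out.alt_fwd, out.alt_rev) == (500, 250, 250)
        assert out.depth == 1000

    def test_depth_unchanged_and_strands_consistent(self):
        sites = [make_site(1200, 600, alt_fwd=400, pos=p)
                 for p in range(1, 301)]
        for s in dilute_in_silico(sites, 0.05, seed=2):
            assert s.depth == 1200
            assert s.alt_fwd + s.alt_rev == s.alt_count
            assert s.ref_fwd + s.ref_rev == s.depth - s.alt_count
            assert s.true_vaf == pytest.approx(s.vaf)

    def test_mean_realized_vaf_matches_target(self):
        # Monte-Carlo calibration over >= 1000 sites
        sites = [make_site(1500, 750, pos=p) for p in range(1, 1201)]
        realized = np.array([s.vaf for s in dilute_in_silico(sites, 0.03,
                                                             seed=4)])
        se = realized.std(ddof=1) / np.sqrt(len(realized))
        assert abs(realized.mean() - 0.03) < 3 * se

    def test_target_above_observed_rejected(self):
        with pytest.raises(ValueError, match="exceeds observed"):
            dilute_in_silico([make_site(1000, 10)], 0.5)


class TestDownsample:
    def test_expectation_preserved(self):
        # E[alt'] = alt * d'/d, checked over 10,000 repetitions
        site = make_site(1500, 52)
        draws = np.array([downsample_site(site, 100, seed=s).alt_count
                          for s in range(10_000)])
        expected = 52 * 100 / 1500  # ~= 3.47
        # hypergeometric variance
        var = 100 * (52 / 1500) * (1 - 52 / 1500) * (1500 - 100) / 1499
        assert abs(draws.mean() - expected) < 3 * np.sqrt(var / len(draws))

    def test_identity_at_full_depth(self):
        site = make_site(500, 100)
        assert downsample_site(site, 500, seed=0) == site

    def test_zero_alt_stays_zero(self):
        for seed in range(20):
            assert downsample_site(make_site(1000, 0), 50,
                                   seed=seed).alt_count == 0

    def test_alt_bounded_by_min(self):
        site = make_site(200, 150)
        for seed in range(20):
            out = downsample_site(site, 40, seed=seed)
            assert out.alt_count <= min(150, 40)
            assert out.depth == 40
            assert out.alt_fwd + out.alt_rev == out.alt_count

    def test_target_above_depth_rejected(self):
        with pytest.raises(ValueError):
            downsample_site(make_site(100, 10), 200)


class TestNormalCohort:
    def test_cohort_af_matches_injected_frequency(self):
        cohort = simulate_normal_cohort(
            400, [{"chrom": "chr1", "pos": 10, "ref": "A", "alt": "G",
                   "pop_af": 0.5}], seed=7)
        af = cohort.allele_frequency[0]
        se = np.sqrt(0.5 * 0.5 / (2 * 400))
        assert abs(af - 0.5) < 3 * se
        assert cohort.n_samples == 400

    def test_af_identity(self):
        cohort = simulate_normal_cohort(
            50, [{"chrom": "1", "pos": i, "ref": "A", "alt": "T",
                  "pop_af": af} for i, af in enumerate([0.1, 0.9], 1)],
            seed=1)
        np.testing.assert_allclose(
            cohort.allele_frequency,
            cohort.genotypes.sum(axis=0) / (2 * cohort.n_samples))
        assert ((cohort.allele_frequency >= 0)
                & (cohort.allele_frequency <= 1)).all()

    def test_zero_pop_af_gives_zero_cohort_af(self):
        cohort = simulate_normal_cohort(
            20, [{"chrom": "1", "pos": 5, "ref": "C", "alt": "T",
                  "pop_af": 0.0}], seed=3)
        assert cohort.allele_frequency[0] == 0.0

    def test_empty_site_spec_rejected(self):
        with pytest.raises(ValueError):
            simulate_normal_cohort(10, [], seed=0)


class TestMixtureVafs:
    def test_equal_ten_line_pool(self):
        # het in one line -> 5%; hom in one line -> 10%; het in all -> 50%
        G = np.zeros((10, 3), dtype=int)
        G[0, 0] = 1
        G[0, 1] = 2
        G[:, 2] = 1
        vafs = simulate_mixture_vafs(G, [0.1] * 10)
        np.testing.assert_allclose(vafs, [0.05, 0.10, 0.50])

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError, match="dosages"):
            simulate_mixture_vafs(np.array([[3]]), [1.0])
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_mixture_vafs(np.array([[1]]), [0.5])


class TestExonDepthMatrix:
    def test_expected_ratios_noise_free(self):
        df = simulate_exon_depth_matrix({"DIPLOID": 2, "AMP": 6, "DEL": 0},
                                        purity=0.5, noise_cv=0.0, seed=0,
                                        n_normals=4)
        normals = df[[c for c in df.columns if c.startswith("normal")]]
        ratio = df["tumor"] / normals.median(axis=1)
        assert ratio.loc["DIPLOID"].values == pytest.approx(1.0)
        assert ratio.loc["AMP"].values == pytest.approx(2.0)  # (0.5*6+1)/2
        assert ratio.loc["DEL"].values == pytest.approx(0.5)  # (0+1)/2

    def test_homozygous_deletion_at_full_purity(self):
        df = simulate_exon_depth_matrix({"GONE": 0}, purity=1.0,
                                        noise_cv=0.0, seed=0)
        assert (df["tumor"] == 0).all()

    def test_negative_cv_rejected(self):
        with pytest.raises(ValueError):
            simulate_exon_depth_matrix({"G": 2}, 1.0, -0.1)


class TestSplitReads:
    def test_side_split_and_counts(self):
        reads = simulate_split_reads([{
            "name": "F1", "chrom_a": "chr2", "pos_a": 100, "chrom_b": "chr5",
            "pos_b": 900, "n_left": 3, "n_right": 2}], seed=0)
        assert len(reads) == 5
        assert sum(r.side == "left" for r in reads) == 3
        assert sum(r.side == "right" for r in reads) == 2

    def test_secondary_alignments_flagged(self):
        reads = simulate_split_reads([{
            "name": "F1", "chrom_a": "1", "pos_a": 10, "chrom_b": "2",
            "pos_b": 20, "n_left": 2, "n_right": 3, "n_secondary": 2}],
            seed=0)
        assert sum(r.is_secondary for r in reads) == 2

    def test_zero_support_and_bad_spec(self):
        assert simulate_split_reads([{
            "name": "F", "chrom_a": "1", "pos_a": 1, "chrom_b": "2",
            "pos_b": 2, "n_left": 0, "n_right": 0}]) == []
        with pytest.raises(ValueError):
            simulate_split_reads([{"name": "broken"}])


class TestSnpPileups:
    def test_neutral_het_snps_center_on_half_at_any_purity(self):
        for purity in (0.3, 1.0):
            sites = simulate_snp_pileups(
                purity, [{"chrom": "seg1", "n_snps": 400, "X": 2, "Y": 1}],
                seed=21)
            vafs = np.array([s.vaf for s in sites])
            assert abs(vafs.mean() - 0.5) < 3 * vafs.std() / 20

    def test_segment_coverage_scales_with_copy_mass(self):
        segs = [{"chrom": "neutral", "n_snps": 300, "X": 2, "Y": 1},
                {"chrom": "gain", "n_snps": 300, "X": 4, "Y": 3}]
        sites = simulate_snp_pileups(1.0, segs, depth_mean=1000, seed=2)
        by_seg = {}
        for s in sites:
            by_seg.setdefault(s.chrom, []).append(s.depth)
        ratio = np.mean(by_seg["gain"]) / np.mean(by_seg["neutral"])
        assert ratio == pytest.approx(2.0, rel=0.1)
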