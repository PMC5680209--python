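"""Detection rule, artifact features, logistic FP filter and filter stack."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln
from scipy.stats import binom

from panelvar import (
    DetectionModel, VariantCall, apply_filters,
    classify_tier, compute_fp_features, detect_site, simulate_normal_cohort,
    train_fp_filter,
)
from panelvar.detect import strand_bias_score
from conftest import make_site


class TestDetectSite:
    def test_strong_low_vaf_signal_called(self):
        # 20/1000 at eps=0.001: error tail far below alpha
        assert binom.sf(19, 1000, 0.001 / 3) < 1e-20
        call = detect_site(make_site(1000, 20), DetectionModel())
        assert call is not None and call.vaf == pytest.approx(0.02)

    def test_below_min_alt_reads_not_called(self):
        assert detect_site(make_site(1000, 3), DetectionModel()) is None

    def test_error_plausible_counts_not_called_at_extreme_depth(self):
        # at 100,000x the error model expects ~33 alt reads; 4 is noise
        assert detect_site(make_site(100_000, 4), DetectionModel()) is None

    def test_zero_depth_never_called(self):
        assert detect_site(make_site(0, 0), DetectionModel()) is None

    def test_min_vaf_floor(self):
        model = DetectionModel(min_vaf=0.05)
        assert detect_site(make_site(1000, 20), model) is None
        assert detect_site(make_site(1000, 60), model) is not None

    def test_required_alt_reads_is_exact_binomial_threshold(self):
        model = DetectionModel()
        p = model.error_rate / 3
        for depth in (50, 200, 1000, 5000, 20_000):
            a = model.required_alt_reads(depth)
            assert binom.sf(a - 1, depth, p) < model.alpha
            if a > model.min_alt_reads:
                assert binom.sf(a - 2, depth, p) >= model.alpha

    @settings(max_examples=60, deadline=None)
    @given(depth=st.integers(10, 5000), alt=st.integers(0, 200),
           extra=st.integers(1, 50))
    def test_monotone_in_alt_reads(self, depth, alt, extra):
        """Adding alt reads at fixed depth never turns a call into no-call."""
        alt = min(alt, depth)
        model = DetectionModel()
        before = detect_site(make_site(depth, alt), model)
        if before is not None:
            after = detect_site(make_site(depth, min(alt + extra, depth)),
                                model)
            assert after is not None


def fisher_two_sided_bruteforce(table) -> float:
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d

    def log_hyper(x):
        return (gammaln(row1 + 1) - gammaln(x + 1) - gammaln(row1 - x + 1)
                + gammaln(n - row1 + 1) - gammaln(col1 - x + 1)
                - gammaln(n - row1 - col1 + x + 1)
                - (gammaln(n + 1) - gammaln(col1 + 1) - gammaln(n - col1 + 1)))

    lo, hi = max(0, col1 - (n - row1)), min(row1, col1)
    probs = {x: math.exp(log_hyper(x)) for x in range(lo, hi + 1)}
    cutoff = probs[a] * (1 + 1e-7)
    return min(1.0, sum(p for p in probs.values() if p <= cutoff))


class TestStrandBias:
    def test_balanced_strands_score_zero(self):
        assert strand_bias_score(50, 50, 10, 10) == 0.0

    def test_one_sided_alt_matches_bruteforce_oracle(self):
        p = fisher_two_sided_bruteforce([[50, 50], [10, 0]])
        assert strand_bias_score(50, 50, 10, 0) == pytest.approx(
            -math.log10(p), rel=1e-9)

    def test_matches_bruteforce_on_small_margin_tables(self):
        """Fisher score equals exhaustive enumeration for margins <= 30."""
        cells = [0, 1, 3, 7, 15]
        for a, b, c, d in itertools.product(cells, repeat=4):
            if a + b == 0 or c + d == 0 or max(a + b, c + d) > 30:
                continue
            expected = fisher_two_sided_bruteforce([[a, b], [c, d]])
            got = strand_bias_score(a, b, c, d)
            assert got == pytest.approx(
                0.0 if expected >= 1 else -math.log10(expected), abs=1e-6)


class TestFeatures:
    def test_clean_context_gives_zero_context_features(self):
        fv = compute_fp_features(make_site(100, 10, pos=500))
        assert fv.indel_proximity == 0.0
        assert fv.neighborhood_mutation_count == 0.0

    def test_windows_respected(self):
        site = make_site(100, 10, pos=500)
        fv = compute_fp_features(site, indel_positions=[520, 600],
                                 candidate_positions=[500, 540, 560])
        assert fv.indel_proximity == 1.0       # 520 within 25 bp
        assert fv.neighborhood_mutation_count == 1.0  # 540 only; 560 outside

    def test_clustered_offsets_score_higher(self):
        tight = make_site(100, 10, offsets=(40,) * 10)
        spread = make_site(100, 10, offsets=tuple(range(0, 100, 10)))
        f_tight = compute_fp_features(tight).read_position_clustering
        f_spread = compute_fp_features(spread).read_position_clustering
        assert f_tight == 1.0 > f_spread


class TestArtifactFilterTraining:
    def _features(self, rng, n, bias_scale):
        return pd.DataFrame({
            "indel_proximity": rng.integers(0, 2, n).astype(float),
            "neighborhood_mutation_count": rng.poisson(0.5, n).astype(float),
            "strand_bias_score": rng.exponential(bias_scale, n),
            "read_position_clustering": rng.uniform(0, 0.3, n),
        })

    def test_separable_data_gives_perfect_auc(self, rng):
        X = pd.concat([self._features(rng, 100, 0.1),
                       self._features(rng, 100, 0.1)], ignore_index=True)
        X.loc[100:, "strand_bias_score"] += 50.0  # artifacts cleanly separated
        res = train_fp_filter(X, [0] * 100 + [1] * 100, seed=0)
        assert res.auc == pytest.approx(1.0)
        assert res.regularized  # perfect separation must be flagged

    def test_permuted_labels_give_chance_auc(self, rng):
        X = self._features(rng, 400, 1.0)
        aucs = []
        for _ in range(20):
            y = rng.permutation([0] * 200 + [1] * 200)
            # cross-validated AUC: the training AUC is optimistically biased
            aucs.append(train_fp_filter(X, y, seed=0).cv_auc)
        se = np.std(aucs, ddof=1) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) < 3 * se + 0.01

    def test_recovers_informative_feature_sign(self, rng):
        # only strand bias carries signal; its weight must come out positive
        n = 600
        X = self._features(rng, n, 1.0)
        logit = -2.0 + 1.5 * X["strand_bias_score"]
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        res = train_fp_filter(X, y.astype(int), seed=1)
        assert res.weights["strand_bias_score"] > 0
        assert res.cv_auc > 0.6

    def test_single_class_rejected(self, rng):
        X = self._features(rng, 50, 1.0)
        with pytest.raises(ValueError, match="both classes"):
            train_fp_filter(X, [1] * 50)


def _call(depth, alt, pos, chrom="chr1"):
    return VariantCall(site=make_site(depth, alt, pos=pos, chrom=chrom),
                       vaf=alt / depth)


class TestFilterStack:
    def test_high_vaf_germline_rule_with_hotspot_exemption(self):
        calls = [_call(1000, 980, pos=100), _call(1000, 980, pos=200)]
        hotspots = [("chr1", 200, "C", "T")]
        report = apply_filters(calls, hotspots=hotspots)
        assert report.calls[0].filter_flags == {"germline_vaf"}
        assert report.calls[1].passes and report.calls[1].is_hotspot

    def test_pon_rule_strictly_above_three_percent(self):
        calls = [_call(1000, 100, pos=100), _call(1000, 100, pos=200)]
        cohort = {("chr1", 100, "C", "T"): 0.05, ("chr1", 200, "C", "T"): 0.03}
        report = apply_filters(calls, cohort_af=cohort)
        assert "pon" in report.calls[0].filter_flags
        assert report.calls[1].passes  # exactly 3% is kept (strict >)

    def test_blacklist_and_missing_cohort_positions(self):
        calls = [_call(500, 50, pos=300)]
        report = apply_filters(calls, blacklist=[("chr1", 300, "C", "T")])
        assert report.calls[0].filter_flags == {"blacklist"}
        # absent from cohort -> treated as AF 0 -> no pon flag
        assert "pon" not in report.calls[0].filter_flags

    def test_flags_commute(self):
        """The surviving set is identical whichever filters run first."""
        calls = [_call(1000, 980, pos=100), _call(1000, 100, pos=200),
                 _call(1000, 50, pos=300), _call(1000, 30, pos=400)]
        cohort = {("chr1", 200, "C", "T"): 0.2}
        black = [("chr1", 300, "C", "T")]
        full = apply_filters(calls, cohort_af=cohort, blacklist=black)
        only_germ = apply_filters(calls)
        only_pon = apply_filters(calls, cohort_af=cohort)
        only_black = apply_filters(calls, blacklist=black)
        intersect = {c.key for c in only_germ.surviving} \
            & {c.key for c in only_pon.surviving} \
            & {c.key for c in only_black.surviving}
        assert {c.key for c in full.surviving} == intersect

    def test_pon_removes_germline_keeps_somatic(self):
        """On a synthetic cohort, >= 90% of injected germline variants at
        population AF >= 5% are removed with zero somatic losses."""
        rng = np.random.default_rng(77)
        germline = [{"chrom": "chr1", "pos": 1000 + i, "ref": "A", "alt": "G",
                     "pop_af": af}
                    for i, af in enumerate(rng.uniform(0.05, 0.5, 60))]
        cohort = simulate_normal_cohort(400, germline, seed=78)
        germ_calls = [VariantCall(
            site=make_site(1000, 500, pos=1000 + i).__class__(
                chrom="chr1", pos=1000 + i, ref_base="A", alt_base="G",
                depth=1000, alt_count=500, alt_fwd=250, alt_rev=250,
                ref_fwd=250, ref_rev=250), vaf=0.5) for i in range(60)]
        som_calls = [_call(1000, 40, pos=5000 + i) for i in range(40)]
        report = apply_filters(germ_calls + som_calls,
                               cohort_af=cohort.af_lookup())
        germ_removed = sum("pon" in c.filter_flags
                           for c in report.calls[:60])
        som_removed = sum("pon" in c.filter_flags for c in report.calls[60:])
        assert germ_removed >= 0.9 * 60
        assert som_removed == 0


class TestTiers:
    tier1 = [("chr7", 55249071, "C", "T")]
    cosmic = [("chr7", 55249071, "C", "T"), ("chr12", 25398284, "C", "A")]

    def _call_at(self, chrom, pos, ref="C", alt="T"):
        site = make_site(1000, 100, pos=pos, chrom=chrom)
        site = site.__class__(chrom=chrom, pos=pos, ref_base=ref,
                              alt_base=alt, depth=1000, alt_count=100,
                              alt_fwd=50, alt_rev=50, ref_fwd=450,
                              ref_rev=450)
        return VariantCall(site=site, vaf=0.1)

    def test_actionable_is_tier1(self):
        call = self._call_at("chr7", 55249071)
        assert classify_tier(call, self.tier1, self.cosmic) == 1

    def test_cosmic_only_is_tier2(self):
        call = self._call_at("chr12", 25398284, alt="A")
        assert classify_tier(call, self.tier1, self.cosmic) == 2

    def test_everything_else_is_tier3(self):
        call = self._call_at("chr2", 1234)
        assert classify_tier(call, self.tier1, self.cosmic) == 3
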