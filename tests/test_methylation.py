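"""Profile binning, region means, group comparison, and positional analysis."""

import math

import numpy as np
import pytest
from scipy import stats

from mircircuit.io_formats import GenomicInterval, MethylationRecord
from mircircuit.methylation import (
    MethylationProfile,
    compare_groups,
    meth_expr_correlation,
    positional_difference,
    profile,
    rank_sum_test,
    region_mean,
)
from mircircuit.synthetic_data import TruthConfig, emit_methylation, generate_truth


def _profile(offsets, fractions, coverages, mirna_id="m"):
    return MethylationProfile(
        mirna_id, np.asarray(offsets, float), np.asarray(fractions, float),
        np.asarray(coverages, int),
    )


class TestProfile:
    def test_plus_strand_upstream_cpg(self):
        locus = GenomicInterval("m1", 10000, 10088, "m1", 0, "+")
        rec = MethylationRecord("m1", 9100, 8, 2)
        prof = profile(locus, [rec], window_bp=2000, bin_bp=100)
        idx = np.where(prof.offsets == -950)[0][0]
        assert prof.fractions[idx] == pytest.approx(0.8)
        assert prof.coverages[idx] == 10

    def test_minus_strand_orientation(self):
        # start site = end - 1 = 9999; CpG at 10900 is 901 bp upstream
        locus = GenomicInterval("m1", 9912, 10000, "m1", 0, "-")
        rec = MethylationRecord("m1", 10900, 5, 5)
        prof = profile(locus, [rec], window_bp=2000, bin_bp=100)
        idx = np.where(prof.offsets == -950)[0][0]
        assert prof.fractions[idx] == pytest.approx(0.5)

    def test_no_cpgs_all_bins_missing(self):
        locus = GenomicInterval("m1", 10000, 10088, "m1", 0, "+")
        prof = profile(locus, [], window_bp=2000, bin_bp=100)
        assert np.isnan(prof.fractions).all()
        assert len(prof.offsets) == 40

    def test_other_chromosome_ignored(self):
        locus = GenomicInterval("m1", 10000, 10088, "m1", 0, "+")
        rec = MethylationRecord("m2", 9100, 8, 2)
        prof = profile(locus, [rec], window_bp=2000, bin_bp=100)
        assert np.isnan(prof.fractions).all()

    def test_bin_width_validation(self):
        locus = GenomicInterval("m1", 10000, 10088, "m1", 0, "+")
        with pytest.raises(ValueError):
            profile(locus, [], window_bp=2000, bin_bp=0)
        with pytest.raises(ValueError, match="divisible"):
            profile(locus, [], window_bp=2000, bin_bp=300)

    def test_strand_reflection_invariance(self):
        """Reflecting coordinates and flipping strand preserves the profile."""
        contig_len = 20000
        rng = np.random.default_rng(7)
        records = [
            MethylationRecord("m1", int(p), int(m), int(10 - m))
            for p, m in zip(
                rng.integers(8000, 12000, size=50),
                rng.integers(1, 10, size=50),
            )
        ]
        plus = GenomicInterval("m1", 10000, 10088, "m1", 0, "+")
        # reflect: pos -> contig_len - 1 - pos; the start site maps to the
        # end of the reflected locus and the strand flips
        reflected = [
            MethylationRecord("m1", contig_len - 1 - r.pos, r.meth_count,
                              r.unmeth_count)
            for r in records
        ]
        minus = GenomicInterval(
            "m1", contig_len - 10088, contig_len - 10000, "m1", 0, "-"
        )
        p1 = profile(plus, records)
        p2 = profile(minus, reflected)
        np.testing.assert_array_equal(p1.coverages, p2.coverages)
        np.testing.assert_allclose(p1.fractions, p2.fractions)


class TestRegionMean:
    def test_coverage_weighted_mean(self):
        prof = _profile([-150, -50], [0.2, 0.6], [10, 30])
        assert region_mean(prof, "upstream") == pytest.approx(0.5)

    def test_single_bin(self):
        prof = _profile([-50], [0.4], [5])
        assert region_mean(prof, "upstream") == pytest.approx(0.4)

    def test_missing_region_propagates_nan(self):
        prof = _profile([-50], [0.4], [5])
        assert math.isnan(region_mean(prof, "downstream"))

    def test_refining_bins_leaves_mean_unchanged(self):
        """Weighted means telescope: bin width does not matter."""
        locus = GenomicInterval("m1", 10000, 10088, "m1", 0, "+")
        rng = np.random.default_rng(8)
        records = [
            MethylationRecord("m1", 10000 + int(o), int(m), int(20 - m))
            for o, m in zip(
                rng.choice(np.arange(-1990, 1990, 37), 60, replace=False),
                rng.integers(1, 20, size=60),
            )
        ]
        coarse = profile(locus, records, bin_bp=200)
        fine = profile(locus, records, bin_bp=20)
        for region in ("upstream", "downstream", "window"):
            assert region_mean(coarse, region) == pytest.approx(
                region_mean(fine, region), abs=1e-12
            )


class TestRankSum:
    def test_separated_groups_exact_p(self):
        # all C(6,3)=20 rank assignments; only the two extremes are as deviant
        w, p, method = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert method == "exact"
        assert p == pytest.approx(0.1)

    def test_identical_groups_all_ties(self):
        _, p, method = rank_sum_test([2, 2, 2], [2, 2, 2])
        assert method == "exact"
        assert p == pytest.approx(1.0)

    def test_exact_matches_permutation_oracle(self):
        """scipy's exact independent-sample permutation test as oracle."""
        rng = np.random.default_rng(9)

        def statistic(x, y):
            return stats.rankdata(np.concatenate([x, y]))[: len(x)].sum()

        for n1, n2 in [(3, 3), (4, 5), (6, 6), (2, 6)]:
            x = rng.normal(size=n1)
            y = rng.normal(0.8, size=n2)
            _, p, method = rank_sum_test(x, y)
            oracle = stats.permutation_test(
                (x, y), statistic, permutation_type="independent",
                alternative="two-sided", n_resamples=1_000_000,
            )
            assert method == "exact"
            assert p == pytest.approx(oracle.pvalue, abs=1e-12)

    def test_large_groups_use_normal_approximation(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=30)
        y = rng.normal(1.0, size=30)
        z, p, method = rank_sum_test(x, y)
        assert method == "normal"
        ref = stats.mannwhitneyu(x, y, alternative="two-sided")
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_minimum_group_size(self):
        with pytest.raises(ValueError):
            rank_sum_test([1], [2, 3])


class TestCompareGroups:
    def test_down_group_shift_detected_upstream(self):
        up = [_profile([-150, -50, 50], [0.1, 0.2, 0.2], [20, 20, 20], f"u{i}")
              for i in range(4)]
        down = [_profile([-150, -50, 50], [0.6, 0.7, 0.2], [20, 20, 20], f"d{i}")
                for i in range(4)]
        comp = compare_groups(up, down, "upstream")
        assert comp.p_value < 0.05
        assert comp.n_up == comp.n_down == 4

    def test_insufficient_group_size_rejected(self):
        prof = _profile([-50], [0.4], [5])
        with pytest.raises(ValueError, match="non-missing"):
            compare_groups([prof], [prof, prof], "upstream")

    def test_synthetic_upstream_signal_downstream_null(self):
        truth = generate_truth(TruthConfig(rng_seed=11))
        records = emit_methylation(truth, meth_effect=0.4, coverage=50)
        profs = {
            s: [
                profile(truth.locus_of(m), records)
                for m in truth.mirna_ids if truth.true_states[m] == s
            ]
            for s in ("up", "down")
        }
        upstream = compare_groups(profs["up"], profs["down"], "upstream")
        downstream = compare_groups(profs["up"], profs["down"], "downstream")
        assert upstream.p_value < 0.01
        assert downstream.p_value > 0.05
        assert upstream.statistic > 0  # down group more methylated


class TestPositionalDifference:
    def test_identical_groups_zero_everywhere(self):
        profs = [_profile([-150, -50, 50], [0.3, 0.4, 0.2], [10, 10, 10])]
        diff = positional_difference(profs, profs)
        assert np.allclose(diff["difference"], 0.0)

    def test_mismatched_binning_rejected(self):
        a = [_profile([-50], [0.3], [10])]
        b = [_profile([-150], [0.3], [10])]
        with pytest.raises(ValueError, match="binning"):
            positional_difference(a, b)

    def test_planted_bump_center_recovered(self):
        truth = generate_truth(TruthConfig(rng_seed=12))
        records = emit_methylation(truth)
        profs = {
            s: [
                profile(truth.locus_of(m), records)
                for m in truth.mirna_ids if truth.true_states[m] == s
            ]
            for s in ("up", "down")
        }
        diff = positional_difference(profs["up"], profs["down"])
        assert -1300 <= diff.attrs["argmax_offset"] <= -700

    def test_null_effect_stays_within_permutation_band(self):
        """With no planted bump, no offset exceeds 3x its permutation SD."""
        truth = generate_truth(TruthConfig(rng_seed=13))
        records = emit_methylation(truth, meth_effect=0.0)
        up = [profile(truth.locus_of(m), records)
              for m in truth.mirna_ids if truth.true_states[m] == "up"]
        down = [profile(truth.locus_of(m), records)
                for m in truth.mirna_ids if truth.true_states[m] == "down"]
        profs = up + down
        n_up = len(up)
        observed = positional_difference(up, down)
        rng = np.random.default_rng(13)
        null = []
        for _ in range(1000):
            perm = rng.permutation(len(profs))
            null.append(
                positional_difference(
                    [profs[i] for i in perm[:n_up]],
                    [profs[i] for i in perm[n_up:]],
                )["difference"].to_numpy()
            )
        sd = np.std(np.vstack(null), axis=0)
        assert (np.abs(observed["difference"].to_numpy()) <= 3 * sd).all()


class TestMethExprCorrelation:
    def test_perfect_anticorrelation(self):
        profs = [_profile([-50], [x], [10], f"m{i}")
                 for i, x in enumerate([0.1, 0.2, 0.3])]
        fc = {"m0": 3.0, "m1": 2.0, "m2": 1.0}
        r, _ = meth_expr_correlation(profs, fc)
        assert r == pytest.approx(-1.0)

    def test_independent_inputs_near_zero(self):
        rng = np.random.default_rng(14)
        x = rng.uniform(0, 1, size=1000)
        profs = [_profile([-50], [xi], [10], f"m{i}") for i, xi in enumerate(x)]
        fc = {f"m{i}": v for i, v in enumerate(rng.permutation(x))}
        r, _ = meth_expr_correlation(profs, fc)
        assert abs(r) < 0.1

    def test_constant_vector_rejected(self):
        profs = [_profile([-50], [0.5], [10], f"m{i}") for i in range(3)]
        fc = {f"m{i}": float(i) for i in range(3)}
        with pytest.raises(ValueError, match="constant"):
            meth_expr_correlation(profs, fc)

    def test_minimum_pairs(self):
        profs = [_profile([-50], [0.1], [10], "m0"),
                 _profile([-50], [0.9], [10], "m1")]
        with pytest.raises(ValueError, match="paired"):
            meth_expr_correlation(profs, {"m0": 1.0, "m1": 2.0})

    def test_planted_coupling_gives_negative_sign(self):
        for seed in range(10):
            truth = generate_truth(TruthConfig(rng_seed=seed))
            records = emit_methylation(truth)
            profs = [
                profile(truth.locus_of(m), records)
                for m in truth.mirna_ids
                if truth.true_states[m] in ("up", "down")
            ]
            fc = {
                m: (2.25 if truth.true_states[m] == "up" else -2.25)
                for m in truth.mirna_ids
            }
            r, p = meth_expr_correlation(profs, fc)
            assert r < 0
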