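import numpy as np
import pandas as pd
import pytest

from checseq.coverage import GENOME_SCALED, NormalizationSpec, genome_scale_normalize
from checseq.genome import GenomeIndex, SignalTrack
from checseq.profiles import (
    CleavageProfile,
    asymmetry_index,
    average_signal_ci,
    normalize_and_subtract,
    oriented_end_profile,
    reflect_profile,
)


def sites_frame(rows):
    df = pd.DataFrame(rows, columns=["chrom", "midpoint", "strand"])
    return df


class TestOrientedEndProfile:
    def test_plus_site_offset(self):
        genome = GenomeIndex({"c": 1000})
        t = SignalTrack.zeros(genome)
        t.data["c"][497] = 7.0  # center 500, offset -3
        prof = oriented_end_profile(t, sites_frame([("c", 500, "+")]), flank=50)
        assert prof.mean[np.where(prof.offsets == -3)[0][0]] == 7.0

    def test_minus_site_reflects(self):
        genome = GenomeIndex({"c": 1000})
        t = SignalTrack.zeros(genome)
        t.data["c"][497] = 7.0
        prof = oriented_end_profile(t, sites_frame([("c", 500, "-")]), flank=50)
        # window reversal maps genomic offset -3 to profile offset +2
        assert prof.mean[np.where(prof.offsets == 2)[0][0]] == 7.0

    def test_edge_sites_skipped_with_warning(self):
        genome = GenomeIndex({"c": 1000})
        t = SignalTrack.zeros(genome)
        t.data["c"][0] = 1.0
        with pytest.warns(UserWarning, match="skipped"):
            prof = oriented_end_profile(
                t, sites_frame([("c", 10, "+"), ("c", 500, "+")]), flank=50
            )
        assert prof.n_sites == 1

    def test_strand_balanced_symmetric_signal_is_symmetric(self, rng):
        genome = GenomeIndex({"c": 100_000})
        t = SignalTrack.zeros(genome)
        centers = np.arange(1000, 99_000, 200)
        strands = np.where(np.arange(len(centers)) % 2 == 0, "+", "-")
        for c in centers:
            # symmetric signal: equal mass at +/- 10 of each center
            t.data["c"][c - 10] += 1.0
            t.data["c"][c + 10] += 1.0
        prof = oriented_end_profile(
            t, sites_frame([("c", int(c), s) for c, s in zip(centers, strands)]), flank=50
        )
        left = prof.mean[np.where(prof.offsets == -10)[0][0]]
        right = prof.mean[np.where(prof.offsets == 10)[0][0]]
        assert left == pytest.approx(right, rel=0.05)


class TestNormalizeAndSubtract:
    def make_profile(self, values):
        values = np.asarray(values, dtype=float)
        return CleavageProfile(np.arange(-len(values) // 2, len(values) // 2),
                               values, n_sites=10)

    def test_equal_profiles_cancel(self):
        p = self.make_profile(np.ones(100))
        spec = NormalizationSpec(GENOME_SCALED, fragments_mapped=1000)
        out = normalize_and_subtract(p, p, spec, spec)
        np.testing.assert_array_equal(out.mean, 0.0)
        assert out.control_subtracted

    def test_zero_control_leaves_normalized_tf(self):
        p = self.make_profile(np.arange(100.0))
        zero = self.make_profile(np.zeros(100))
        spec = NormalizationSpec(GENOME_SCALED, genome_size=5000, fragments_mapped=50)
        out = normalize_and_subtract(p, zero, spec, spec)
        np.testing.assert_allclose(out.mean, p.mean * 100.0, rtol=1e-12)

    def test_scale_invariance(self, rng):
        raw_tf = rng.poisson(5, 100).astype(float)
        raw_ctrl = rng.poisson(3, 100).astype(float)
        spec1_tf = NormalizationSpec(GENOME_SCALED, fragments_mapped=1000)
        spec1_ct = NormalizationSpec(GENOME_SCALED, fragments_mapped=500)
        spec2_tf = NormalizationSpec(GENOME_SCALED, fragments_mapped=2000)
        spec2_ct = NormalizationSpec(GENOME_SCALED, fragments_mapped=1000)
        a = normalize_and_subtract(self.make_profile(raw_tf), self.make_profile(raw_ctrl),
                                   spec1_tf, spec1_ct)
        b = normalize_and_subtract(self.make_profile(2 * raw_tf), self.make_profile(2 * raw_ctrl),
                                   spec2_tf, spec2_ct)
        np.testing.assert_allclose(a.mean, b.mean, rtol=1e-12)

    def test_missing_fragment_count_errors(self):
        p = self.make_profile(np.ones(10))
        good = NormalizationSpec(GENOME_SCALED, fragments_mapped=10)
        bad = NormalizationSpec(GENOME_SCALED)
        with pytest.raises(ValueError, match="fragments_mapped"):
            normalize_and_subtract(p, p, good, bad)


class TestAverageSignalCi:
    def test_identical_sites_zero_width_band(self):
        genome = GenomeIndex({"c": 10_000})
        t = SignalTrack.zeros(genome)
        for c in (1000, 2000, 3000):
            t.data["c"][c - 5] = 4.0
        prof = average_signal_ci(
            t, sites_frame([("c", c, "+") for c in (1000, 2000, 3000)]),
            flank=50, n_boot=200, seed=0,
        )
        np.testing.assert_allclose(prof.lo, prof.mean, atol=1e-12)
        np.testing.assert_allclose(prof.hi, prof.mean, atol=1e-12)

    def test_band_contains_mean(self, rng):
        genome = GenomeIndex({"c": 50_000})
        t = SignalTrack(genome, {"c": rng.exponential(1, 50_000)})
        sites = sites_frame([("c", int(m), "+") for m in rng.integers(100, 49_900, 30)])
        prof = average_signal_ci(t, sites, flank=50, n_boot=300, seed=1)
        assert (prof.lo <= prof.mean + 1e-9).all()
        assert (prof.hi >= prof.mean - 1e-9).all()

    def test_single_site_mean_only(self):
        genome = GenomeIndex({"c": 1000})
        t = SignalTrack.zeros(genome)
        with pytest.warns(UserWarning, match="fewer than 2"):
            prof = average_signal_ci(t, sites_frame([("c", 500, "+")]), flank=50)
        assert prof.lo is None

    def test_bootstrap_coverage_calibration(self, rng):
        """~95% of per-offset bands should contain the true site-mean signal
        for Gaussian synthetic site signals."""
        genome = GenomeIndex({"c": 30_000})
        hits = 0
        total = 0
        for rep in range(60):
            t = SignalTrack(genome, {"c": rng.normal(2.0, 1.0, 30_000)})
            sites = sites_frame([("c", int(m), "+")
                                 for m in rng.integers(100, 29_900, 40)])
            prof = average_signal_ci(t, sites, flank=5, n_boot=300, seed=rep)
            hits += int(np.sum((prof.lo <= 2.0) & (2.0 <= prof.hi)))
            total += len(prof.mean)
        coverage = hits / total
        assert 0.88 <= coverage <= 0.99


class TestAsymmetryIndex:
    def make_profile(self, mean, flank=50):
        return CleavageProfile(np.arange(-flank, flank), np.asarray(mean, float),
                               n_sites=1)

    def test_all_upstream_plus_one(self):
        mean = np.zeros(100)
        mean[:30] = 1.0  # offsets -50..-21
        assert asymmetry_index(self.make_profile(mean), motif_width=8) == 1.0

    def test_symmetric_profile_zero(self):
        mean = np.zeros(100)
        mean[10] = 3.0   # offset -40
        mean[89] = 3.0   # offset +39 -> reflection of -40
        assert asymmetry_index(self.make_profile(mean), motif_width=8) == 0.0

    def test_zero_profile_nan(self):
        assert np.isnan(asymmetry_index(self.make_profile(np.zeros(100)), 8))

    def test_matches_direct_sums(self, rng):
        for w in (5, 8, 11):
            mean = rng.exponential(1, 100)
            prof = self.make_profile(mean)
            h = (w + 1) // 2
            up = mean[prof.offsets < -h].sum()
            down = mean[prof.offsets >= h].sum()
            assert asymmetry_index(prof, w) == pytest.approx((up - down) / (up + down))

    @pytest.mark.parametrize("w", [4, 7, 8, 13])
    def test_reflection_negates_exactly(self, rng, w):
        mean = rng.exponential(1, 100)
        prof = self.make_profile(mean)
        assert asymmetry_index(reflect_profile(prof), w) == -asymmetry_index(prof, w)
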