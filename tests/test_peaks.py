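import numpy as np
import pandas as pd
import pytest

from checseq.genome import GenomeIndex, PeakSet, SignalTrack
from checseq.peaks import (
    PeakCallParams,
    call_peaks,
    composite_max,
    intersect_window_sets,
    overlap_fdr,
    spearman_reproducibility,
    unique_fraction,
    window_sum,
)


def track_from(genome, **arrays):
    data = {n: np.asarray(arrays.get(n, np.zeros(genome[n])), dtype=float)
            for n in genome.names}
    return SignalTrack(genome, data)


def peaks_from(rows):
    return PeakSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def brute_force_call(values, fold, merge):
    """Exhaustive threshold-and-merge simulation (independent oracle)."""
    mean = np.mean(values)
    if mean == 0:
        return [], 0.0
    T = fold * mean
    qual = [i for i, v in enumerate(values) if v >= T]
    peaks = []
    for i in qual:
        if peaks and i - peaks[-1][1] <= merge:
            peaks[-1] = (peaks[-1][0], i)
        else:
            peaks.append((i, i))
    return [(s, e + 1) for s, e in peaks], T


class TestCompositeMax:
    def test_positionwise_maximum(self, small_genome):
        a = track_from(small_genome, chrI=np.full(1000, 1.0))
        b = track_from(small_genome, chrI=np.full(1000, 3.0))
        c = track_from(small_genome, chrI=np.full(1000, 2.0))
        assert composite_max([a, b, c]).data["chrI"][0] == 3.0

    def test_single_track_identity(self, random_track):
        assert composite_max([random_track]).allclose(random_track)

    def test_matches_brute_force_loop(self, small_genome, rng):
        tracks = [
            track_from(small_genome,
                       chrI=rng.exponential(1, 1000), chrII=rng.exponential(1, 500))
            for _ in range(4)
        ]
        comp = composite_max(tracks)
        for chrom in small_genome.names:
            for pos in range(small_genome[chrom]):
                assert comp.data[chrom][pos] == max(
                    t.data[chrom][pos] for t in tracks
                )

    def test_genome_mismatch_errors(self, random_track):
        other = SignalTrack(GenomeIndex({"x": 10}), {"x": np.zeros(10)})
        with pytest.raises(ValueError, match="different genomes"):
            composite_max([random_track, other])


class TestCallPeaks:
    def test_single_spike_forced_arithmetic(self):
        genome = GenomeIndex({"c": 100})
        v = np.zeros(100)
        v[40] = 1000.0
        pk = call_peaks(track_from(genome, c=v))
        assert pk.threshold == pytest.approx(100.0)  # mean 10, fold 10
        assert len(pk) == 1
        row = pk.frame.iloc[0]
        assert (row["start"], row["end"]) == (40, 41)
        assert row["midpoint"] == 40

    def test_merge_boundary_30_vs_31(self):
        genome = GenomeIndex({"c": 1000})
        for gap, n_expected in ((30, 1), (31, 2)):
            v = np.zeros(1000)
            v[100] = 1e6
            v[100 + gap] = 1e6
            pk = call_peaks(track_from(genome, c=v))
            assert len(pk) == n_expected, f"gap {gap}"

    def test_uniform_track_no_peaks(self):
        genome = GenomeIndex({"c": 200})
        pk = call_peaks(track_from(genome, c=np.full(200, 5.0)))
        assert len(pk) == 0

    def test_all_zero_track_warns_no_peaks(self):
        genome = GenomeIndex({"c": 100})
        with pytest.warns(UserWarning, match="all-zero"):
            pk = call_peaks(track_from(genome, c=np.zeros(100)))
        assert len(pk) == 0

    def test_oracle_equivalence_random_tracks(self, rng):
        """Caller output equals an exhaustive threshold-and-merge simulation."""
        for _ in range(200):
            L = int(rng.integers(50, 500))
            v = rng.poisson(0.05, L) * rng.exponential(20, L)
            genome = GenomeIndex({"c": L})
            pk = call_peaks(track_from(genome, c=v))
            expected, T = brute_force_call(v, 10.0, 30)
            got = list(zip(pk.frame["start"], pk.frame["end"]))
            assert got == expected
            if expected:
                assert pk.threshold == pytest.approx(T)

    def test_every_qualifying_position_inside_a_peak(self, rng):
        L = 2000
        v = rng.poisson(0.1, L) * rng.exponential(30, L)
        genome = GenomeIndex({"c": L})
        pk = call_peaks(track_from(genome, c=v))
        T = pk.threshold
        covered = np.zeros(L, dtype=bool)
        for _, r in pk.frame.iterrows():
            covered[r["start"]:r["end"]] = True
            assert (v[r["start"]:r["end"]] >= T).any()
        assert covered[v >= T].all()

    def test_merging_idempotent(self, rng):
        """Re-calling on a track that is nonzero only inside called peaks
        reproduces the same intervals."""
        L = 3000
        v = rng.poisson(0.05, L) * rng.exponential(50, L)
        genome = GenomeIndex({"c": L})
        pk = call_peaks(track_from(genome, c=v))
        if not len(pk):
            pytest.skip("no peaks in draw")
        v2 = np.zeros(L)
        for _, r in pk.frame.iterrows():
            v2[r["start"]:r["end"]] = np.maximum(v[r["start"]:r["end"]], pk.threshold)
        pk2 = call_peaks(
            track_from(genome, c=v2),
            PeakCallParams(fold=pk.threshold / np.mean(v2), merge_distance=30),
        )
        assert list(zip(pk2.frame["start"], pk2.frame["end"])) == list(
            zip(pk.frame["start"], pk.frame["end"])
        )


class TestWindowSum:
    def test_delta_at_midpoint(self, small_genome):
        t = track_from(small_genome)
        t.data["chrI"][100] = 5.0
        pk = peaks_from([("chrI", 100, 101)])
        assert window_sum(t, pk, width=50)[0] == 5.0

    def test_uniform_track_width(self, small_genome):
        t = track_from(small_genome, chrI=np.ones(1000))
        pk = peaks_from([("chrI", 500, 501)])
        assert window_sum(t, pk, width=50)[0] == 50.0

    def test_matches_brute_force_slices(self, random_track, rng):
        mids = rng.integers(0, 1000, 50)
        pk = peaks_from([("chrI", int(m), int(m) + 1) for m in mids])
        got = window_sum(random_track, pk, width=50)
        v = random_track.data["chrI"]
        for i, m in enumerate(pk.frame["midpoint"]):
            lo, hi = max(0, m - 25), min(1000, m + 25)
            assert got[i] == pytest.approx(v[lo:hi].sum())

    def test_edge_clipping_warns(self, random_track):
        pk = peaks_from([("chrI", 0, 1)])
        with pytest.warns(UserWarning, match="clipped"):
            window_sum(random_track, pk, width=50)


class TestOverlapFdr:
    def test_count_total_percentage_arithmetic(self):
        # 269 overlapping of 7,260 peaks -> 3.71% (Rap1-style worked example)
        tf_rows = [("c", i * 100, i * 100 + 10) for i in range(7260)]
        ctrl_rows = [("c", i * 100, i * 100 + 10) for i in range(269)]
        fdr = overlap_fdr(peaks_from(tf_rows), peaks_from(ctrl_rows))
        assert fdr == pytest.approx(100 * 269 / 7260)
        assert round(fdr, 2) == 3.71

    def test_disjoint_sets_zero(self):
        a = peaks_from([("c", 0, 10)])
        b = peaks_from([("c", 20, 30)])
        assert overlap_fdr(a, b) == 0.0

    def test_identical_sets_hundred(self):
        a = peaks_from([("c", 0, 10), ("c", 50, 60)])
        assert overlap_fdr(a, a) == 100.0

    def test_empty_tf_errors(self):
        with pytest.raises(ValueError, match="empty TF"):
            overlap_fdr(PeakSet(pd.DataFrame(columns=["chrom", "start", "end"])),
                        peaks_from([("c", 0, 1)]))

    def test_empty_control_gives_zero(self):
        a = peaks_from([("c", 0, 10)])
        empty = PeakSet(pd.DataFrame(columns=["chrom", "start", "end"]))
        assert overlap_fdr(a, empty) == 0.0

    def test_monotone_in_control_peaks(self, rng):
        tf = peaks_from([("c", int(s), int(s) + 20) for s in rng.integers(0, 5000, 50)])
        ctrl_rows = [("c", int(s), int(s) + 20) for s in rng.integers(0, 5000, 30)]
        prev = 0.0
        for k in range(len(ctrl_rows) + 1):
            if k == 0:
                continue
            fdr = overlap_fdr(tf, peaks_from(ctrl_rows[:k]))
            assert fdr >= prev - 1e-12
            assert 0 <= fdr <= 100
            prev = fdr


class TestIntersectWindowSets:
    def test_reference_percentage_arithmetic(self):
        # 929 of 1,277 reference sites hit -> 72.7%
        ref = [("c", i * 1000, i * 1000 + 2) for i in range(1277)]
        query = [("c", i * 1000, i * 1000 + 2) for i in range(929)]
        count, pct = intersect_window_sets(peaks_from(query), peaks_from(ref))
        assert count == 929
        assert round(pct, 1) == 72.7

    def test_abutting_windows_do_not_overlap(self):
        # midpoints 100 and 200, width 100: windows [50,150) and [150,250)
        a = peaks_from([("c", 100, 101)])
        b = peaks_from([("c", 200, 201)])
        count, _ = intersect_window_sets(a, b, width=100)
        assert count == 0

    def test_symmetric_counts_on_one_to_one_mapping(self, rng):
        mids = np.sort(rng.choice(np.arange(100, 100_000, 250), 80, replace=False))
        jitter = rng.integers(-20, 21, 80)
        a = peaks_from([("c", int(m), int(m) + 1) for m in mids])
        b = peaks_from([("c", int(m + j), int(m + j) + 1) for m, j in zip(mids, jitter)])
        ca, _ = intersect_window_sets(a, b, width=100)
        cb, _ = intersect_window_sets(b, a, width=100)
        assert ca == cb
        # brute-force all-pairs oracle
        def hits(qa, qb):
            n = 0
            for mb in qb.frame["midpoint"]:
                for ma in qa.frame["midpoint"]:
                    if max(ma - 50, mb - 50) < min(ma + 50, mb + 50):
                        n += 1
                        break
            return n
        assert ca == hits(a, b)


class TestUniqueFraction:
    def test_printed_overlap_structure(self):
        """Sites overlapping no other factor reproduce the count/total
        percentage arithmetic (e.g. 7,550/8,649 non-overlapping -> 87.3%)."""
        own = peaks_from([("c", i * 1000, i * 1000 + 2) for i in range(8649)])
        n_shared = 8649 - 7550
        other = peaks_from([("c", i * 1000, i * 1000 + 2) for i in range(n_shared)])
        n_unique, pct = unique_fraction(own, [other], width=100)
        assert n_unique == 7550
        assert round(pct, 1) == 87.3


class TestSpearman:
    def test_identical_vectors(self):
        v = np.array([3.0, 1.0, 2.0, 5.0])
        assert spearman_reproducibility(v, v) == pytest.approx(1.0)

    def test_reversed_ranks(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert spearman_reproducibility(a, a[::-1]) == pytest.approx(-1.0)

    def test_equals_rank_then_pearson_oracle(self, rng):
        a = rng.normal(size=200)
        b = 0.5 * a + rng.normal(size=200)
        rho = spearman_reproducibility(a, b)
        ra = pd.Series(a).rank().to_numpy()
        rb = pd.Series(b).rank().to_numpy()
        oracle = np.corrcoef(ra, rb)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_reproducibility(np.ones(5), np.arange(5.0))
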