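"""Tag density, input subtraction, peak overlap and PWM scanning."""

import numpy as np
import pandas as pd
import pytest

from ptmkit.chip_signal import (
    PWM,
    OverlapPartition,
    TagSet,
    call_peaks,
    dedupe_and_subsample,
    motif_fraction,
    peak_overlap,
    pwm_scan,
    reverse_complement,
    subtract_input,
    tag_density,
)


def make_tags(rows, sizes):
    return TagSet(pd.DataFrame(rows, columns=["chrom", "pos", "strand"]), sizes)


class TestDedupeSubsample:
    def test_duplicates_collapse_before_sampling(self):
        tags = make_tags(
            [("chr1", 10, "+"), ("chr1", 10, "+"), ("chr1", 10, "-"), ("chr1", 20, "+"), ("chr1", 20, "+")],
            {"chr1": 100},
        )
        out = dedupe_and_subsample(tags, 3, seed=0)
        assert len(out) == 3

    def test_sampling_all_unique_is_identity(self):
        tags = make_tags([("chr1", i, "+") for i in range(10)], {"chr1": 100})
        out = dedupe_and_subsample(tags, 10, seed=5)
        assert sorted(out.tags["pos"]) == list(range(10))

    def test_same_seed_reproduces_selection(self):
        tags = make_tags([("chr1", i, "+") for i in range(100)], {"chr1": 1000})
        a = dedupe_and_subsample(tags, 30, seed=42)
        b = dedupe_and_subsample(tags, 30, seed=42)
        pd.testing.assert_frame_equal(a.tags, b.tags)

    def test_oversampling_rejected_with_counts(self):
        tags = make_tags([("chr1", 1, "+")], {"chr1": 10})
        with pytest.raises(ValueError, match="1 unique"):
            dedupe_and_subsample(tags, 5, seed=0)


class TestTagDensity:
    def test_tag_inside_dilated_window_counted(self):
        # bin [80,100) with flank 75 -> window [5,175): tag at 100 counted
        tags = make_tags([("chr1", 100, "+")], {"chr1": 400})
        track = tag_density(tags, bin_size=20, flank=75, normalize_to=1)
        assert track.data["chr1"][4] == pytest.approx(1.0)

    def test_tag_outside_window_not_counted(self):
        # bin [0,20) flank 75 -> window [-75,95): tag at 200 missed
        tags = make_tags([("chr1", 200, "+")], {"chr1": 400})
        track = tag_density(tags, bin_size=20, flank=75, normalize_to=1)
        assert track.data["chr1"][0] == 0.0

    def test_uniform_coverage_counts_window_length(self):
        size = 2000
        tags = make_tags([("chr1", i, "+") for i in range(size)], {"chr1": size})
        track = tag_density(tags, bin_size=20, flank=75, normalize_to=size)
        # interior bins see exactly bin + 2*flank tags before normalization
        interior = track.data["chr1"][10:-10]
        assert np.allclose(interior, 20 + 2 * 75)

    def test_empty_tagset_warns_and_zeroes(self):
        tags = make_tags([], {"chr1": 100})
        with pytest.warns(UserWarning, match="empty"):
            track = tag_density(tags)
        assert not track.data["chr1"].any()

    def test_normalization_scales_with_library_size(self):
        tags = make_tags([("chr1", 50, "+"), ("chr1", 55, "-")], {"chr1": 400})
        track = tag_density(tags, normalize_to=10)
        assert track.data["chr1"].max() == pytest.approx(2 * 10 / 2)


class TestSubtractInput:
    def test_self_subtraction_identically_zero(self):
        rng = np.random.default_rng(0)
        tags = make_tags([("chr1", int(p), "+") for p in rng.integers(0, 400, 50)], {"chr1": 400})
        track = tag_density(tags)
        diff = subtract_input(track, track)
        assert not diff.values().any()

    def test_zero_input_is_identity_and_negatives_preserved(self):
        chip = make_tags([("chr1", 100, "+")], {"chr1": 400})
        inp = make_tags([("chr1", 300, "+")], {"chr1": 400})
        c = tag_density(chip, normalize_to=1)
        i = tag_density(inp, normalize_to=1)
        diff = subtract_input(c, i)
        assert diff.data["chr1"][4] == pytest.approx(1.0)
        assert diff.values().min() < 0  # bins where input > chip stay negative

    def test_mismatched_bins_rejected(self):
        a = tag_density(make_tags([("chr1", 1, "+")], {"chr1": 400}), bin_size=20)
        b = tag_density(make_tags([("chr1", 1, "+")], {"chr1": 400}), bin_size=40)
        with pytest.raises(ValueError):
            subtract_input(a, b)


def _track_from_values(values, bin_size=20):
    from ptmkit.chip_signal import SignalTrack

    values = np.asarray(values, dtype=float)
    return SignalTrack(bin_size, {"chr1": len(values) * bin_size}, {"chr1": values}, 1.0)


class TestCallPeaks:
    def test_single_run_of_bins_becomes_one_peak(self):
        track = _track_from_values([0, 0, 5, 5, 5, 5, 5, 0, 0])
        peaks = call_peaks(track, threshold=1.0, min_width=20, merge_gap=0)
        assert peaks[["start", "end"]].values.tolist() == [[40, 140]]

    def test_runs_within_merge_gap_merged(self):
        track = _track_from_values([5, 5, 0, 5, 5])
        peaks = call_peaks(track, threshold=1.0, min_width=20, merge_gap=40)
        assert peaks[["start", "end"]].values.tolist() == [[0, 100]]
        split = call_peaks(track, threshold=1.0, min_width=20, merge_gap=10)
        assert len(split) == 2

    def test_short_runs_discarded(self):
        track = _track_from_values([0, 5, 0, 5, 5, 5, 0])
        peaks = call_peaks(track, threshold=1.0, min_width=60, merge_gap=10)
        assert peaks[["start", "end"]].values.tolist() == [[60, 120]]

    def test_all_below_threshold_gives_empty_set(self):
        assert call_peaks(_track_from_values([0.1] * 10), threshold=1.0).empty


def brute_force_overlap(a: pd.DataFrame, b: pd.DataFrame) -> np.ndarray:
    """All-pairs any-overlap checker (half-open intervals)."""
    hits = np.zeros(len(a), dtype=bool)
    for i, ra in enumerate(a.itertuples(index=False)):
        for rb in b.itertuples(index=False):
            if ra.chrom == rb.chrom and ra.start < rb.end and rb.start < ra.end:
                hits[i] = True
                break
    return hits


def random_peaks(rng, n, chroms=("chr1", "chr2")):
    starts = rng.integers(0, 5000, size=n)
    return pd.DataFrame(
        {
            "chrom": rng.choice(chroms, size=n),
            "start": starts,
            "end": starts + rng.integers(1, 400, size=n),
        }
    )


class TestPeakOverlap:
    def test_overlapping_intervals_shared(self):
        a = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
        b = pd.DataFrame({"chrom": ["chr1"], "start": [50], "end": [150]})
        part = peak_overlap(a, b)
        assert len(part.shared_a) == 1 and len(part.shared_b) == 1

    def test_touching_half_open_intervals_not_shared(self):
        a = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
        b = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})
        part = peak_overlap(a, b)
        assert part.shared_a.empty and part.specific_a.shape[0] == 1

    def test_partition_is_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(0)
        a, b = random_peaks(rng, 40), random_peaks(rng, 40)
        part = peak_overlap(a, b)
        assert len(part.shared_a) + len(part.specific_a) == len(a)
        assert len(part.shared_b) + len(part.specific_b) == len(b)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle_on_random_sets(self, seed):
        rng = np.random.default_rng(seed)
        a = random_peaks(rng, int(rng.integers(1, 50)))
        b = random_peaks(rng, int(rng.integers(1, 50)))
        part = peak_overlap(a, b)
        from ptmkit.chip_signal import sort_peaks

        a_sorted, b_sorted = sort_peaks(a), sort_peaks(b)
        assert len(part.shared_a) == brute_force_overlap(a_sorted, b_sorted).sum()
        assert len(part.shared_b) == brute_force_overlap(b_sorted, a_sorted).sum()


class TestPwmScan:
    # non-palindromic consensus so strand assignment is unambiguous
    pwm = PWM.from_consensus("ACGG")

    def test_single_forward_hit_with_hand_summed_score(self):
        hits = pwm_scan("AAACGGAA", self.pwm, 0.9 * self.pwm.max_score)
        assert len(hits) == 1
        off, strand, score = hits[0]
        assert (off, strand) == (2, "+")
        assert score == pytest.approx(float(self.pwm.matrix.max(axis=0).sum()))

    def test_reverse_complement_site_found_on_minus_strand(self):
        # CCGT is the reverse complement of the ACGG consensus
        hits = pwm_scan("TTCCGTTT", self.pwm, 0.9 * self.pwm.max_score)
        assert [(h[0], h[1]) for h in hits] == [(2, "-")]

    def test_threshold_above_max_score_yields_nothing(self):
        assert pwm_scan("AAACGGAA", self.pwm, self.pwm.max_score + 1.0) == []

    def test_sequence_shorter_than_width_yields_nothing(self):
        assert pwm_scan("AC", self.pwm, 0.0) == []

    def test_windows_containing_n_skipped(self):
        hits = pwm_scan("AANGGAAN", self.pwm, -1e9)
        seq = "AANGGAAN"
        assert hits  # N-free windows still scored
        assert all("N" not in seq[o : o + self.pwm.width] for o, _, _ in hits)
        assert len(pwm_scan("NACGGN", self.pwm, 0.9 * self.pwm.max_score)) == 1

    def test_forward_hits_mirror_on_reverse_complement(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        pwm = PWM.from_consensus("CTTTGTT", match_prob=0.85)
        thr = 0.6 * pwm.max_score
        fwd = {(o, s) for o, s, _ in pwm_scan(seq, pwm, thr)}
        rc = reverse_complement(seq)
        mirrored = {
            (len(seq) - pwm.width - o, {"+": "-", "-": "+"}[s])
            for o, s, _ in pwm_scan(rc, pwm, thr)
        }
        assert fwd == mirrored

    def test_agrees_with_biopython_pssm(self):
        from Bio import motifs
        from Bio.Seq import Seq

        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        counts = rng.integers(1, 50, size=(4, 8)).astype(float)
        pwm = PWM.from_counts(counts, pseudocount=0.0)
        motif = motifs.Motif(
            alphabet="ACGT",
            counts={b: list(counts[i]) for i, b in enumerate("ACGT")},
        )
        pssm = motif.counts.normalize().log_odds()
        ref = pssm.calculate(Seq(seq))
        ours = np.full(len(seq) - 7, np.nan)
        for off, strand, score in pwm_scan(seq, pwm, -1e9):
            if strand == "+":
                ours[off] = score
        assert np.allclose(ours, np.asarray(ref), atol=1e-3)


class TestMotifFraction:
    def test_every_peak_with_consensus_scores_one(self):
        genome = {"chr1": "TTTT" + "ACGT" + "TTTT" + "ACGT" + "TT"}
        peaks = pd.DataFrame({"chrom": ["chr1"] * 2, "start": [2, 10], "end": [10, 18]})
        frac, flags = motif_fraction(peaks, genome, PWM.from_consensus("ACGT"), None)
        assert frac == 1.0

    def test_no_matching_peak_scores_zero(self):
        genome = {"chr1": "T" * 40}
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [20]})
        frac, _ = motif_fraction(peaks, genome, PWM.from_consensus("ACGA"), None)
        assert frac == 0.0

    def test_empty_peak_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            motif_fraction(pd.DataFrame(columns=["chrom", "start", "end"]), {}, PWM.from_consensus("ACGT"))
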