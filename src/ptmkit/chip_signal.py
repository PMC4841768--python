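"""Binned ChIP-seq tag-density signal, peak overlap and PWM motif scanning.

Aligned tags (the 5' positions of sequenced fragments) are deduplicated,
subsampled to a fixed count, and turned into a density track: the number of
tags within a flank (default 75 bp) of each fixed-width bin (default 20 bp),
scaled so every library is expressed per ``normalize_to`` tags (default
1e7).  The matched, identically normalised input (sonicated chromatin
without immunoprecipitation) track is subtracted bin-wise; negative values
are kept.  Peak sets — called here by a simple threshold/merge rule, or
loaded from BED — are partitioned into shared/specific by any-overlap of
half-open intervals, and the fraction of peaks containing a position weight
matrix (PWM) match is computed by log-odds scanning of both strands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "TagSet",
    "SignalTrack",
    "PWM",
    "OverlapPartition",
    "dedupe_and_subsample",
    "tag_density",
    "subtract_input",
    "call_peaks",
    "sort_peaks",
    "peak_overlap",
    "pwm_scan",
    "motif_fraction",
    "reverse_complement",
]

_BASES = "ACGT"
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TagSet:
    """Aligned tag records (chrom, 0-based 5' position, strand) plus genome sizes."""

    tags: pd.DataFrame
    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "strand"}
        if not required.issubset(self.tags.columns):
            raise ValueError(f"tag table lacks columns {sorted(required - set(self.tags.columns))}")
        bad_strand = set(self.tags["strand"]) - {"+", "-"}
        if bad_strand:
            raise ValueError(f"invalid strands {sorted(bad_strand)}")
        for chrom, grp in self.tags.groupby("chrom", sort=False):
            if chrom not in self.chrom_sizes:
                raise ValueError(f"chromosome {chrom!r} absent from sizes table")
            size = self.chrom_sizes[chrom]
            pos = grp["pos"].to_numpy()
            if pos.min(initial=0) < 0 or (len(pos) and pos.max() >= size):
                raise ValueError(f"tag position outside [0, {size}) on {chrom!r}")

    def __len__(self) -> int:
        return len(self.tags)


def dedupe_and_subsample(tags: TagSet, n: int, seed: int | np.random.Generator = 0) -> TagSet:
    """Collapse duplicate (chrom, pos, strand) records, then sample ``n`` uniformly.

    Sampling is without replacement and reproducible for a fixed seed.
    """
    unique = tags.tags.drop_duplicates(subset=["chrom", "pos", "strand"]).reset_index(drop=True)
    if n > len(unique):
        raise ValueError(f"requested {n} tags but only {len(unique)} unique tags available")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(unique), size=n, replace=False))
    picked = unique.iloc[idx].sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)
    return TagSet(picked, dict(tags.chrom_sizes))


@dataclass
class SignalTrack:
    """Per-chromosome binned density vectors (may be negative after subtraction)."""

    bin_size: int
    chrom_sizes: dict[str, int]
    data: dict[str, np.ndarray]
    normalize_to: float

    def __post_init__(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            nbins = -(-size // self.bin_size)
            if chrom not in self.data or len(self.data[chrom]) != nbins:
                raise ValueError(f"track for {chrom!r} must have {nbins} bins")

    def values(self) -> np.ndarray:
        return np.concatenate([self.data[c] for c in sorted(self.data)])


def tag_density(
    tags: TagSet,
    bin_size: int = 20,
    flank: int = 75,
    normalize_to: float = 1e7,
    window_mode: str = "dilate",
) -> SignalTrack:
    """Tag count within ``flank`` bp of each ``bin_size`` bp bin, library-normalised.

    ``window_mode='dilate'`` (default) counts tags in the bin interval
    dilated by ``flank`` on each side, i.e. ``[s - flank, s + bin + flank)``
    for bin start ``s``; ``'center'`` counts within ``flank`` of the bin
    centre.  Values are scaled by ``normalize_to / total tag count`` so
    libraries of different depth are comparable.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if flank < 0:
        raise ValueError("flank must be non-negative")
    if window_mode not in ("dilate", "center"):
        raise ValueError(f"unknown window_mode {window_mode!r}")
    total = len(tags)
    if total == 0:
        warnings.warn("empty TagSet: all-zero track")
        scale = 0.0
    else:
        scale = normalize_to / total
    data: dict[str, np.ndarray] = {}
    by_chrom = {c: g["pos"].to_numpy(dtype=np.int64) for c, g in tags.tags.groupby("chrom", sort=False)}
    for chrom, size in tags.chrom_sizes.items():
        nbins = -(-size // bin_size)
        pos = np.sort(by_chrom.get(chrom, np.empty(0, dtype=np.int64)))
        starts = np.arange(nbins, dtype=np.int64) * bin_size
        if window_mode == "dilate":
            lo = starts - flank
            hi = starts + bin_size + flank
        else:
            centre = starts + bin_size / 2.0
            lo = centre - flank
            hi = centre + flank
        counts = np.searchsorted(pos, hi, side="left") - np.searchsorted(pos, lo, side="left")
        data[chrom] = counts.astype(float) * scale
    return SignalTrack(bin_size, dict(tags.chrom_sizes), data, normalize_to)


def subtract_input(chip: SignalTrack, input_track: SignalTrack) -> SignalTrack:
    """Element-wise ChIP minus input; negative values are retained."""
    if chip.bin_size != input_track.bin_size:
        raise ValueError("bin sizes differ between ChIP and input tracks")
    if chip.chrom_sizes != input_track.chrom_sizes:
        raise ValueError("genomes differ between ChIP and input tracks")
    if chip.normalize_to != input_track.normalize_to:
        raise ValueError("normalization counts differ between ChIP and input tracks")
    data = {c: chip.data[c] - input_track.data[c] for c in chip.data}
    return SignalTrack(chip.bin_size, dict(chip.chrom_sizes), data, chip.normalize_to)


def sort_peaks(peaks: pd.DataFrame) -> pd.DataFrame:
    """Validate and interval-normalise a peak table (chrom, start, end[, score])."""
    required = {"chrom", "start", "end"}
    if not required.issubset(peaks.columns):
        raise ValueError(f"peak table lacks columns {sorted(required - set(peaks.columns))}")
    if (peaks["start"] >= peaks["end"]).any():
        raise ValueError("peak with start >= end")
    return peaks.sort_values(["chrom", "start", "end"]).reset_index(drop=True)


def call_peaks(
    track: SignalTrack,
    threshold: float | None = None,
    min_width: int = 60,
    merge_gap: int = 100,
) -> pd.DataFrame:
    """Threshold/merge peak caller over a signal track.

    Maximal runs of bins with value >= ``threshold`` become intervals (bp
    coordinates, clipped to the chromosome); runs separated by less than
    ``merge_gap`` bp are merged; intervals narrower than ``min_width`` bp are
    discarded.  When ``threshold`` is None it defaults to mean + 5 SD of the
    track values, a data-driven default for tracks that are mostly
    background.  This is deliberately simple plumbing: externally called
    peaks (BED) are accepted everywhere a peak set is consumed.
    """
    if threshold is None:
        vals = track.values()
        threshold = float(vals.mean() + 5.0 * vals.std())
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    rows = []
    B = track.bin_size
    for chrom in track.chrom_sizes:
        v = track.data[chrom]
        above = v >= threshold
        if not above.any():
            continue
        edges = np.diff(above.astype(np.int8))
        starts = list(np.flatnonzero(edges == 1) + 1)
        ends = list(np.flatnonzero(edges == -1) + 1)
        if above[0]:
            starts.insert(0, 0)
        if above[-1]:
            ends.append(len(v))
        intervals = [
            [s * B, min(e * B, track.chrom_sizes[chrom]), float(v[s:e].max())]
            for s, e in zip(starts, ends)
        ]
        merged = [intervals[0]]
        for s, e, sc in intervals[1:]:
            if s - merged[-1][1] < merge_gap:
                merged[-1][1] = e
                merged[-1][2] = max(merged[-1][2], sc)
            else:
                merged.append([s, e, sc])
        for s, e, sc in merged:
            if e - s >= min_width:
                rows.append({"chrom": chrom, "start": s, "end": e, "score": sc})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])


class OverlapPartition(NamedTuple):
    shared_a: pd.DataFrame
    shared_b: pd.DataFrame
    specific_a: pd.DataFrame
    specific_b: pd.DataFrame


def _overlaps_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Per query interval, whether any subject interval overlaps >= 1 bp."""
    hit = np.zeros(len(query), dtype=bool)
    subj_by_chrom = dict(tuple(subject.groupby("chrom", sort=False)))
    for chrom, grp in query.groupby("chrom", sort=False):
        sub = subj_by_chrom.get(chrom)
        if sub is None or sub.empty:
            continue
        sub = sub.sort_values("start")
        s_start = sub["start"].to_numpy()
        s_end_cummax = np.maximum.accumulate(sub["end"].to_numpy())
        q_start = grp["start"].to_numpy()
        q_end = grp["end"].to_numpy()
        idx = np.searchsorted(s_start, q_end, side="left")
        ok = idx > 0
        ok[ok] = s_end_cummax[idx[ok] - 1] > q_start[ok]
        hit[grp.index.to_numpy()] = ok
    return hit


def peak_overlap(a: pd.DataFrame, b: pd.DataFrame) -> OverlapPartition:
    """Partition two peak sets into shared and set-specific peaks.

    A peak is shared iff it overlaps at least 1 bp (half-open intervals)
    with any peak of the other set; the partition is exhaustive and
    exclusive per set.
    """
    a = sort_peaks(a)
    b = sort_peaks(b)
    a_hit = _overlaps_any(a, b)
    b_hit = _overlaps_any(b, a)
    return OverlapPartition(
        a.loc[a_hit].reset_index(drop=True),
        b.loc[b_hit].reset_index(drop=True),
        a.loc[~a_hit].reset_index(drop=True),
        b.loc[~b_hit].reset_index(drop=True),
    )


@dataclass
class PWM:
    """Position weight matrix: per-position log2-odds of bases vs background.

    ``matrix`` is 4 x width with rows in A, C, G, T order; ``background``
    holds the four background base frequencies (positive, summing to 1).
    """

    matrix: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4 or self.matrix.shape[1] < 1:
            raise ValueError("PWM matrix must be 4 x width with width >= 1")
        if self.background.shape != (4,) or np.any(self.background <= 0):
            raise ValueError("background must be 4 positive frequencies")
        if abs(self.background.sum() - 1.0) > 1e-6:
            raise ValueError("background frequencies must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=0))

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        background: np.ndarray | None = None,
        pseudocount: float = 0.25,
    ) -> "PWM":
        """Log2-odds matrix from a 4 x width base-count matrix (rows A,C,G,T)."""
        counts = np.asarray(counts, dtype=float)
        if background is None:
            background = np.full(4, 0.25)
        background = np.asarray(background, dtype=float)
        freq = (counts + pseudocount) / (counts.sum(axis=0) + 4 * pseudocount)
        return cls(np.log2(freq / background[:, None]), background)

    @classmethod
    def from_consensus(cls, consensus: str, match_prob: float = 0.97) -> "PWM":
        """Sharp PWM favouring one consensus sequence (mismatch prob split evenly)."""
        consensus = consensus.upper()
        counts = np.full((4, len(consensus)), (1 - match_prob) / 3 * 1000.0)
        for j, base in enumerate(consensus):
            if base not in _BASES:
                raise ValueError(f"consensus contains non-ACGT base {base!r}")
            counts[_BASES.index(base), j] = match_prob * 1000.0
        return cls.from_counts(counts, pseudocount=0.0)


def _scan_codes(codes: np.ndarray, matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores and validity for every window over an encoded sequence."""
    w = matrix.shape[1]
    n = len(codes) - w + 1
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for j in range(w):
        c = codes[j : j + n]
        bad = c < 0
        valid &= ~bad
        scores += np.where(bad, 0.0, matrix[np.clip(c, 0, 3), j])
    return scores, valid


def pwm_scan(
    sequence: str, pwm: PWM, score_threshold: float | None = None
) -> list[tuple[int, str, float]]:
    """Score every window on both strands; return hits at or above threshold.

    The reverse strand is scored on the reverse complement; a minus-strand
    hit at offset ``o`` means the reverse complement of
    ``sequence[o:o+width]`` matches.  Windows containing N are skipped.
    When ``score_threshold`` is None it defaults to 80% of the maximum
    achievable score.  Sequences shorter than the PWM width yield no hits.
    """
    if score_threshold is None:
        score_threshold = 0.8 * pwm.max_score
    w = pwm.width
    if len(sequence) < w:
        return []
    codes = _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    hits: list[tuple[int, str, float]] = []
    fwd_scores, fwd_valid = _scan_codes(codes, pwm.matrix)
    for off in np.flatnonzero(fwd_valid & (fwd_scores >= score_threshold)):
        hits.append((int(off), "+", float(fwd_scores[off])))
    rc_codes = np.where(codes >= 0, 3 - codes, -1)[::-1]
    rev_scores, rev_valid = _scan_codes(rc_codes, pwm.matrix)
    n_rev = len(rc_codes) - w + 1
    for p in np.flatnonzero(rev_valid & (rev_scores >= score_threshold)):
        hits.append((int(n_rev - 1 - p), "-", float(rev_scores[p])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def motif_fraction(
    peaks: pd.DataFrame,
    genome: Mapping[str, str],
    pwm: PWM,
    score_threshold: float | None = None,
) -> tuple[float, pd.DataFrame]:
    """Fraction of peaks whose sequence contains >= 1 PWM hit.

    Returns the proportion in [0, 1] and the peak table augmented with a
    boolean ``has_motif`` column.
    """
    peaks = sort_peaks(peaks)
    if peaks.empty:
        raise ValueError("empty peak set")
    flags = []
    for row in peaks.itertuples(index=False):
        seq = genome[row.chrom][row.start : row.end]
        if row.end > len(genome[row.chrom]) or row.start < 0:
            raise ValueError(f"peak {row.chrom}:{row.start}-{row.end} outside genome bounds")
        flags.append(bool(pwm_scan(seq, pwm, score_threshold)))
    out = peaks.copy()
    out["has_motif"] = flags
    return float(np.mean(flags)), out
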