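"""Transcriptional-peak discovery from pooled strand-aware pileups.

A transcriptional peak (TP) is a maximal genomic run of bases whose pooled
read depth strictly exceeds the peak threshold (default 10 reads/base),
retained when its length is within 17..150 nt and its mean depth over its
own bases is >= 10 (inclusive).  Note the two thresholds deliberately use
different operators: segmentation follows "more than 10 per base" (strict)
while the retention filter follows "10 or more" (inclusive).

Peaks are called on the merged pileup of all libraries, per strand, then
concatenated and sorted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_formats import AlignmentRecord

DEFAULT_PEAK_THRESHOLD = 10
DEFAULT_MIN_LEN = 17
DEFAULT_MAX_LEN = 150
DEFAULT_MIN_MEAN_COV = 10.0


@dataclass
class CoverageTrack:
    """Per-base read depth over one contig, one strand."""

    contig: str
    strand: str
    depth: np.ndarray  # int array, length == contig length

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if (self.depth < 0).any():
            raise ValueError("negative depth")


@dataclass(frozen=True)
class TranscriptionalPeak:
    tp_id: str
    contig: str
    start: int
    end: int
    strand: str
    mean_coverage: float
    max_coverage: int

    @property
    def length(self) -> int:
        return self.end - self.start


def pool_and_pileup(
    samples: Iterable[Iterable[AlignmentRecord]],
    contig_lengths: dict[str, int],
) -> dict[tuple[str, str], CoverageTrack]:
    """Merge alignment record streams and build per-contig, per-strand depth.

    depth[i] on strand s = number of pooled mapped records on strand s whose
    span covers base i.  Returns a dict keyed by (contig, strand).
    """
    tracks = {
        (contig, strand): CoverageTrack(contig, strand, np.zeros(length, dtype=np.int64))
        for contig, length in contig_lengths.items()
        for strand in ("+", "-")
    }
    # difference-array accumulation, then cumulative sum
    deltas = {
        key: np.zeros(contig_lengths[key[0]] + 1, dtype=np.int64) for key in tracks
    }
    for stream in samples:
        for rec in stream:
            if not rec.mapped:
                continue
            if rec.contig not in contig_lengths:
                raise ValueError(f"record {rec.query_id}: unknown contig {rec.contig}")
            if rec.end > contig_lengths[rec.contig] or rec.start < 0:
                raise ValueError(f"record {rec.query_id}: beyond contig bounds")
            d = deltas[(rec.contig, rec.strand)]
            d[rec.start] += 1
            d[rec.end] -= 1
    for key, d in deltas.items():
        tracks[key].depth = np.cumsum(d[:-1])
    return tracks


def segment_peaks(
    track: CoverageTrack,
    peak_threshold: float = DEFAULT_PEAK_THRESHOLD,
    merge_gap: int = 0,
) -> list[tuple[int, int]]:
    """Maximal runs of consecutive bases with depth strictly > peak_threshold.

    Runs separated by more than ``merge_gap`` sub-threshold bases are
    distinct (default 0: any sub-threshold base splits).
    """
    if peak_threshold < 0:
        raise ValueError("peak_threshold must be >= 0")
    above = track.depth > peak_threshold
    if not above.any():
        return []
    # boundaries of True runs via a padded difference
    padded = np.concatenate(([0], above.astype(np.int8), [0]))
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    runs = list(zip(starts.tolist(), ends.tolist()))
    if merge_gap > 0 and len(runs) > 1:
        merged = [runs[0]]
        for s, e in runs[1:]:
            ps, pe = merged[-1]
            if s - pe <= merge_gap:
                merged[-1] = (ps, e)
            else:
                merged.append((s, e))
        runs = merged
    return runs


def filter_peaks(
    candidates: Sequence[tuple[int, int]],
    track: CoverageTrack,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    min_mean_cov: float = DEFAULT_MIN_MEAN_COV,
) -> list[TranscriptionalPeak]:
    """Retain candidates with min_len <= length <= max_len and mean depth
    >= min_mean_cov (inclusive); assign stable ids TP_<contig>_<strand>_<start>."""
    peaks = []
    for start, end in candidates:
        length = end - start
        if not (min_len <= length <= max_len):
            continue
        window = track.depth[start:end]
        mean_cov = float(window.mean())
        if mean_cov < min_mean_cov:
            continue
        peaks.append(
            TranscriptionalPeak(
                tp_id=f"TP_{track.contig}_{track.strand}_{start}",
                contig=track.contig,
                start=start,
                end=end,
                strand=track.strand,
                mean_coverage=mean_cov,
                max_coverage=int(window.max()),
            )
        )
    return peaks


def call_peaks(
    samples: Iterable[Iterable[AlignmentRecord]],
    contig_lengths: dict[str, int],
    peak_threshold: float = DEFAULT_PEAK_THRESHOLD,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    min_mean_cov: float = DEFAULT_MIN_MEAN_COV,
    merge_gap: int = 0,
) -> list[TranscriptionalPeak]:
    """Pool samples, segment each strand independently, filter, and sort."""
    tracks = pool_and_pileup(samples, contig_lengths)
    peaks: list[TranscriptionalPeak] = []
    for track in tracks.values():
        candidates = segment_peaks(track, peak_threshold, merge_gap)
        peaks.extend(filter_peaks(candidates, track, min_len, max_len, min_mean_cov))
    peaks.sort(key=lambda p: (p.contig, p.start, p.end, p.strand))
    return peaks
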