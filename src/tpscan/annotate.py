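"""Genomic-context classification of transcriptional peaks.

A peak is classified against the reference annotation by a decision cascade:

1. ``known`` / ``exact_srna_match`` — it matches an annotated small-RNA
   feature (miRNA, pre-miRNA, piRNA, tRNA, sno/snRNA) on the same strand
   with reciprocal overlap at or above a threshold (default 0.8);
2. ``partially_novel`` / ``nested`` — it lies fully inside some feature;
3. ``partially_novel`` / ``overlapping`` — it partially intersects a feature;
4. ``novel`` / ``intergenic`` — it touches nothing.

Orientation (sense/antisense) is taken from the host with the largest
overlap, ties broken by the smallest feature; intergenic peaks get "n/a".
Classification is against leaf features (exons, introns, UTRs, sRNA genes),
not gene containers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .io_formats import SRNA_BIOTYPES, AnnotationFeature
from .peaks import TranscriptionalPeak

CATEGORIES = ("known", "partially_novel", "novel")


@dataclass(frozen=True)
class TpClassification:
    tp_id: str
    category: str  # known | partially_novel | novel
    relation: str  # exact_srna_match | nested | overlapping | intergenic
    orientation: str  # sense | antisense | n/a
    host_feature_ids: tuple[str, ...]
    host_biotypes: tuple[str, ...]


class GenomeIntervalIndex:
    """Per-contig interval index over annotation features (half-open)."""

    def __init__(self, features: Iterable[AnnotationFeature]):
        self._trees: dict[str, IntervalTree] = {}
        for feat in features:
            self._trees.setdefault(feat.contig, IntervalTree()).addi(
                feat.start, feat.end, feat
            )

    def overlapping(self, contig: str, start: int, end: int) -> list[AnnotationFeature]:
        """All features intersecting [start, end) on ``contig`` (stable order)."""
        tree = self._trees.get(contig)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        hits.sort(key=lambda f: (f.start, f.end, f.feature_id))
        return hits


def build_interval_index(features: Iterable[AnnotationFeature]) -> GenomeIntervalIndex:
    return GenomeIntervalIndex(features)


def _reciprocal_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    inter = min(a_end, b_end) - max(a_start, b_start)
    if inter <= 0:
        return 0.0
    return min(inter / (a_end - a_start), inter / (b_end - b_start))


def classify_tp(
    tp: TranscriptionalPeak,
    index: GenomeIntervalIndex,
    srna_biotypes: frozenset[str] = SRNA_BIOTYPES,
    reciprocal_overlap_for_known: float = 0.8,
    require_same_strand_for_known: bool = True,
) -> TpClassification:
    hits = index.overlapping(tp.contig, tp.start, tp.end)
    if not hits:
        return TpClassification(tp.tp_id, "novel", "intergenic", "n/a", (), ())

    host_ids = tuple(f.feature_id for f in hits)
    host_biotypes = tuple(f.biotype for f in hits)

    # orientation host: largest overlap, ties -> smallest feature
    def overlap_len(f: AnnotationFeature) -> int:
        return min(tp.end, f.end) - max(tp.start, f.start)

    orient_host = max(hits, key=lambda f: (overlap_len(f), -f.length))
    orientation = "sense" if orient_host.strand == tp.strand else "antisense"

    for f in hits:
        if f.biotype not in srna_biotypes:
            continue
        if require_same_strand_for_known and f.strand != tp.strand:
            continue
        if _reciprocal_overlap(tp.start, tp.end, f.start, f.end) >= (
            reciprocal_overlap_for_known
        ):
            orientation = "sense" if f.strand == tp.strand else "antisense"
            return TpClassification(
                tp.tp_id, "known", "exact_srna_match", orientation,
                host_ids, host_biotypes,
            )

    if any(f.start <= tp.start and tp.end <= f.end for f in hits):
        return TpClassification(
            tp.tp_id, "partially_novel", "nested", orientation, host_ids, host_biotypes
        )
    return TpClassification(
        tp.tp_id, "partially_novel", "overlapping", orientation, host_ids, host_biotypes
    )


def classify_all(
    peaks: Sequence[TranscriptionalPeak],
    features: Iterable[AnnotationFeature],
    **kwargs,
) -> list[TpClassification]:
    index = build_interval_index(features)
    return [classify_tp(tp, index, **kwargs) for tp in peaks]


def summarize_classes(classifications: Sequence[TpClassification]) -> dict:
    """Counts and fractions by category, plus relation/orientation/biotype tallies."""
    if not classifications:
        raise ValueError("cannot summarize an empty classification set")
    n = len(classifications)
    counts = {c: 0 for c in CATEGORIES}
    relations: dict[str, int] = {}
    orientations: dict[str, int] = {}
    biotypes: dict[str, int] = {}
    for cl in classifications:
        counts[cl.category] += 1
        relations[cl.relation] = relations.get(cl.relation, 0) + 1
        orientations[cl.orientation] = orientations.get(cl.orientation, 0) + 1
        for bt in set(cl.host_biotypes):
            biotypes[bt] = biotypes.get(bt, 0) + 1
    return {
        "n": n,
        "counts": counts,
        "fractions": {c: counts[c] / n for c in CATEGORIES},
        "relations": relations,
        "orientations": orientations,
        "host_biotypes": biotypes,
    }
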