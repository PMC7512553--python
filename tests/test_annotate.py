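"""Genomic-context classification: cascade rules and brute-force equivalence."""

import numpy as np
import pytest

from tpscan.annotate import (
    build_interval_index,
    classify_all,
    classify_tp,
    summarize_classes,
)
from tpscan.io_formats import SRNA_BIOTYPES, AnnotationFeature
from tpscan.peaks import TranscriptionalPeak


def feature(fid, start, end, strand="+", biotype="coding_exon", contig="chr1"):
    return AnnotationFeature(fid, contig, start, end, strand, biotype)


def peak(start, end, strand="+", contig="chr1"):
    return TranscriptionalPeak(
        tp_id=f"TP_{contig}_{strand}_{start}", contig=contig, start=start,
        end=end, strand=strand, mean_coverage=15.0, max_coverage=20,
    )


def brute_force_classify(tp, features, srna=SRNA_BIOTYPES, rec_ov=0.8):
    """Independent O(N*M) re-derivation of the classification cascade."""
    hits = [
        f for f in features
        if f.contig == tp.contig and min(tp.end, f.end) - max(tp.start, f.start) > 0
    ]
    if not hits:
        return ("novel", "intergenic", "n/a")
    ov = lambda f: min(tp.end, f.end) - max(tp.start, f.start)
    host = max(hits, key=lambda f: (ov(f), -(f.end - f.start)))
    orientation = "sense" if host.strand == tp.strand else "antisense"
    for f in hits:
        inter = ov(f)
        rec = min(inter / (tp.end - tp.start), inter / (f.end - f.start))
        if f.biotype in srna and f.strand == tp.strand and rec >= rec_ov:
            return ("known", "exact_srna_match", "sense")
    if any(f.start <= tp.start and tp.end <= f.end for f in hits):
        return ("partially_novel", "nested", orientation)
    return ("partially_novel", "overlapping", orientation)


class TestIntervalIndex:
    def test_empty_index_returns_nothing(self):
        idx = build_interval_index([])
        assert idx.overlapping("chr1", 0, 1000) == []

    def test_half_open_abutting_query_misses(self):
        idx = build_interval_index([feature("f", 100, 200)])
        assert idx.overlapping("chr1", 200, 300) == []
        assert idx.overlapping("chr1", 50, 100) == []
        assert len(idx.overlapping("chr1", 199, 200)) == 1

    def test_random_queries_match_linear_scan(self, rng):
        feats = [
            feature(f"f{i}", int(s), int(s) + int(l))
            for i, (s, l) in enumerate(
                zip(rng.integers(0, 9_000, 1000), rng.integers(1, 500, 1000))
            )
        ]
        idx = build_interval_index(feats)
        for _ in range(1000):
            q0 = int(rng.integers(0, 9_500))
            q1 = q0 + int(rng.integers(1, 300))
            got = {f.feature_id for f in idx.overlapping("chr1", q0, q1)}
            want = {
                f.feature_id for f in feats
                if min(q1, f.end) - max(q0, f.start) > 0
            }
            assert got == want


class TestClassifyCascade:
    def test_exact_mirna_match_is_known(self):
        feats = [feature("mir", 100, 122, biotype="miRNA")]
        idx = build_interval_index(feats)
        cl = classify_tp(peak(100, 122), idx)
        assert (cl.category, cl.relation, cl.orientation) == (
            "known", "exact_srna_match", "sense",
        )

    def test_opposite_strand_srna_is_not_known(self):
        feats = [feature("mir", 100, 122, strand="-", biotype="miRNA")]
        idx = build_interval_index(feats)
        cl = classify_tp(peak(100, 122), idx)
        assert cl.category == "partially_novel"
        assert cl.relation == "nested"
        assert cl.orientation == "antisense"

    def test_strand_toggle_moves_known_to_partially_novel_only(self):
        feats = [feature("mir", 100, 122, strand="-", biotype="miRNA")]
        idx = build_interval_index(feats)
        strict = classify_tp(peak(100, 122), idx, require_same_strand_for_known=True)
        lax = classify_tp(peak(100, 122), idx, require_same_strand_for_known=False)
        assert strict.category == "partially_novel"
        assert lax.category == "known"

    def test_nested_in_intron_antisense(self):
        feats = [feature("int", 500, 900, strand="+", biotype="intron")]
        idx = build_interval_index(feats)
        cl = classify_tp(peak(600, 640, strand="-"), idx)
        assert (cl.category, cl.relation, cl.orientation) == (
            "partially_novel", "nested", "antisense",
        )

    def test_partial_overlap(self):
        feats = [feature("utr", 500, 600, biotype="three_prime_UTR")]
        idx = build_interval_index(feats)
        cl = classify_tp(peak(580, 630), idx)
        assert (cl.category, cl.relation) == ("partially_novel", "overlapping")

    def test_intergenic_is_novel(self):
        idx = build_interval_index([feature("far", 5000, 6000)])
        cl = classify_tp(peak(100, 140), idx)
        assert (cl.category, cl.relation, cl.orientation) == (
            "novel", "intergenic", "n/a",
        )
        assert cl.host_feature_ids == ()

    def test_containment_beats_partial_overlap(self):
        feats = [
            feature("big", 100, 400, biotype="intron"),
            feature("edge", 380, 500, biotype="coding_exon"),
        ]
        idx = build_interval_index(feats)
        cl = classify_tp(peak(350, 400), idx)
        assert cl.relation == "nested"


class TestOracleEquivalence:
    def test_random_tps_vs_random_annotation(self, rng):
        feats = []
        biotypes = list(SRNA_BIOTYPES) + ["coding_exon", "intron", "three_prime_UTR"]
        for i in range(1000):
            s = int(rng.integers(0, 95_000))
            l = int(rng.integers(20, 800))
            feats.append(
                feature(
                    f"f{i}", s, s + l,
                    strand="+-"[int(rng.integers(0, 2))],
                    biotype=biotypes[int(rng.integers(0, len(biotypes)))],
                )
            )
        idx = build_interval_index(feats)
        agree = 0
        for j in range(1000):
            s = int(rng.integers(0, 98_000))
            l = int(rng.integers(17, 151))
            tp = peak(s, s + l, strand="+-"[int(rng.integers(0, 2))])
            got = classify_tp(tp, idx)
            want = brute_force_classify(tp, feats)
            assert (got.category, got.relation, got.orientation) == want
            agree += 1
        assert agree == 1000


class TestSummary:
    def test_fractions(self):
        cls = classify_all(
            [peak(100, 130)],
            [feature("mir", 100, 130, biotype="miRNA")],
        ) + classify_all(
            [peak(5000 + 40 * i, 5030 + 40 * i) for i in range(8)],
            [feature("big", 4900, 5500, biotype="intron")],
        ) + classify_all([peak(90_000, 90_040)], [])
        summary = summarize_classes(cls)
        assert summary["fractions"] == pytest.approx(
            {"known": 0.1, "partially_novel": 0.8, "novel": 0.1}
        )
        assert abs(sum(summary["fractions"].values()) - 1) < 1e-12

    def test_all_novel(self):
        summary = summarize_classes(classify_all([peak(10, 40), peak(100, 140)], []))
        assert summary["fractions"]["known"] == 0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            summarize_classes([])

    def test_matches_planted_truth(self, small_scenario, small_alignments):
        from tpscan import peaks as pk
        from tpscan.pipeline import match_peak_to_locus

        called = pk.call_peaks(
            small_alignments.values(), small_scenario["contig_lengths"]
        )
        cls = {c.tp_id: c for c in classify_all(called, small_scenario["annotation"])}
        match = match_peak_to_locus(called, small_scenario["loci"])
        expected = {"known": "known", "nested": "partially_novel",
                    "overlapping": "partially_novel", "novel": "novel"}
        n_checked = 0
        for locus in small_scenario["loci"]:
            p = match[locus.locus_id]
            if p is not None:
                assert cls[p.tp_id].category == expected[locus.truth_class]
                if locus.truth_orientation != "n/a":
                    assert cls[p.tp_id].orientation == locus.truth_orientation
                n_checked += 1
        assert n_checked >= 10
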