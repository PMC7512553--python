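"""Read counting over called peaks (featureCounts-style semantics).

A read is assigned to a feature when its span intersects the feature by at
least ``min_overlap`` bases (default 1) and, in stranded mode, the strands
agree.  A read intersecting more than one feature is discarded as ambiguous
(the default of the counting tool this mirrors); reads on unknown contigs
are tallied into an ``unassigned_contig`` bucket.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotate import build_interval_index
from .io_formats import AlignmentRecord, AnnotationFeature
from .peaks import TranscriptionalPeak
from .synth import StudyDesign


@dataclass
class CountResult:
    counts: dict[str, int]
    assigned: int = 0
    ambiguous: int = 0
    no_feature: int = 0
    unassigned_contig: int = 0

    @property
    def total(self) -> int:
        return self.assigned + self.ambiguous + self.no_feature + self.unassigned_contig


@dataclass
class CountMatrix:
    """Features x samples integer counts plus the study design."""

    counts: pd.DataFrame
    design: StudyDesign | None = None
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


def _as_features(features: Sequence) -> list[AnnotationFeature]:
    out = []
    for f in features:
        if isinstance(f, TranscriptionalPeak):
            out.append(
                AnnotationFeature(
                    feature_id=f.tp_id, contig=f.contig, start=f.start,
                    end=f.end, strand=f.strand, biotype="other",
                )
            )
        else:
            out.append(f)
    return out


def count_reads(
    features: Sequence,
    sample: Iterable[AlignmentRecord],
    mode: str = "any_overlap_unstranded",
    min_overlap: int = 1,
) -> CountResult:
    """Count one sample's reads over features (peaks or annotation features)."""
    if mode not in ("any_overlap_unstranded", "any_overlap_stranded"):
        raise ValueError(f"unknown counting mode {mode!r}")
    feats = _as_features(features)
    index = build_interval_index(feats)
    known_contigs = {f.contig for f in feats}
    result = CountResult(counts={f.feature_id: 0 for f in feats})
    for rec in sample:
        if not rec.mapped:
            continue
        if rec.contig not in known_contigs:
            result.unassigned_contig += 1
            continue
        hits = [
            f
            for f in index.overlapping(rec.contig, rec.start, rec.end)
            if min(rec.end, f.end) - max(rec.start, f.start) >= min_overlap
            and (mode == "any_overlap_unstranded" or f.strand == rec.strand)
        ]
        if len(hits) == 0:
            result.no_feature += 1
        elif len(hits) == 1:
            result.counts[hits[0].feature_id] += 1
            result.assigned += 1
        else:
            result.ambiguous += 1
    return result


def assemble_matrix(
    per_sample_counts: dict[str, CountResult],
    sample_sheet: pd.DataFrame,
    design: StudyDesign | None = None,
) -> CountMatrix:
    """Stack per-sample count vectors into a matrix ordered by the sample sheet."""
    sample_ids = list(sample_sheet["sample_id"])
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"duplicated sample ids in sample sheet: {dupes}")
    missing = [s for s in sample_ids if s not in per_sample_counts]
    if missing:
        raise ValueError(f"sample sheet entries without counts: {missing}")
    universes = {tuple(sorted(cr.counts)) for cr in per_sample_counts.values()}
    if len(universes) > 1:
        raise ValueError("samples do not share a common feature universe")
    features = sorted(next(iter(per_sample_counts.values())).counts)
    data = {
        sid: [per_sample_counts[sid].counts[f] for f in features] for sid in sample_ids
    }
    df = pd.DataFrame(data, index=features, columns=sample_ids, dtype=np.int64)
    lib = pd.Series(
        {sid: per_sample_counts[sid].total for sid in sample_ids}, name="library_size"
    )
    return CountMatrix(counts=df, design=design, library_sizes=lib)


def write_counts_tsv(matrix: CountMatrix, path) -> None:
    with open(path, "w") as out:
        out.write("# tpscan counts; library_sizes="
                  + ",".join(f"{s}:{int(v)}" for s, v in matrix.library_sizes.items())
                  + "\n")
        matrix.counts.to_csv(out, sep="\t", index_label="feature_id")


def read_counts_tsv(path) -> CountMatrix:
    with open(path) as fh:
        header = fh.readline()
        lib = None
        if header.startswith("#"):
            if "library_sizes=" in header:
                pairs = header.split("library_sizes=")[1].strip().split(",")
                lib = pd.Series({k: int(v) for k, v in (p.split(":") for p in pairs)})
            df = pd.read_csv(fh, sep="\t", index_col="feature_id")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col="feature_id")
    return CountMatrix(counts=df.astype(np.int64), library_sizes=lib)
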