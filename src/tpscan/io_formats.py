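"""Readers and writers for the on-disk formats the pipeline touches.

All genomic coordinates are 0-based half-open internally.  GFF3 is 1-based
closed on disk and converted on the way in/out; SAM positions are 1-based;
BED is already 0-based half-open.

SAM parsing is delegated to :mod:`pysam`; GFF3 parsing to :mod:`gffutils`
(in-memory database).  BED6 is a plain six-column table and is handled
directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gffutils
import pysam

logger = logging.getLogger(__name__)

# Closed biotype vocabulary.  Unknown feature types map to "other" (logged).
BIOTYPES = frozenset(
    {
        "miRNA",
        "pre_miRNA",
        "rRNA",
        "piRNA_21ur",
        "tRNA",
        "pseudogene",
        "lincRNA",
        "snoRNA",
        "snRNA",
        "coding_exon",
        "intron",
        "five_prime_UTR",
        "three_prime_UTR",
        "other",
    }
)

#: Small-RNA biotypes whose annotated loci a peak can be "known" against.
SRNA_BIOTYPES = frozenset(
    {"miRNA", "pre_miRNA", "piRNA_21ur", "tRNA", "snoRNA", "snRNA"}
)

#: Default mapping from GFF3 ``type`` column (or ``biotype`` attribute) to the
#: internal vocabulary.  Explicit and logged so annotation dialects can be
#: audited; anything absent maps to ``other``.
GFF_TYPE_TO_BIOTYPE = {
    "miRNA": "miRNA",
    "pre_miRNA": "pre_miRNA",
    "miRNA_primary_transcript": "pre_miRNA",
    "rRNA": "rRNA",
    "piRNA": "piRNA_21ur",
    "piRNA_21ur": "piRNA_21ur",
    "tRNA": "tRNA",
    "pseudogene": "pseudogene",
    "lincRNA": "lincRNA",
    "lnc_RNA": "lincRNA",
    "snoRNA": "snoRNA",
    "snRNA": "snRNA",
    "exon": "coding_exon",
    "coding_exon": "coding_exon",
    "intron": "intron",
    "five_prime_UTR": "five_prime_UTR",
    "three_prime_UTR": "three_prime_UTR",
}


class FormatError(ValueError):
    """A malformed on-disk record (carries the offending line number)."""


@dataclass(frozen=True)
class AlignmentRecord:
    """A mapped, strand-aware single-end read span on the reference."""

    query_id: str
    contig: str
    start: int  # 0-based
    end: int  # 0-based exclusive
    strand: str  # "+" or "-"
    mapped: bool = True

    def __post_init__(self) -> None:
        if self.mapped and self.end <= self.start:
            raise ValueError(f"{self.query_id}: end must exceed start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.query_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AnnotationFeature:
    """A reference annotation feature in internal coordinates."""

    feature_id: str
    contig: str
    start: int
    end: int
    strand: str
    biotype: str
    parent_id: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.feature_id}: end must exceed start")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"{self.feature_id}: unknown biotype {self.biotype}")

    @property
    def length(self) -> int:
        return self.end - self.start


def _sort_key(rec: AlignmentRecord) -> tuple[str, int, int]:
    return (rec.contig, rec.start, rec.end)


def read_alignments(path: str | Path, fmt: str | None = None) -> list[AlignmentRecord]:
    """Read mapped alignment records from SAM or BED6.

    Records are returned coordinate-sorted per contig.  Unmapped SAM records
    are skipped and counted (logged).  ``fmt`` defaults from the file suffix.
    """
    path = Path(path)
    if fmt is None:
        fmt = "SAM" if path.suffix.lower() == ".sam" else "BED6"
    fmt = fmt.upper()
    if fmt == "SAM":
        records = _read_sam(path)
    elif fmt == "BED6":
        records = _read_bed6(path)
    else:
        raise ValueError(f"unknown alignment format {fmt!r}")
    records.sort(key=_sort_key)
    return records


def _read_sam(path: Path) -> list[AlignmentRecord]:
    records: list[AlignmentRecord] = []
    skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                skipped += 1
                continue
            # reference_end accounts for reference-consuming CIGAR ops only
            records.append(
                AlignmentRecord(
                    query_id=aln.query_name or "read",
                    contig=aln.reference_name,
                    start=aln.reference_start,
                    end=aln.reference_end,
                    strand="-" if aln.is_reverse else "+",
                )
            )
    if skipped:
        logger.info("skipped %d unmapped records in %s", skipped, path)
    return records


def _read_bed6(path: Path) -> list[AlignmentRecord]:
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if parts[5] not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: bad strand {parts[5]!r}")
            records.append(
                AlignmentRecord(
                    query_id=parts[3],
                    contig=parts[0],
                    start=start,
                    end=end,
                    strand=parts[5],
                )
            )
    return records


def write_alignments_sam(
    records: Sequence[AlignmentRecord],
    contig_lengths: dict[str, int],
    path: str | Path,
) -> None:
    """Write records as minimal mapped single-end SAM (header + ungapped reads)."""
    with open(path, "w") as out:
        out.write("@HD\tVN:1.6\tSO:coordinate\n")
        for contig in sorted(contig_lengths):
            out.write(f"@SQ\tSN:{contig}\tLN:{contig_lengths[contig]}\n")
        for rec in sorted(records, key=_sort_key):
            flag = 16 if rec.strand == "-" else 0
            out.write(
                f"{rec.query_id}\t{flag}\t{rec.contig}\t{rec.start + 1}\t255\t"
                f"{rec.length}M\t*\t0\t0\t*\t*\n"
            )


def write_alignments_bed6(records: Sequence[AlignmentRecord], path: str | Path) -> None:
    with open(path, "w") as out:
        for rec in sorted(records, key=_sort_key):
            out.write(
                f"{rec.contig}\t{rec.start}\t{rec.end}\t{rec.query_id}\t0\t{rec.strand}\n"
            )


def read_annotation(path: str | Path) -> list[AnnotationFeature]:
    """Read a GFF3 annotation into internal 0-based half-open features.

    The biotype is taken from the ``biotype`` attribute when present, else
    mapped from the GFF ``type`` column via :data:`GFF_TYPE_TO_BIOTYPE`;
    anything unrecognized becomes ``other`` with a warning.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    features: list[AnnotationFeature] = []
    for feat in db.all_features():
        if feat.end < feat.start:
            raise FormatError(f"{path}: feature {feat.id}: start > end")
        attr_biotype = feat.attributes.get("biotype", [None])[0]
        biotype = attr_biotype or GFF_TYPE_TO_BIOTYPE.get(feat.featuretype)
        if biotype not in BIOTYPES:
            logger.warning(
                "feature %s: unknown type %r mapped to 'other'", feat.id, feat.featuretype
            )
            biotype = "other"
        parent = feat.attributes.get("Parent", [None])[0]
        features.append(
            AnnotationFeature(
                feature_id=feat.id,
                contig=feat.seqid,
                start=feat.start - 1,  # GFF3 is 1-based closed
                end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else "+",
                biotype=biotype,
                parent_id=parent,
            )
        )
    features.sort(key=lambda f: (f.contig, f.start, f.end, f.feature_id))
    return features


def write_annotation_gff(features: Iterable[AnnotationFeature], path: str | Path) -> None:
    """Write features as GFF3 (1-based closed), sorted by contig then start."""
    feats = sorted(features, key=lambda f: (f.contig, f.start, f.end, f.feature_id))
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for f in feats:
            attrs = f"ID={f.feature_id};biotype={f.biotype}"
            if f.parent_id:
                attrs += f";Parent={f.parent_id}"
            out.write(
                f"{f.contig}\ttpscan\t{f.biotype}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{attrs}\n"
            )


def write_tp_gff(peaks: Sequence, path: str | Path) -> None:
    """Write transcriptional peaks as a custom GFF3 (id, mean/max coverage attrs)."""
    peaks = sorted(peaks, key=lambda p: (p.contig, p.start, p.end, p.strand))
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for p in peaks:
            out.write(
                f"{p.contig}\ttpscan\ttranscriptional_peak\t{p.start + 1}\t{p.end}\t.\t"
                f"{p.strand}\t.\tID={p.tp_id};mean_coverage={p.mean_coverage:.4f};"
                f"max_coverage={p.max_coverage}\n"
            )


def read_tp_gff(path: str | Path):
    """Read a transcriptional-peak GFF3 written by :func:`write_tp_gff`."""
    from .peaks import TranscriptionalPeak

    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF columns")
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            peaks.append(
                TranscriptionalPeak(
                    tp_id=attrs["ID"],
                    contig=cols[0],
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    strand=cols[6],
                    mean_coverage=float(attrs["mean_coverage"]),
                    max_coverage=int(float(attrs["max_coverage"])),
                )
            )
    return peaks


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as out:
        for name, seq in sequences.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
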