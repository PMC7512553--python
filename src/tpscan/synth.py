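"""Synthetic study generator: toy genome, annotation, planted sRNA loci,
strand-aware read pileups, and negative-binomial count matrices with known
ground truth.

The generator emulates a two-generation feeding design: three bacteria
(E. coli OP50 control; P. aeruginosa PAO1 and S. enterica MST1 pathogens),
two generations (F1, F2), three replicate libraries per condition, with
pathogen-vs-control contrasts within each generation.  Every quantity is a
pure function of the supplied seed.

Coverage semantics: ``target_mean_coverage`` of a planted locus is the
*pooled* per-base depth over all libraries at baseline (no condition
effect).  It is split evenly across libraries and scaled per library by
``2**log2fc`` of that library's condition, matching the downstream
count-level model.  Reads are clamped to locus bounds, so realized pooled
coverage is near-rectangular: flat across the locus, zero outside — which
is what makes exact-boundary recovery of sufficiently covered loci a
meaningful check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_formats import AlignmentRecord, AnnotationFeature

BACTERIA = ("OP50", "PAO1", "MST1")
GENERATIONS = ("F1", "F2")
CONTRASTS = ("PAO1_F1", "PAO1_F2", "MST1_F1", "MST1_F2")

_TRUTH_CLASSES = ("known", "nested", "overlapping", "novel")


@dataclass(frozen=True)
class StudyDesign:
    """3 bacteria x 2 generations x n replicates, pathogen-vs-OP50 contrasts."""

    bacteria: tuple[str, ...] = BACTERIA
    generations: tuple[str, ...] = GENERATIONS
    replicates_per_condition: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates_per_condition < 2:
            raise ValueError("need >= 2 replicates per condition")

    @property
    def contrasts(self) -> tuple[str, ...]:
        """Pathogen-vs-control contrast ids, one per pathogen x generation."""
        return tuple(
            f"{b}_{g}" for b in self.bacteria if b != "OP50" for g in self.generations
        )

    @property
    def samples(self) -> list[dict]:
        """Sample sheet rows: sample_id, bacterium, generation, replicate."""
        rows = []
        for b in self.bacteria:
            for g in self.generations:
                for r in range(1, self.replicates_per_condition + 1):
                    rows.append(
                        {
                            "sample_id": f"{b}_{g}_r{r}",
                            "bacterium": b,
                            "generation": g,
                            "replicate": r,
                        }
                    )
        return rows

    @property
    def n_samples(self) -> int:
        return len(self.bacteria) * len(self.generations) * self.replicates_per_condition

    def condition_multiplier(self, bacterium: str, generation: str,
                             planted_log2fc: Mapping[str, float]) -> float:
        """2**log2fc for the contrast this condition belongs to (1 for control)."""
        key = f"{bacterium}_{generation}"
        if bacterium == "OP50" or key not in planted_log2fc:
            return 1.0
        return float(2.0 ** planted_log2fc[key])


@dataclass(frozen=True)
class PlantedLocus:
    """A ground-truth sRNA locus planted into the synthetic genome."""

    locus_id: str
    contig: str
    start: int
    end: int
    strand: str
    target_mean_coverage: float
    truth_class: str
    truth_orientation: str = "n/a"
    planted_log2fc: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.locus_id}: end must exceed start")
        if not 1 <= self.end - self.start <= 500:
            raise ValueError(f"{self.locus_id}: length outside 1..500")
        if self.truth_class not in _TRUTH_CLASSES:
            raise ValueError(f"{self.locus_id}: bad truth class {self.truth_class}")
        if self.target_mean_coverage < 0:
            raise ValueError(f"{self.locus_id}: negative coverage target")

    @property
    def length(self) -> int:
        return self.end - self.start


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def generate_genome_and_annotation(
    n_contigs: int = 1,
    contig_length: int = 50_000,
    seed: int = 0,
) -> tuple[dict[str, str], list[AnnotationFeature]]:
    """Generate a toy genome plus an annotation with the required biotype mix.

    Each contig hosts at least: miRNA loci (with pre-miRNA parents), one rRNA
    gene, coding genes with UTR/exon/intron sub-features, a tRNA, a piRNA and
    a lincRNA, separated by guaranteed intergenic gaps >= 1,000 nt.
    Deterministic for a fixed seed.
    """
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    if contig_length < 10_000:
        raise ValueError("contig_length must be >= 10,000 to host the feature mix")

    rng = np.random.default_rng(seed)
    genome: dict[str, str] = {}
    features: list[AnnotationFeature] = []

    for c in range(n_contigs):
        contig = f"chrS{c + 1}"
        genome[contig] = _random_seq(rng, contig_length)
        features.extend(_annotate_contig(contig, contig_length, rng))

    features.sort(key=lambda f: (f.contig, f.start, f.end, f.feature_id))
    return genome, features


def _annotate_contig(
    contig: str, contig_length: int, rng: np.random.Generator
) -> list[AnnotationFeature]:
    feats: list[AnnotationFeature] = []
    cursor = 300 + int(rng.integers(0, 200))

    def gap(minimum: int, spread: int = 300) -> None:
        nonlocal cursor
        cursor += minimum + int(rng.integers(0, spread))

    def strand() -> str:
        return "+" if rng.random() < 0.5 else "-"

    # Two coding genes: 5'UTR - exon - intron - exon - 3'UTR
    for g in range(1, 3):
        s = strand()
        gene_id = f"{contig}_gene{g}"
        utr5 = int(rng.integers(80, 150))
        exon1 = int(rng.integers(150, 300))
        intron = int(rng.integers(250, 450))
        exon2 = int(rng.integers(150, 300))
        utr3 = int(rng.integers(100, 200))
        parts = [
            ("five_prime_UTR", utr5),
            ("coding_exon", exon1),
            ("intron", intron),
            ("coding_exon", exon2),
            ("three_prime_UTR", utr3),
        ]
        if s == "-":
            parts = parts[::-1]
        pos = cursor
        for i, (biotype, length) in enumerate(parts):
            feats.append(
                AnnotationFeature(
                    feature_id=f"{gene_id}_{biotype}{i}",
                    contig=contig,
                    start=pos,
                    end=pos + length,
                    strand=s,
                    biotype=biotype,
                    parent_id=gene_id,
                )
            )
            pos += length
        cursor = pos
        gap(1_100)  # guaranteed intergenic gap >= 1,000 nt

    # Two miRNA hairpins, each a pre-miRNA hosting a 22-nt mature miRNA
    for m in range(1, 3):
        s = strand()
        pre_len = int(rng.integers(55, 70))
        mat_off = int(rng.integers(5, pre_len - 27))
        feats.append(
            AnnotationFeature(
                feature_id=f"{contig}_pre_mir{m}",
                contig=contig,
                start=cursor,
                end=cursor + pre_len,
                strand=s,
                biotype="pre_miRNA",
            )
        )
        feats.append(
            AnnotationFeature(
                feature_id=f"{contig}_mir{m}",
                contig=contig,
                start=cursor + mat_off,
                end=cursor + mat_off + 22,
                strand=s,
                biotype="miRNA",
                parent_id=f"{contig}_pre_mir{m}",
            )
        )
        cursor += pre_len
        gap(1_100)

    singles = [
        ("rRNA", int(rng.integers(600, 900))),
        ("tRNA", 72),
        ("piRNA_21ur", 21),
        ("lincRNA", int(rng.integers(200, 400))),
        ("snoRNA", int(rng.integers(60, 120))),
    ]
    for biotype, length in singles:
        feats.append(
            AnnotationFeature(
                feature_id=f"{contig}_{biotype}1",
                contig=contig,
                start=cursor,
                end=cursor + length,
                strand=strand(),
                biotype=biotype,
            )
        )
        cursor += length
        gap(1_100)

    if cursor > contig_length - 1_000:
        raise ValueError(
            f"contig_length {contig_length} too small to host the feature mix"
        )
    return feats


def plant_loci_and_simulate_alignments(
    genome: dict[str, str],
    annotation: Sequence[AnnotationFeature],
    loci: Sequence[PlantedLocus],
    design: StudyDesign,
    read_length: int = 24,
    background_reads_per_kb: float = 0.05,
    poisson_depth: bool = True,
) -> dict[str, list[AlignmentRecord]]:
    """Simulate per-library strand-aware alignment records over planted loci.

    Per library, the expected locus coverage is ``target / n_samples`` times
    the library's condition multiplier; read intervals are clamped to the
    locus so pooled coverage is flat over the locus and zero outside.  Read
    start offsets are stratified (evenly spaced with a random per-library
    phase) so realized depth stays within ~1 read of flat per library.
    Background reads are placed sparsely away from loci with pooled depth
    capped at 2.
    """
    if not 17 <= read_length <= 36:
        raise ValueError("read_length must be within 17..36")
    contig_lengths = {c: len(s) for c, s in genome.items()}
    for locus in loci:
        if locus.contig not in contig_lengths:
            raise ValueError(f"{locus.locus_id}: unknown contig {locus.contig}")
        if locus.start < 0 or locus.end > contig_lengths[locus.contig]:
            raise ValueError(f"{locus.locus_id}: outside contig bounds")

    rng = np.random.default_rng(design.seed)
    out: dict[str, list[AlignmentRecord]] = {}
    samples = design.samples
    n_samples = len(samples)

    for sample in samples:
        srng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        recs: list[AlignmentRecord] = []
        for locus in loci:
            mult = design.condition_multiplier(
                sample["bacterium"], sample["generation"], locus.planted_log2fc
            )
            per_sample_cov = locus.target_mean_coverage * mult / n_samples
            recs.extend(
                _locus_reads(locus, per_sample_cov, read_length, srng,
                             sample["sample_id"], poisson_depth)
            )
        recs.extend(
            _background_reads(
                contig_lengths, loci, read_length, background_reads_per_kb,
                srng, sample["sample_id"],
            )
        )
        recs.sort(key=lambda r: (r.contig, r.start, r.end))
        out[sample["sample_id"]] = recs
    return out


def _locus_reads(
    locus: PlantedLocus,
    per_sample_cov: float,
    read_length: int,
    rng: np.random.Generator,
    sample_id: str,
    poisson_depth: bool,
) -> list[AlignmentRecord]:
    if per_sample_cov <= 0:
        return []
    L = locus.length
    rl = min(read_length, L)
    span = L + rl - 1  # admissible unclamped start offsets
    expected_n = per_sample_cov * span / rl
    n = int(rng.poisson(expected_n)) if poisson_depth else int(round(expected_n))
    if n == 0:
        return []
    # stratified offsets: even grid + random phase, so per-library depth is
    # within ~1 read of flat across the locus
    phase = rng.integers(0, span)
    offsets = (phase + np.floor(np.arange(n) * span / n).astype(int)) % span
    reads = []
    lo = locus.start - rl + 1
    for k, off in enumerate(offsets):
        a = lo + int(off)
        start = max(locus.start, a)
        end = min(locus.end, a + rl)
        reads.append(
            AlignmentRecord(
                query_id=f"{sample_id}_{locus.locus_id}_{k}",
                contig=locus.contig,
                start=start,
                end=end,
                strand=locus.strand,
            )
        )
    return reads


def _background_reads(
    contig_lengths: dict[str, int],
    loci: Sequence[PlantedLocus],
    read_length: int,
    per_kb: float,
    rng: np.random.Generator,
    sample_id: str,
) -> list[AlignmentRecord]:
    """Sparse background on a coarse grid, kept clear of planted loci.

    Grid slots are ~1 kb apart and each slot receives at most one read per
    library drawn with probability `per_kb`, so pooled depth at any base is
    bounded well below the peak threshold for realistic designs.
    """
    reads = []
    for contig, length in contig_lengths.items():
        exclusion = [
            (l.start - read_length, l.end + read_length)
            for l in loci
            if l.contig == contig
        ]
        for slot in range(200, length - read_length, 1_000):
            if any(s <= slot < e for s, e in exclusion):
                continue
            if rng.random() < per_kb:
                strand = "+" if rng.random() < 0.5 else "-"
                reads.append(
                    AlignmentRecord(
                        query_id=f"{sample_id}_bg_{contig}_{slot}",
                        contig=contig,
                        start=slot,
                        end=slot + read_length,
                        strand=strand,
                    )
                )
    return reads


def simulate_count_matrix(
    features: Sequence[str],
    design: StudyDesign,
    baseline_mean: float = 100.0,
    dispersion: float = 0.1,
    planted_log2fc: Mapping[str, Mapping[str, float]] | None = None,
    size_factors: Mapping[str, float] | None = None,
    seed: int = 0,
):
    """Draw an NB counts table (features x samples) with planted effects.

    mean = baseline * 2**log2fc(condition) * sample size factor;
    ``dispersion`` is the NB phi (variance = mu + phi mu^2); phi = 0 degrades
    to Poisson.  Deterministic per seed.  Returns a pandas DataFrame.
    """
    import pandas as pd

    if baseline_mean <= 0:
        raise ValueError("baseline_mean must be positive")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    planted_log2fc = planted_log2fc or {}
    rng = np.random.default_rng(seed)
    samples = design.samples
    sample_ids = [s["sample_id"] for s in samples]
    sf = {sid: (size_factors or {}).get(sid, 1.0) for sid in sample_ids}

    counts = np.zeros((len(features), len(samples)), dtype=np.int64)
    for j, sample in enumerate(samples):
        mu = np.full(len(features), baseline_mean, dtype=float)
        for i, fid in enumerate(features):
            lfc = planted_log2fc.get(fid, {})
            mu[i] *= design.condition_multiplier(
                sample["bacterium"], sample["generation"], lfc
            )
        mu *= sf[sample["sample_id"]]
        if dispersion == 0:
            counts[:, j] = rng.poisson(mu)
        else:
            r = 1.0 / dispersion
            p = r / (r + mu)
            counts[:, j] = rng.negative_binomial(r, p)
    return pd.DataFrame(counts, index=list(features), columns=sample_ids)


def default_scenario(seed: int = 0) -> dict:
    """The default synthetic study: 1 contig x 50 kb, ~20 planted loci.

    Loci straddle the peak-calling thresholds (coverage above/below 10x
    pooled, lengths below/within/above 17..150) and cover all four truth
    classes.  One locus (the mir-243 analog) is planted +2 log2 in all four
    pathogen contrasts; one (the mir-70 analog) is planted -2 in all four;
    others are bacterium-, generation-specific, or null.
    """
    genome, annotation = generate_genome_and_annotation(1, 50_000, seed=seed)
    design = StudyDesign(seed=seed)
    contig = next(iter(genome))
    by_biotype: dict[str, list[AnnotationFeature]] = {}
    for f in annotation:
        by_biotype.setdefault(f.biotype, []).append(f)

    mir1, mir2 = by_biotype["miRNA"][:2]
    intron = by_biotype["intron"][0]
    rrna = by_biotype["rRNA"][0]
    utr3 = by_biotype["three_prime_UTR"][0]
    utr5 = by_biotype["five_prime_UTR"][0]

    all4_up = {c: 2.0 for c in CONTRASTS}
    all4_down = {c: -2.0 for c in CONTRASTS}
    occupied = sorted((f.start, f.end) for f in annotation)

    def alloc_intergenic(length: int, margin: int = 250) -> tuple[int, int]:
        """Place a locus at the midpoint of the current largest free gap."""
        gaps = []
        prev = 0
        for s, e in sorted(occupied):
            if s - prev >= length + 2 * margin:
                gaps.append((prev, s))
            prev = max(prev, e)
        if len(genome[contig]) - prev >= length + 2 * margin:
            gaps.append((prev, len(genome[contig])))
        g0, g1 = max(gaps, key=lambda g: g[1] - g[0])
        mid = (g0 + g1 - length) // 2
        occupied.append((mid, mid + length))
        return mid, mid + length

    loci: list[PlantedLocus] = []

    def add(locus_id, start, end, strand, cov, tclass, orient="n/a", lfc=None):
        loci.append(
            PlantedLocus(
                locus_id=locus_id,
                contig=contig,
                start=start,
                end=end,
                strand=strand,
                target_mean_coverage=cov,
                truth_class=tclass,
                truth_orientation=orient,
                planted_log2fc=lfc or {},
            )
        )

    # the mir-243 analog: known miRNA locus, up in all four contrasts
    add("mir243_analog", mir1.start, mir1.end, mir1.strand, 150, "known", "sense",
        all4_up)
    # the mir-70 analog: known miRNA locus, down in all four contrasts;
    # generous baseline so the pooled pileup still clears the 10x threshold
    add("mir70_analog", mir2.start, mir2.end, mir2.strand, 300, "known", "sense",
        all4_down)
    # nested loci: inside an intron (antisense) and inside the rRNA (sense)
    add("nested_intron", intron.start + 40, intron.start + 40 + 24,
        "-" if intron.strand == "+" else "+", 120, "nested", "antisense",
        {"PAO1_F1": 2.0, "PAO1_F2": 2.0})  # bacterium-specific up
    add("nested_rrna", rrna.start + 100, rrna.start + 100 + 30, rrna.strand,
        150, "nested", "sense", {"MST1_F1": 2.0})  # generation-specific up
    # overlapping loci: straddle UTR edges
    add("overlap_utr3", utr3.end - 12, utr3.end - 12 + 28, utr3.strand, 160,
        "overlapping", "sense", {"PAO1_F1": -2.0, "MST1_F1": -2.0})
    add("overlap_utr5", utr5.start - 15, utr5.start - 15 + 30,
        "-" if utr5.strand == "+" else "+", 100, "overlapping", "antisense")
    # novel intergenic loci, null effects, straddling thresholds
    s, e = alloc_intergenic(40)
    add("novel_pass", s, e, "+", 80, "novel")
    s, e = alloc_intergenic(120)
    add("novel_long_pass", s, e, "-", 40, "novel")
    s, e = alloc_intergenic(60)
    add("novel_low_cov", s, e, "+", 5, "novel")  # fails the >10 pooled rule
    s, e = alloc_intergenic(16)
    add("novel_too_short", s, e, "+", 40, "novel")  # fails the 17-nt minimum
    s, e = alloc_intergenic(170)
    add("novel_too_long", s, e, "-", 30, "novel")  # fails the 150-nt maximum
    s, e = alloc_intergenic(17)
    add("novel_min_len", s, e, "+", 60, "novel")  # exactly 17 nt: retained
    s, e = alloc_intergenic(150)
    add("novel_max_len", s, e, "-", 40, "novel")  # exactly 150 nt: retained
    s, e = alloc_intergenic(50)
    add("novel_up_pao1_f2", s, e, "+", 100, "novel", "n/a", {"PAO1_F2": 2.5})
    s, e = alloc_intergenic(45)
    add("novel_down_mst1", s, e, "-", 160, "novel", "n/a",
        {"MST1_F1": -2.0, "MST1_F2": -2.0})
    s, e = alloc_intergenic(35)
    add("novel_zero", s, e, "+", 0, "novel")  # no reads at all
    s, e = alloc_intergenic(80)
    add("novel_mid", s, e, "-", 20, "novel")
    s, e = alloc_intergenic(55)
    add("novel_quiet", s, e, "+", 60, "novel")
    s, e = alloc_intergenic(70)
    add("novel_extra", s, e, "-", 90, "novel")
    s, e = alloc_intergenic(26)
    add("novel_small", s, e, "+", 120, "novel")

    return {
        "genome": genome,
        "annotation": annotation,
        "design": design,
        "loci": loci,
        "contig_lengths": {c: len(s_) for c, s_ in genome.items()},
    }
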