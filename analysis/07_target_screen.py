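#!/usr/bin/env python
"""Seed + free-energy screen of the universal miRNA against downregulated
transcripts.

Takes the mature sequence of the universally upregulated peak from the
synthetic genome and screens it against the transcript sequences of all
peaks called down in any contrast, plus one synthetic positive-control
transcript carrying a planted 14-nt complementary site.  Hits require a
perfect-complement seed >= 12 nt; each is scored with the nearest-neighbor
duplex energy at 20 degC.
"""

import json
from pathlib import Path

import pandas as pd

from tpscan import io_formats, targets

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"
COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def transcript(genome: dict[str, str], contig, start, end, strand) -> str:
    seq = genome[contig][start:end].replace("T", "U")
    if strand == "-":
        seq = "".join(COMP[b] for b in reversed(seq))
    return seq


def main() -> None:
    genome = io_formats.read_fasta(OUT / "genome.fa")
    venn_report = json.loads((OUT / "venn_report.json").read_text())
    peaks = {p.tp_id: p for p in io_formats.read_tp_gff(OUT / "transcriptional_peaks.gff3")}

    (mirna_tp_id,) = venn_report["up"]["shared_all"]
    mp = peaks[mirna_tp_id]
    mirna = transcript(genome, mp.contig, mp.start, mp.end, mp.strand)

    down_ids = sorted(
        {fid for cells in venn_report["down"]["cells"].values() for fid in cells}
    )
    candidates = {
        fid: transcript(genome, peaks[fid].contig, peaks[fid].start,
                        peaks[fid].end, peaks[fid].strand)
        for fid in down_ids
        if peaks[fid].length >= 8
    }
    # synthetic positive control: a transcript with a planted 14-nt site
    site = "".join(COMP[b] for b in reversed(mirna[4:18]))
    candidates["synthetic_positive_control"] = (
        "ACGU" * 25 + site + "UGCA" * 25
    )

    hits = targets.screen_targets(mirna, candidates, mirna_id=mirna_tp_id)
    pd.DataFrame(
        {
            "mirna": [h.mirna_id for h in hits],
            "target": [h.target_id for h in hits],
            "seed_len": [h.seed_length for h in hits],
            "target_span": [f"{h.target_span[0]}-{h.target_span[1]}" for h in hits],
            "nfe_kcal_mol": [round(h.nfe, 3) for h in hits],
            "strong": [h.strong for h in hits],
        }
    ).to_csv(OUT / "target_hits.tsv", sep="\t", index=False)
    print(f"screened {len(candidates)} downregulated transcripts against "
          f"{mirna_tp_id} ({len(mirna)} nt): {len(hits)} hits with seed >= 12")
    for h in hits:
        print(f"  {h.target_id}: seed {h.seed_length} nt, "
              f"dG = {h.nfe:.2f} kcal/mol{' (strong)' if h.strong else ''}")


if __name__ == "__main__":
    main()
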