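#!/usr/bin/env python
"""Generate the synthetic two-generation feeding study.

Writes the toy genome, the annotation, one SAM per library (3 bacteria x 2
generations x 3 replicates), the sample sheet, and the planted-locus truth
table under results/analysis/.
"""

import argparse
from pathlib import Path

import pandas as pd

from tpscan import io_formats, synth

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    OUT.mkdir(parents=True, exist_ok=True)
    scenario = synth.default_scenario(seed=args.seed)
    io_formats.write_fasta(scenario["genome"], OUT / "genome.fa")
    io_formats.write_annotation_gff(scenario["annotation"], OUT / "annotation.gff3")
    with open(OUT / "contig_lengths.tsv", "w") as fh:
        for c, n in scenario["contig_lengths"].items():
            fh.write(f"{c}\t{n}\n")

    alignments = synth.plant_loci_and_simulate_alignments(
        scenario["genome"], scenario["annotation"], scenario["loci"],
        scenario["design"],
    )
    for sid, recs in alignments.items():
        io_formats.write_alignments_sam(recs, scenario["contig_lengths"],
                                        OUT / f"{sid}.sam")
    pd.DataFrame(scenario["design"].samples).to_csv(
        OUT / "sample_sheet.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [
            {
                "locus_id": l.locus_id, "contig": l.contig, "start": l.start,
                "end": l.end, "strand": l.strand,
                "target_mean_coverage": l.target_mean_coverage,
                "truth_class": l.truth_class,
                "planted_log2fc": ";".join(
                    f"{k}:{v}" for k, v in sorted(l.planted_log2fc.items())
                ),
            }
            for l in scenario["loci"]
        ]
    ).to_csv(OUT / "planted_loci.tsv", sep="\t", index=False)

    n_reads = sum(len(r) for r in alignments.values())
    print(f"wrote {len(alignments)} libraries ({n_reads} reads), "
          f"{len(scenario['loci'])} planted loci, seed={args.seed}")


if __name__ == "__main__":
    main()
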