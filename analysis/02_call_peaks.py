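#!/usr/bin/env python
"""Pool all libraries and call transcriptional peaks.

Reads the SAM files from step 01, merges them into strand-specific pileups,
segments runs of depth > 10 per base, keeps runs of 17-150 nt with mean
depth >= 10, and writes the custom peak GFF3.
"""

from pathlib import Path

import pandas as pd

from tpscan import io_formats, peaks

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"


def main() -> None:
    sheet = pd.read_csv(OUT / "sample_sheet.tsv", sep="\t")
    lengths = {}
    for line in (OUT / "contig_lengths.tsv").read_text().splitlines():
        c, n = line.split("\t")
        lengths[c] = int(n)
    streams = [
        io_formats.read_alignments(OUT / f"{sid}.sam") for sid in sheet["sample_id"]
    ]
    called = peaks.call_peaks(streams, lengths)
    io_formats.write_tp_gff(called, OUT / "transcriptional_peaks.gff3")
    print(f"called {len(called)} transcriptional peaks from "
          f"{len(streams)} pooled libraries")
    for p in called:
        print(f"  {p.tp_id}: {p.length} nt, mean {p.mean_coverage:.1f}x, "
              f"max {p.max_coverage}x")


if __name__ == "__main__":
    main()
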