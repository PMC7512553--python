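#!/usr/bin/env python
"""Consensus differential expression for all four pathogen-vs-control
contrasts.

For each pathogen x generation, the pathogen libraries are compared with the
OP50 control libraries of the same generation using the NB Wald test
(median-of-ratios normalization, BH adjustment) and the conditional NB exact
test (TMM-equalized pseudo-counts).  A feature is called when |log2FC| > 1,
padj(Wald) < 0.05 and p(exact) < 0.05.
"""

from pathlib import Path

from tpscan import de, quantify, synth

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"


def main() -> None:
    matrix = quantify.read_counts_tsv(OUT / "counts.tsv")
    matrix.design = synth.StudyDesign()
    for cid, table in de.run_all_contrasts(matrix).items():
        table.to_csv(OUT / f"de_{cid}.tsv", sep="\t", index=False)
        up = list(table.index[table["call"] == "up"])
        down = list(table.index[table["call"] == "down"])
        print(f"{cid}: {len(up)} up {up}, {len(down)} down {down}")


if __name__ == "__main__":
    main()
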