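#!/usr/bin/env python
"""Classify each peak by genomic context against the annotation.

Every peak becomes known (matching an annotated sRNA), partially novel
(nested in or overlapping a feature, sense or antisense), or novel
(intergenic).  Writes the per-peak table and a category summary.
"""

import json
from pathlib import Path

import pandas as pd

from tpscan import annotate, io_formats

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"


def main() -> None:
    called = io_formats.read_tp_gff(OUT / "transcriptional_peaks.gff3")
    features = io_formats.read_annotation(OUT / "annotation.gff3")
    classifications = annotate.classify_all(called, features)
    pd.DataFrame(
        {
            "tp_id": [c.tp_id for c in classifications],
            "category": [c.category for c in classifications],
            "relation": [c.relation for c in classifications],
            "orientation": [c.orientation for c in classifications],
            "hosts": [",".join(c.host_feature_ids) for c in classifications],
            "host_biotypes": [",".join(c.host_biotypes) for c in classifications],
        }
    ).to_csv(OUT / "peak_classification.tsv", sep="\t", index=False)
    summary = annotate.summarize_classes(classifications)
    (OUT / "classification_summary.json").write_text(json.dumps(summary, indent=2))
    f = summary["fractions"]
    print(f"{summary['n']} peaks: {f['known']:.1%} known, "
          f"{f['partially_novel']:.1%} partially novel, {f['novel']:.1%} novel")


if __name__ == "__main__":
    main()
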