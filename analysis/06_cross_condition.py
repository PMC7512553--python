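#!/usr/bin/env python
"""Cross-condition set logic: which peaks respond on both pathogens in both
generations?

Builds the four-set Venn membership per direction from the DE tables and
flags shared-all features — the pattern that singles out a universally
induced small RNA — alongside bacterium- and generation-specific ones.
"""

import json
from pathlib import Path

import pandas as pd

from tpscan import venn

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"
CONTRASTS = ("PAO1_F1", "PAO1_F2", "MST1_F1", "MST1_F2")


def main() -> None:
    tables = {
        cid: pd.read_csv(OUT / f"de_{cid}.tsv", sep="\t", index_col="feature_id")
        for cid in CONTRASTS
    }
    report = {}
    for direction in ("up", "down"):
        r = venn.build_venn(tables, direction)
        report[direction] = {
            "shared_all": r.shared_all,
            "bacterium_specific": r.bacterium_specific,
            "generation_specific": r.generation_specific,
            "cells": {
                "+".join(sorted(k)): v for k, v in r.venn_cells().items()
            },
        }
    (OUT / "venn_report.json").write_text(json.dumps(report, indent=2))

    up = venn.build_venn(tables, "up")
    down = venn.build_venn(tables, "down")
    universal = venn.flag_universal_candidates(up, down, tables)
    universal.to_csv(OUT / "universal_candidates.tsv", sep="\t", index=False)
    print("shared-all up:", report["up"]["shared_all"])
    print("shared-all down:", report["down"]["shared_all"])


if __name__ == "__main__":
    main()
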