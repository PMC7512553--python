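"""Set logic across pathogens and generations.

Features are identified by their peak id from the single pooled peak call,
so membership across the four pathogen-vs-control contrasts (PAO1_F1,
PAO1_F2, MST1_F1, MST1_F2) is well defined.  The report partitions DE
features by their Venn cell per direction and singles out features
responsive in all four contrasts — the pattern that isolates a universally
induced sRNA — plus bacterium-specific (both generations of exactly one
pathogen) and generation-specific (exactly one contrast) features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

FULL_CONTRAST_SET = frozenset({"PAO1_F1", "PAO1_F2", "MST1_F1", "MST1_F2"})


@dataclass
class SharedFeatureReport:
    direction: str  # up | down
    membership: dict[str, frozenset[str]]
    shared_all: list[str] = field(default_factory=list)
    bacterium_specific: list[str] = field(default_factory=list)
    generation_specific: list[str] = field(default_factory=list)

    def venn_cells(self) -> dict[frozenset[str], list[str]]:
        cells: dict[frozenset[str], list[str]] = {}
        for fid, mem in self.membership.items():
            cells.setdefault(mem, []).append(fid)
        for v in cells.values():
            v.sort()
        return cells


def build_venn(
    de_tables: Mapping[str, pd.DataFrame],
    direction: str,
    contrasts: frozenset[str] = FULL_CONTRAST_SET,
) -> SharedFeatureReport:
    """Partition features called ``direction`` by the contrasts calling them."""
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    missing = sorted(contrasts - set(de_tables))
    if missing:
        raise ValueError(f"missing contrasts: {missing}")

    membership: dict[str, set[str]] = {}
    for cid in sorted(contrasts):
        table = de_tables[cid]
        for fid in table.index[table["call"] == direction]:
            membership.setdefault(fid, set()).add(cid)

    frozen = {fid: frozenset(mem) for fid, mem in membership.items()}
    report = SharedFeatureReport(direction=direction, membership=frozen)
    pathogens = {c.rsplit("_", 1)[0] for c in contrasts}
    for fid, mem in sorted(frozen.items()):
        if mem == contrasts:
            report.shared_all.append(fid)
        elif len(mem) == 1:
            report.generation_specific.append(fid)
        else:
            mem_pathogens = {c.rsplit("_", 1)[0] for c in mem}
            if len(mem_pathogens) == 1 and len(mem) == 2:
                report.bacterium_specific.append(fid)
    return report


def flag_universal_candidates(
    report_up: SharedFeatureReport,
    report_down: SharedFeatureReport,
    de_tables: Mapping[str, pd.DataFrame],
    classifications: Sequence | None = None,
) -> pd.DataFrame:
    """Features DE in the same direction in all four contrasts, annotated with
    their genomic-context classification and per-contrast log2 fold changes."""
    class_by_id = {c.tp_id: c for c in (classifications or [])}
    rows = []
    for report in (report_up, report_down):
        for fid in report.shared_all:
            row = {"feature_id": fid, "direction": report.direction}
            cl = class_by_id.get(fid)
            row["category"] = cl.category if cl else "unclassified"
            row["relation"] = cl.relation if cl else "unclassified"
            for cid, table in sorted(de_tables.items()):
                row[f"log2fc_{cid}"] = (
                    float(table.loc[fid, "log2fc"]) if fid in table.index else float("nan")
                )
            rows.append(row)
    return pd.DataFrame(rows)
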