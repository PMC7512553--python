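"""End-to-end driver: synthetic study -> peaks -> classes -> counts -> DE ->
cross-condition report.

This is the single entry point the analysis scripts and the acceptance
script share.  Everything is computed from the seed at run time.
"""

from __future__ import annotations

import pandas as pd

from . import annotate, de, peaks, quantify, synth, venn


def run_default_pipeline(seed: int = 0) -> dict:
    """Run the whole discovery pipeline on the default synthetic scenario.

    Returns a dict with the scenario, called peaks, classifications, count
    matrix, per-contrast DE tables, Venn reports, and the universal
    candidate table.
    """
    scenario = synth.default_scenario(seed=seed)
    design = scenario["design"]
    alignments = synth.plant_loci_and_simulate_alignments(
        scenario["genome"], scenario["annotation"], scenario["loci"], design
    )

    called = peaks.call_peaks(alignments.values(), scenario["contig_lengths"])
    classifications = annotate.classify_all(called, scenario["annotation"])
    summary = annotate.summarize_classes(classifications) if classifications else None

    per_sample = {
        sid: quantify.count_reads(called, recs, mode="any_overlap_stranded")
        for sid, recs in alignments.items()
    }
    sheet = pd.DataFrame(design.samples)
    matrix = quantify.assemble_matrix(per_sample, sheet, design=design)

    de_tables = de.run_all_contrasts(matrix)
    report_up = venn.build_venn(de_tables, "up")
    report_down = venn.build_venn(de_tables, "down")
    universal = venn.flag_universal_candidates(
        report_up, report_down, de_tables, classifications
    )

    return {
        "scenario": scenario,
        "alignments": alignments,
        "peaks": called,
        "classifications": classifications,
        "class_summary": summary,
        "count_matrix": matrix,
        "de_tables": de_tables,
        "venn_up": report_up,
        "venn_down": report_down,
        "universal_candidates": universal,
    }


def match_peak_to_locus(called, loci, max_slack: int = 0):
    """Map each planted locus to a called peak with identical boundaries
    (or within max_slack nt); returns {locus_id: peak or None}."""
    out = {}
    for locus in loci:
        hit = None
        for p in called:
            if (
                p.contig == locus.contig
                and p.strand == locus.strand
                and abs(p.start - locus.start) <= max_slack
                and abs(p.end - locus.end) <= max_slack
            ):
                hit = p
                break
        out[locus.locus_id] = hit
    return out
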