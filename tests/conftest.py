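import numpy as np
import pytest

from tpscan import synth


@pytest.fixture(scope="session")
def small_scenario():
    """Default synthetic scenario at a fixed seed, shared across tests."""
    return synth.default_scenario(seed=7)


@pytest.fixture(scope="session")
def small_alignments(small_scenario):
    return synth.plant_loci_and_simulate_alignments(
        small_scenario["genome"],
        small_scenario["annotation"],
        small_scenario["loci"],
        small_scenario["design"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def brute_force_pileup(records, contig_lengths):
    """Independent per-base pileup oracle: increment every covered base."""
    depth = {
        (c, s): np.zeros(n, dtype=int)
        for c, n in contig_lengths.items()
        for s in "+-"
    }
    for rec in records:
        for i in range(rec.start, rec.end):
            depth[(rec.contig, rec.strand)][i] += 1
    return depth


def brute_force_peaks(depth, threshold=10, min_len=17, max_len=150, min_mean=10.0):
    """Independent per-base scanner: runs of depth > threshold, then filters."""
    out = []
    run_start = None
    for i, d in enumerate(list(depth) + [0]):
        if d > threshold and run_start is None:
            run_start = i
        elif d <= threshold and run_start is not None:
            length = i - run_start
            window = depth[run_start:i]
            if min_len <= length <= max_len and np.mean(window) >= min_mean:
                out.append((run_start, i, float(np.mean(window)), int(np.max(window))))
            run_start = None
    return out
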