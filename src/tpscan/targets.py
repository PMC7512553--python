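"""miRNA target screening by maximal perfect-complement seed search plus
nearest-neighbor RNA duplex hybridization free energy.

The screen looks for the longest contiguous antiparallel Watson-Crick
complement (the "seed" in this pipeline's usage) between a mature miRNA and
each candidate transcript, keeps candidates whose seed reaches a minimum
length (default 12 nt, capped at 20), and scores the seed helix with a
nearest-neighbor stacking model (Xia et al. 1998 RNA/RNA Watson-Crick
parameters: per-stack enthalpy/entropy plus a duplex-initiation term)
evaluated at the experiment's temperature (default 20 degC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

logger = logging.getLogger(__name__)

WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
GU_PAIRS = {("G", "U"), ("U", "G")}

# Xia et al. 1998 RNA/RNA Watson-Crick nearest-neighbor parameters.
# Key: the two adjacent top-strand (5'->3') bases of a stacked pair in a
# perfect helix; dH kcal/mol, dS cal/(mol K).  The 16 stacks reduce to 10 by
# the antiparallel symmetry stack(XY) == stack(comp(Y)comp(X)).
_NN_UNIQUE: dict[str, tuple[float, float]] = {
    "AA": (-6.82, -19.0),
    "AU": (-9.38, -26.7),
    "UA": (-7.69, -20.5),
    "CU": (-10.48, -27.1),
    "CA": (-10.44, -26.9),
    "GU": (-11.40, -29.5),
    "GA": (-12.44, -32.5),
    "CG": (-10.64, -26.7),
    "GG": (-13.39, -32.7),
    "GC": (-14.88, -36.9),
}
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _symmetric_key(stack: str) -> str:
    alt = _COMPLEMENT[stack[1]] + _COMPLEMENT[stack[0]]
    return stack if stack in _NN_UNIQUE else alt


NN_STACKS: dict[str, tuple[float, float]] = {
    top: _NN_UNIQUE[_symmetric_key(top)]
    for top in (a + b for a in "ACGU" for b in "ACGU")
}
NN_INITIATION = (3.61, -1.5)  # duplex initiation dH, dS
NN_PARAMETER_SET = "xia1998_rna_wc"


@dataclass(frozen=True)
class ScanConfig:
    min_seed: int = 12
    max_seed: int = 20
    default_seed: int = 8
    temperature_c: float = 20.0
    allow_GU_in_seed: bool = False
    nn_parameter_set: str = NN_PARAMETER_SET
    strong_nfe_threshold: float = -10.0  # repo default; no cutoff is canonical

    def __post_init__(self) -> None:
        if not self.default_seed <= self.min_seed <= self.max_seed:
            raise ValueError("require default_seed <= min_seed <= max_seed")


@dataclass(frozen=True)
class DuplexHit:
    mirna_id: str
    target_id: str
    seed_length: int
    mirna_span: tuple[int, int]  # 0-based half-open on the miRNA
    target_span: tuple[int, int]  # 0-based half-open on the target
    nfe: float  # hybridization free energy of the seed helix, kcal/mol
    temperature_c: float
    strong: bool


def _validate_rna(seq: str, name: str) -> str:
    seq = seq.upper()
    if "T" in seq:
        logger.warning("%s: DNA alphabet detected; converting T->U", name)
        seq = seq.replace("T", "U")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"{name}: invalid RNA characters {sorted(bad)}")
    return seq


def _pairs(a: str, b: str, allow_gu: bool) -> bool:
    return (a, b) in WC_PAIRS or (allow_gu and (a, b) in GU_PAIRS)


def longest_complement_seed(
    mirna: str,
    target: str,
    config: ScanConfig = ScanConfig(),
) -> tuple[int, tuple[int, int], tuple[int, int]]:
    """Longest contiguous antiparallel perfect-complement match.

    Returns (seed_length, mirna_span, target_span); seed_length is capped at
    ``config.max_seed`` (the reported spans cover the cap-length window).
    Ties are broken by smallest target start, then smallest miRNA start.
    """
    mirna = _validate_rna(mirna, "miRNA")
    target = _validate_rna(target, "target")
    if len(mirna) < 8 or len(target) < 8:
        raise ValueError("sequences must be at least 8 nt")
    n, m = len(mirna), len(target)
    allow_gu = config.allow_GU_in_seed
    cap = config.max_seed

    # run[j] after processing miRNA position i: length of the contiguous
    # pairing ending at (mirna i, target j) with previous pair (i-1, j+1)
    best = (0, (0, 0), (0, 0))  # (length, target_span, mirna_span) for ordering
    prev = [0] * (m + 1)
    for i in range(n):
        cur = [0] * (m + 1)
        for j in range(m):
            if _pairs(mirna[i], target[j], allow_gu):
                run = prev[j + 1] + 1
                cur[j] = run
                eff = min(run, cap)
                # cap-length window with the smallest target start ends at j
                cand = (eff, (j, j + eff), (i - eff + 1, i + 1))
                if (
                    eff > best[0]
                    or (eff == best[0] and eff > 0 and (
                        cand[1][0] < best[1][0]
                        or (cand[1][0] == best[1][0] and cand[2][0] < best[2][0])
                    ))
                ):
                    best = cand
        prev = cur
    length, t_span, m_span = best
    return length, m_span, t_span


def duplex_energy(
    mirna_window: str,
    target_window: str,
    temperature_c: float = 20.0,
    nn_parameter_set: str = NN_PARAMETER_SET,
) -> float:
    """Hybridization dG(T) of a perfect antiparallel helix, kcal/mol.

    dG = sum over stacked pairs of (dH - T dS) + duplex initiation, with the
    miRNA window 5'->3' on top and the target window reversed beneath it.
    Requires >= 2 consecutive Watson-Crick pairs; G.U windows are rejected
    (no GU stack parameters are shipped).
    """
    if nn_parameter_set != NN_PARAMETER_SET:
        raise ValueError(f"unknown parameter set {nn_parameter_set!r}")
    top = _validate_rna(mirna_window, "miRNA window")
    bottom = _validate_rna(target_window, "target window")[::-1]
    if len(top) != len(bottom) or len(top) < 2:
        raise ValueError("windows must be equal length >= 2")
    for a, b in zip(top, bottom):
        if (a, b) not in WC_PAIRS:
            raise ValueError(f"unpairable bases {a}-{b} in duplex window")
    t_kelvin = temperature_c + 273.15
    dh, ds = NN_INITIATION
    for i in range(len(top) - 1):
        sdh, sds = NN_STACKS[top[i : i + 2]]
        dh += sdh
        ds += sds
    return dh - t_kelvin * ds / 1000.0


def screen_targets(
    mirna: str,
    candidates: Mapping[str, str],
    config: ScanConfig = ScanConfig(),
    mirna_id: str = "miRNA",
) -> list[DuplexHit]:
    """Scan candidate transcripts; keep seeds >= min_seed ranked by
    (seed_length desc, nfe asc, target_id)."""
    if not candidates:
        logger.warning("empty candidate set for %s", mirna_id)
        return []
    mirna = _validate_rna(mirna, mirna_id)
    hits = []
    for target_id in sorted(candidates):
        seq = _validate_rna(candidates[target_id], target_id)
        seed_len, m_span, t_span = longest_complement_seed(mirna, seq, config)
        if seed_len < config.min_seed:
            continue
        nfe = duplex_energy(
            mirna[m_span[0] : m_span[1]],
            seq[t_span[0] : t_span[1]],
            config.temperature_c,
            config.nn_parameter_set,
        ) if not config.allow_GU_in_seed else _safe_energy(
            mirna, seq, m_span, t_span, config
        )
        hits.append(
            DuplexHit(
                mirna_id=mirna_id,
                target_id=target_id,
                seed_length=seed_len,
                mirna_span=m_span,
                target_span=t_span,
                nfe=nfe,
                temperature_c=config.temperature_c,
                strong=nfe <= config.strong_nfe_threshold,
            )
        )
    hits.sort(key=lambda h: (-h.seed_length, h.nfe, h.target_id))
    return hits


def _safe_energy(mirna, seq, m_span, t_span, config) -> float:
    """Energy for possibly GU-containing seeds: WC-only sub-model or +inf."""
    try:
        return duplex_energy(
            mirna[m_span[0] : m_span[1]], seq[t_span[0] : t_span[1]],
            config.temperature_c, config.nn_parameter_set,
        )
    except ValueError:
        return float("inf")
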