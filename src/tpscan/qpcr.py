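"""Relative-expression arithmetic for calibrator-normalized qPCR (ddCt).

Each measurement is a pair of cycle thresholds: the target (e.g. a mature
miRNA assay) and a calibrator run on the same sample (e.g. U6).  Per
sample, dCt = target_ct - calibrator_ct; ddCt is the difference of group
means of dCt (test minus reference); relative expression = eff**(-ddCt)
with amplification efficiency fixed at 2 (the classic 2^-ddCt model).
Values below 1 mean repression relative to the reference, above 1 induction.

Replicates are averaged on the dCt scale (not on Ct, not on folds).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence


@dataclass(frozen=True)
class QpcrMeasurement:
    sample_id: str
    target_ct: float
    calibrator_ct: float
    group: str  # test | reference

    def __post_init__(self) -> None:
        for name, ct in (("target_ct", self.target_ct),
                         ("calibrator_ct", self.calibrator_ct)):
            if not 0 < ct < 45:
                raise ValueError(f"{self.sample_id}: {name}={ct} outside (0, 45)")

    @property
    def delta_ct(self) -> float:
        return self.target_ct - self.calibrator_ct


def relative_expression(
    test: Sequence[QpcrMeasurement],
    reference: Sequence[QpcrMeasurement],
    efficiency: float = 2.0,
) -> dict:
    """Fold expression of the test group over the reference group.

    Returns {"ddct": ..., "fold": efficiency**(-ddct)}.
    """
    if not test or not reference:
        raise ValueError("need at least one measurement per group")
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    mean_test = sum(m.delta_ct for m in test) / len(test)
    mean_ref = sum(m.delta_ct for m in reference) / len(reference)
    ddct = mean_test - mean_ref
    return {"ddct": ddct, "fold": float(efficiency ** (-ddct))}
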