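"""Screening calls from the expected glottal visibility.

Lower V means a harder airway.  The positive standards are inclusive:
V <= -4 mm flags predicted difficult intubation and V <= -1 mm predicted
difficult laryngoscopy (both thresholds configurable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .config import ModelConfig, DEFAULT_CONFIG
from .errors import RangeError


@dataclass(frozen=True)
class ScreeningResult:
    visibility_mm: float
    difficult_intubation_pred: bool
    difficult_laryngoscopy_pred: bool
    tau_di_mm: float
    tau_dl_mm: float


def classify(visibility_mm: float, config: ModelConfig = DEFAULT_CONFIG) -> ScreeningResult:
    """Apply both positive standards to an (unrounded) visibility value."""
    if not math.isfinite(visibility_mm):
        raise RangeError("visibility_mm", visibility_mm, "V finite")
    return ScreeningResult(
        visibility_mm=float(visibility_mm),
        difficult_intubation_pred=visibility_mm <= config.tau_di_mm,
        difficult_laryngoscopy_pred=visibility_mm <= config.tau_dl_mm,
        tau_di_mm=config.tau_di_mm,
        tau_dl_mm=config.tau_dl_mm,
    )
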