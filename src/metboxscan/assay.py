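"""Reporter-assay arithmetic: Miller units and repression ratios.

The unit definition here is Abs420 / (volume_ul * time_min * OD600), i.e.
without the classical x1000 scaling; pass ``classic=True`` for the textbook
convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import mean, stdev
from typing import Sequence

__all__ = ["AssayMeasurement", "RepressionResult", "miller_units", "repression_ratio"]


@dataclass(frozen=True)
class AssayMeasurement:
    abs420: float
    vol_ul: float
    time_min: float
    od600: float

    def __post_init__(self) -> None:
        for name in ("vol_ul", "time_min", "od600"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")


@dataclass(frozen=True)
class RepressionResult:
    ratio: float
    sd: float


def miller_units(m: AssayMeasurement, classic: bool = False) -> float:
    """Normalized beta-galactosidase activity of one measurement."""
    units = m.abs420 / (m.vol_ul * m.time_min * m.od600)
    return units * 1000.0 if classic else units


def repression_ratio(
    repressed: Sequence[AssayMeasurement],
    derepressed: Sequence[AssayMeasurement],
) -> RepressionResult:
    """Ratio of mean activity with repressor present to without.

    The standard deviation is first-order error propagation for a quotient
    of independent means:

        sd = ratio * sqrt((sd_r / mean_r)^2 + (sd_d / mean_d)^2)

    with the repressed term dropped when its mean is zero.
    """
    if not repressed or not derepressed:
        raise ValueError("need at least one replicate per condition")
    r = [miller_units(m) for m in repressed]
    d = [miller_units(m) for m in derepressed]
    mean_r, mean_d = mean(r), mean(d)
    if mean_d == 0:
        raise ValueError("derepressed mean activity is zero; ratio undefined")
    ratio = mean_r / mean_d
    sd_r = stdev(r) if len(r) > 1 else 0.0
    sd_d = stdev(d) if len(d) > 1 else 0.0
    if mean_r == 0:
        sd = sd_r / mean_d
    else:
        sd = abs(ratio) * math.sqrt((sd_r / mean_r) ** 2 + (sd_d / mean_d) ** 2)
    return RepressionResult(ratio=ratio, sd=sd)
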