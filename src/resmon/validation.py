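"""Analytical QC statistics: LOD/LOQ, recovery, precision, linearity.

LOD and LOQ follow the replicate-SD convention: five (or more) replicate
analyses of a low-level spiked sample give a sample standard deviation SD,
and

    LOD = 3.3 x SD        LOQ = 10 x SD

so LOQ/LOD is identically 10/3.3.  Recovery is the mean measured
concentration as a percentage of the spike level; precision is the relative
standard deviation (RSD, %).  A method passes for a pesticide when recovery
lies inside the configured window (70-120% by default, inclusive) and RSD
is strictly below the limit (10%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .types import AnalysisConfig, round_half_up

__all__ = [
    "SpikeReplicateSet",
    "ValidationResult",
    "lod_loq",
    "recovery_precision",
    "linearity",
    "check_acceptance",
    "LOD_FACTOR",
    "LOQ_FACTOR",
]

LOD_FACTOR = 3.3
LOQ_FACTOR = 10.0


@dataclass(frozen=True)
class SpikeReplicateSet:
    """Replicate determinations of a sample spiked at a known level (mg/kg)."""

    pesticide: str
    spike_level: float
    measured: Tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "measured", tuple(float(x) for x in self.measured))
        if self.spike_level <= 0:
            raise ValueError(f"{self.pesticide!r}: spike_level must be > 0")
        if len(self.measured) < 2:
            raise ValueError(f"{self.pesticide!r}: need at least 2 replicates")
        if any(x < 0 for x in self.measured):
            raise ValueError(f"{self.pesticide!r}: measured values must be >= 0")


@dataclass(frozen=True)
class ValidationResult:
    """Validation summary for one pesticide (a line of the QC table)."""

    pesticide: str
    lod: float
    loq: float
    recovery_pct: float
    rsd_pct: float
    r_squared: Optional[float] = None
    passed: Optional[bool] = None


def lod_loq(reps: SpikeReplicateSet, decimals: Optional[int] = None) -> Tuple[float, float]:
    """Limits of detection and quantification from replicate SD.

    SD uses the n-1 (sample) denominator, appropriate for the small
    replicate counts used in practice (n = 5).  ``decimals`` optionally
    rounds for presentation; full precision is the default.
    """
    sd = float(np.std(reps.measured, ddof=1))
    lod, loq = LOD_FACTOR * sd, LOQ_FACTOR * sd
    if decimals is not None:
        lod, loq = round_half_up(lod, decimals), round_half_up(loq, decimals)
    return lod, loq


def recovery_precision(reps: SpikeReplicateSet) -> Tuple[float, float]:
    """(recovery %, RSD %) of a spiked replicate set.

    recovery = 100 x mean(measured) / spike_level
    RSD      = 100 x SD(measured) / mean(measured)
    """
    mean = float(np.mean(reps.measured))
    if mean == 0:
        raise ValueError(f"{reps.pesticide!r}: zero mean response, RSD undefined")
    sd = float(np.std(reps.measured, ddof=1))
    return 100.0 * mean / reps.spike_level, 100.0 * sd / mean


def linearity(levels: Sequence[Tuple[float, Sequence[float]]]) -> float:
    """R-squared of the calibration line over all replicate points.

    ``levels`` is a list of (concentration, replicate responses); an
    ordinary least-squares line is fit to the pooled (concentration,
    response) points.  A perfectly constant response has no explained
    variance (R^2 = 0).
    """
    distinct = {c for c, _ in levels}
    if len(distinct) < 3:
        raise ValueError(f"need >= 3 distinct concentration levels, got {len(distinct)}")
    xs: List[float] = []
    ys: List[float] = []
    for conc, responses in levels:
        for r in responses:
            xs.append(float(conc))
            ys.append(float(r))
    if np.std(xs) == 0:
        raise ValueError("zero variance in concentration")
    if np.std(ys) == 0:
        return 0.0
    fit = stats.linregress(xs, ys)
    return float(fit.rvalue**2)


def check_acceptance(result: ValidationResult, config: Optional[AnalysisConfig] = None) -> bool:
    """Accept a pesticide's method: recovery in range (inclusive), RSD < limit."""
    config = config or AnalysisConfig()
    low, high = config.recovery_range
    return bool(low <= result.recovery_pct <= high and result.rsd_pct < config.rsd_limit)
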