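"""Domain types shared by every stage of the residue-monitoring pipeline.

The vocabulary follows regulatory dietary risk assessment:

* an **MRL** (maximum residue limit) is the highest legally permitted
  concentration of a pesticide in a commodity, in mg/kg; under Korea's
  Positive List System any unregistered pesticide x commodity pair falls
  back to a uniform default (0.01 mg/kg);
* **ADI** (acceptable daily intake, mg/kg bw/day) and **ARfD** (acute
  reference dose, mg/kg bw) are the chronic and acute toxicological
  reference doses.  Some pesticides have no authorized ARfD; that absence
  is modelled as ``None`` and must never be coerced to zero.

All concentrations are mg/kg, intakes kg/person/day, body weight kg.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import yaml

__all__ = [
    "Group",
    "FunctionClass",
    "Verdict",
    "SampleRecord",
    "ResidueMeasurement",
    "MRLEntry",
    "MRLSource",
    "ToxRef",
    "ConsumptionEntry",
    "AnalysisConfig",
    "round_half_up",
]


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round with ties away from zero (0.05 -> 0.1), not banker's rounding.

    Survey percentages are conventionally presented this way; Python's
    built-in ``round`` uses round-half-even and would turn 46.875 into 46.88
    only by accident of binary representation.
    """
    q = decimal.Decimal(10) ** -decimals
    return float(decimal.Decimal(repr(value)).quantize(q, rounding=decimal.ROUND_HALF_UP))


class Group(str, Enum):
    """Commodity group of the monitoring campaign."""

    VEGETABLE = "vegetable"
    FRUIT = "fruit"


class FunctionClass(str, Enum):
    """Pesticide function class: fungicide, growth regulator, herbicide, insecticide."""

    FUNGICIDE = "F"
    GROWTH_REGULATOR = "G"
    HERBICIDE = "H"
    INSECTICIDE = "I"


class Verdict(str, Enum):
    """Residue (and sample) classification against the applicable MRL.

    Ordered by severity; ``classify_sample`` takes the worst verdict over a
    sample's residues.
    """

    NOT_DETECTED = "not_detected"
    BELOW_MRL = "below_mrl"
    ABOVE_MRL = "above_mrl"

    @property
    def severity(self) -> int:
        return (Verdict.NOT_DETECTED, Verdict.BELOW_MRL, Verdict.ABOVE_MRL).index(self)


class MRLSource(str, Enum):
    REGISTERED = "registered"
    PLS_DEFAULT = "pls_default"


@dataclass(frozen=True)
class SampleRecord:
    """One collected sample: an opaque id, its commodity and commodity group."""

    sample_id: str
    commodity: str
    group: Group

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if not self.commodity:
            raise ValueError(f"sample {self.sample_id!r}: commodity must be non-empty")


@dataclass(frozen=True)
class ResidueMeasurement:
    """One quantified pesticide residue in one sample (mg/kg).

    ``lod``/``loq`` are the detection and quantification limits applicable to
    this determination; a concentration below ``lod`` counts as not detected.
    """

    sample_id: str
    pesticide: str
    concentration: float
    lod: float = 0.0
    loq: Optional[float] = None  # defaults to lod when not given

    def __post_init__(self) -> None:
        if self.loq is None:
            object.__setattr__(self, "loq", self.lod)
        if self.concentration < 0:
            raise ValueError(
                f"sample {self.sample_id!r}, pesticide {self.pesticide!r}: "
                f"negative concentration {self.concentration}"
            )
        if self.lod < 0 or self.loq < self.lod:
            raise ValueError(
                f"sample {self.sample_id!r}: require loq >= lod >= 0, "
                f"got lod={self.lod}, loq={self.loq}"
            )


@dataclass(frozen=True)
class MRLEntry:
    """Resolved legal limit for one pesticide x commodity pair.

    ``source`` records whether the limit is a registered MRL or the Positive
    List System uniform default applied to unregistered pairs.
    """

    pesticide: str
    commodity: str
    mrl: float
    source: MRLSource = MRLSource.REGISTERED

    def __post_init__(self) -> None:
        if self.mrl <= 0:
            raise ValueError(
                f"MRL for ({self.pesticide!r}, {self.commodity!r}) must be > 0, got {self.mrl}"
            )


@dataclass(frozen=True)
class ToxRef:
    """Per-pesticide reference doses: chronic ADI, optional acute ARfD.

    ``arfd is None`` means no authorized acute reference dose exists; acute
    hazard quotients are then undefined (reported as absent, never 0).
    """

    pesticide: str
    adi: float
    arfd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.adi <= 0:
            raise ValueError(f"{self.pesticide!r}: ADI must be > 0, got {self.adi}")
        if self.arfd is not None and self.arfd <= 0:
            raise ValueError(f"{self.pesticide!r}: ARfD, when present, must be > 0")


@dataclass(frozen=True)
class ConsumptionEntry:
    """Average daily intake of one commodity, kg/person/day."""

    commodity: str
    daily_intake: float

    def __post_init__(self) -> None:
        if self.daily_intake < 0:
            raise ValueError(f"{self.commodity!r}: daily_intake must be >= 0")


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters.

    body_weight
        Consumer body weight in kg used in every intake formula.  The
        conventional Korean adult default of 60 kg is used when the user
        supplies nothing.
    pls_default_mrl
        Uniform fallback MRL (mg/kg) applied to pesticide x commodity pairs
        with no registered limit.
    percent_decimals
        Decimals used when presenting percentages (round-half-up).
    rsd_limit, recovery_range
        Method-validation acceptance: RSD strictly below the limit, recovery
        inside the closed range.
    """

    body_weight: float = 60.0
    pls_default_mrl: float = 0.01
    percent_decimals: int = 1
    rsd_limit: float = 10.0
    recovery_range: Sequence[float] = (70.0, 120.0)

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise ValueError("body_weight must be > 0")
        if self.pls_default_mrl <= 0:
            raise ValueError("pls_default_mrl must be > 0")
        low, high = self.recovery_range
        if not low < high:
            raise ValueError("recovery_range must satisfy low < high")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        """Load a config from a YAML file mirroring the field names."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "recovery_range" in raw:
            raw["recovery_range"] = tuple(raw["recovery_range"])
        return cls(**raw)

    def percent(self, numerator: float, denominator: float) -> float:
        """A presentation-rounded percentage (round-half-up)."""
        if denominator == 0:
            return 0.0
        return round_half_up(100.0 * numerator / denominator, self.percent_decimals)
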