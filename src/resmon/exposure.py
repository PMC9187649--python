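"""Deterministic acute and chronic dietary exposure and hazard indices.

For a pesticide found in a commodity with per-capita daily consumption C
(kg/day) and consumer body weight bw (kg):

    ESTI = max residue x C / bw          (estimated short-term intake)
    EDI  = mean residue x C / bw         (estimated daily intake)
    aHQ  = 100 x ESTI / ARfD             (acute hazard quotient, %)
    HQ   = 100 x EDI / ADI               (chronic hazard quotient, %)
    cHI  = sum of HQ over all pairs      (cumulative hazard index, %)

"Mean residue" is the arithmetic mean over *detected* concentrations only;
non-detects are excluded rather than substituted.  An index above 100%
flags a potential risk; 100% exactly is still acceptable.  A pesticide
without an authorized ARfD has no acute index: absence propagates as
``None`` and is excluded from acute range statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

from .compliance import ResidueVerdict
from .types import AnalysisConfig, ConsumptionEntry, ResidueMeasurement, ToxRef, Verdict

__all__ = [
    "ExposureRecord",
    "RiskSummary",
    "esti",
    "edi",
    "acute_hq",
    "chronic_hq",
    "cumulative_hi",
    "interpret",
    "risk_table",
    "ACCEPTABLE",
    "POTENTIAL_RISK",
]

ACCEPTABLE = "acceptable"
POTENTIAL_RISK = "potential_risk"


@dataclass(frozen=True)
class ExposureRecord:
    """Acute and chronic exposure bundle for one pesticide x commodity pair.

    ``esti``/``ahq`` are ``None`` exactly when the pesticide has no
    authorized ARfD (the acute index cannot be computed); ``arfd`` is then
    ``None`` as well.
    """

    pesticide: str
    commodity: str
    esti: Optional[float]
    ahq: Optional[float]
    edi: float
    hq: float
    arfd: Optional[float]
    adi: float


@dataclass(frozen=True)
class RiskSummary:
    """Aggregate over an exposure table: cumulative index, maxima, verdict."""

    chi: float
    ahq_max: Optional[float]
    hq_max: float
    verdict: str


def esti(highest_residue: float, consumption: float, body_weight: float) -> float:
    """Estimated short-term intake: highest residue x consumption / bw."""
    if body_weight <= 0:
        raise ValueError(f"body_weight must be > 0, got {body_weight}")
    if highest_residue < 0 or consumption < 0:
        raise ValueError("residue and consumption must be >= 0")
    return highest_residue * consumption / body_weight


def edi(mean_residue: float, consumption: float, body_weight: float) -> float:
    """Estimated daily intake: mean residue x consumption / bw."""
    return esti(mean_residue, consumption, body_weight)


def acute_hq(esti_value: float, arfd: Optional[float]) -> Optional[float]:
    """Acute hazard quotient, 100 x ESTI/ARfD in percent.

    An absent ARfD yields ``None`` (undefined index, never 0 and never an
    error); an ARfD of 0 is invalid.
    """
    if esti_value < 0:
        raise ValueError("ESTI must be >= 0")
    if arfd is None:
        return None
    if arfd <= 0:
        raise ValueError(f"ARfD must be > 0, got {arfd}")
    return 100.0 * esti_value / arfd


def chronic_hq(edi_value: float, adi: float) -> float:
    """Chronic hazard quotient, 100 x EDI/ADI in percent."""
    if edi_value < 0:
        raise ValueError("EDI must be >= 0")
    if adi <= 0:
        raise ValueError(f"ADI must be > 0, got {adi}")
    return 100.0 * edi_value / adi


def cumulative_hi(hqs: Iterable[float]) -> float:
    """Cumulative hazard index: the arithmetic sum of chronic HQs (%)."""
    total = 0.0
    for hq in hqs:
        if hq < 0:
            raise ValueError("hazard quotients must be >= 0")
        total += hq
    return total


def interpret(index: float) -> str:
    """Read a hazard index: strictly above 100% flags a potential risk."""
    if index < 0:
        raise ValueError("index must be >= 0")
    return POTENTIAL_RISK if index > 100.0 else ACCEPTABLE


ConsumptionLike = Union[Mapping[str, float], Iterable[ConsumptionEntry]]
ToxLike = Union[Mapping[str, ToxRef], Iterable[ToxRef]]


def _consumption_index(consumption: ConsumptionLike) -> Dict[str, float]:
    if isinstance(consumption, Mapping):
        return dict(consumption)
    return {c.commodity: c.daily_intake for c in consumption}


def _tox_index(tox: ToxLike) -> Dict[str, ToxRef]:
    if isinstance(tox, Mapping):
        return dict(tox)
    return {t.pesticide: t for t in tox}


def risk_table(
    measurements: Sequence[ResidueMeasurement],
    verdicts: Sequence[ResidueVerdict],
    consumption: ConsumptionLike,
    tox: ToxLike,
    config: Optional[AnalysisConfig] = None,
) -> Tuple[List[ExposureRecord], RiskSummary]:
    """Exposure table over every pesticide x commodity pair with a detection.

    The highest detected concentration of the pair feeds ESTI, the mean of
    detected concentrations feeds EDI; the commodity comes from the MRL used
    in each verdict.  Missing ADIs or consumption entries for any involved
    pesticide/commodity raise an error listing all offenders at once.
    """
    config = config or AnalysisConfig()
    if len(measurements) != len(verdicts):
        raise ValueError("verdicts must align one-to-one with measurements")
    cons = _consumption_index(consumption)
    toxi = _tox_index(tox)

    detected: Dict[Tuple[str, str], List[float]] = {}
    for m, v in zip(measurements, verdicts):
        if v.value is Verdict.NOT_DETECTED:
            continue
        detected.setdefault((m.pesticide, v.mrl_used.commodity), []).append(m.concentration)

    missing_adi = sorted({p for p, _ in detected if p not in toxi})
    if missing_adi:
        raise ValueError(f"no toxicological reference (ADI) for: {missing_adi}")
    missing_cons = sorted({c for _, c in detected if c not in cons})
    if missing_cons:
        raise ValueError(f"no consumption entry for: {missing_cons}")

    records: List[ExposureRecord] = []
    for pesticide, commodity in sorted(detected):
        concs = detected[(pesticide, commodity)]
        ref = toxi[pesticide]
        intake = cons[commodity]
        esti_val = esti(max(concs), intake, config.body_weight)
        edi_val = edi(sum(concs) / len(concs), intake, config.body_weight)
        ahq_val = acute_hq(esti_val, ref.arfd)
        records.append(
            ExposureRecord(
                pesticide=pesticide,
                commodity=commodity,
                esti=esti_val if ref.arfd is not None else None,
                ahq=ahq_val,
                edi=edi_val,
                hq=chronic_hq(edi_val, ref.adi),
                arfd=ref.arfd,
                adi=ref.adi,
            )
        )
    return records, summarize(records)


def summarize(records: Sequence[ExposureRecord]) -> RiskSummary:
    """Aggregate an exposure table into its cumulative index and maxima."""
    chi = cumulative_hi(r.hq for r in records)
    ahqs = [r.ahq for r in records if r.ahq is not None]
    return RiskSummary(
        chi=chi,
        ahq_max=max(ahqs) if ahqs else None,
        hq_max=max((r.hq for r in records), default=0.0),
        verdict=interpret(chi),
    )
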