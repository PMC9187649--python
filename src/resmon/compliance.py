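"""MRL compliance screening and monitoring summary statistics.

Classification convention
-------------------------
A measured concentration below the determination's LOD counts as *not
detected*; a detected residue at or below the applicable MRL is compliant
(*below_mrl*); only a strictly greater concentration *exceeds* the MRL
(regulatory convention: equality is compliant).  A sample's category is the
worst verdict over its residues, so each sample is counted exactly once in
occurrence tables.

Percentage convention of the occurrence table
---------------------------------------------
Following the survey presentation, the percentage printed beside the
below-MRL count is the ANY-residue rate, ``(n_below + n_above) / n_total``.
Machine output additionally carries an unambiguous ``pct_below`` column.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

from .types import (
    AnalysisConfig,
    FunctionClass,
    Group,
    MRLEntry,
    MRLSource,
    ResidueMeasurement,
    SampleRecord,
    Verdict,
)

__all__ = [
    "ResidueVerdict",
    "OccurrenceRow",
    "IncidenceRow",
    "build_mrl_index",
    "resolve_mrl",
    "classify_residue",
    "classify_sample",
    "classify_dataset",
    "occurrence_by_commodity",
    "incidence_by_pesticide",
    "function_class_breakdown",
    "TOTAL_LABEL",
]

TOTAL_LABEL = "Total"


@dataclass(frozen=True)
class ResidueVerdict:
    """Verdict for one residue measurement together with the MRL it used."""

    value: Verdict
    mrl_used: MRLEntry


@dataclass(frozen=True)
class OccurrenceRow:
    """Per-commodity sample accounting (one line of the occurrence table)."""

    product: str
    group: Optional[Group]
    n_total: int
    n_without: int
    pct_without: float
    n_below: int
    pct_with: float  # ANY-residue rate, printed beside the below-MRL count
    n_above: int
    pct_above: float
    pct_below: float  # unambiguous below-MRL-only rate


@dataclass(frozen=True)
class IncidenceRow:
    """Per-pesticide detection summary (one line of the incidence table)."""

    pesticide: str
    function_class: Optional[FunctionClass]
    n_detected: int
    pct_detected: float  # of all samples analysed
    n_above: int
    pct_above: float
    conc_min: float
    conc_max: float
    mrl_min: float
    mrl_max: float


MRLTable = Union[Mapping[Tuple[str, str], MRLEntry], Iterable[MRLEntry]]


def build_mrl_index(mrl_table: MRLTable) -> Dict[Tuple[str, str], MRLEntry]:
    """Index registered MRL entries by (pesticide, commodity)."""
    if isinstance(mrl_table, Mapping):
        return dict(mrl_table)
    index: Dict[Tuple[str, str], MRLEntry] = {}
    for entry in mrl_table:
        key = (entry.pesticide, entry.commodity)
        if key in index and index[key] != entry:
            raise ValueError(f"conflicting MRL entries for {key}")
        index[key] = entry
    return index


def resolve_mrl(
    pesticide: str,
    commodity: str,
    mrl_table: MRLTable,
    config: Optional[AnalysisConfig] = None,
) -> MRLEntry:
    """Resolve the legal limit for a pesticide x commodity pair.

    Registered entries win; any unregistered pair falls back to the Positive
    List System uniform default (``config.pls_default_mrl``, 0.01 mg/kg).
    The fallback is total: this function never fails.
    """
    if not pesticide or not commodity:
        raise ValueError("pesticide and commodity must be non-empty")
    config = config or AnalysisConfig()
    index = build_mrl_index(mrl_table)
    entry = index.get((pesticide, commodity))
    if entry is not None:
        return entry
    return MRLEntry(pesticide, commodity, config.pls_default_mrl, MRLSource.PLS_DEFAULT)


def classify_residue(m: ResidueMeasurement, mrl: MRLEntry) -> ResidueVerdict:
    """Classify one residue against its MRL.

    concentration < LOD        -> not_detected
    LOD <= concentration <= MRL -> below_mrl
    concentration > MRL        -> above_mrl  (strict: equality is compliant)
    """
    if m.concentration < m.lod:
        value = Verdict.NOT_DETECTED
    elif m.concentration > mrl.mrl:
        value = Verdict.ABOVE_MRL
    else:
        value = Verdict.BELOW_MRL
    return ResidueVerdict(value, mrl)


def classify_sample(verdicts: Sequence[Union[ResidueVerdict, Verdict]]) -> Verdict:
    """Collapse a sample's residue verdicts to one category: worst wins.

    An empty list is a clean sample (``not_detected``).
    """
    worst = Verdict.NOT_DETECTED
    for v in verdicts:
        value = v.value if isinstance(v, ResidueVerdict) else v
        if value.severity > worst.severity:
            worst = value
    return worst


def classify_dataset(
    samples: Sequence[SampleRecord],
    measurements: Sequence[ResidueMeasurement],
    mrl_table: MRLTable,
    config: Optional[AnalysisConfig] = None,
) -> Tuple[List[ResidueVerdict], Dict[str, Verdict]]:
    """Classify every measurement and every sample of a dataset.

    Returns the per-measurement verdicts (aligned with ``measurements``) and
    the per-sample worst-case category keyed by sample id.
    """
    config = config or AnalysisConfig()
    index = build_mrl_index(mrl_table)
    commodity_of = {s.sample_id: s.commodity for s in samples}
    unknown = sorted({m.sample_id for m in measurements} - set(commodity_of))
    if unknown:
        raise ValueError(f"measurements reference unknown sample ids: {unknown}")

    residue_verdicts: List[ResidueVerdict] = []
    per_sample: Dict[str, List[ResidueVerdict]] = {s.sample_id: [] for s in samples}
    for m in measurements:
        mrl = resolve_mrl(m.pesticide, commodity_of[m.sample_id], index, config)
        rv = classify_residue(m, mrl)
        residue_verdicts.append(rv)
        per_sample[m.sample_id].append(rv)
    sample_verdicts = {sid: classify_sample(vs) for sid, vs in per_sample.items()}
    return residue_verdicts, sample_verdicts


def occurrence_by_commodity(
    samples: Sequence[SampleRecord],
    sample_verdicts: Mapping[str, Verdict],
    config: Optional[AnalysisConfig] = None,
) -> List[OccurrenceRow]:
    """Per-commodity occurrence table plus a grand-total row.

    Every sample must be classified.  Rows are ordered vegetables before
    fruits, alphabetically within each group; the total row (labelled
    ``Total``) comes last.
    """
    config = config or AnalysisConfig()
    missing = sorted({s.sample_id for s in samples} - set(sample_verdicts))
    if missing:
        raise ValueError(f"unclassified samples: {missing}")

    counts: Dict[Tuple[Group, str], List[int]] = defaultdict(lambda: [0, 0, 0])
    for s in samples:
        counts[(s.group, s.commodity)][sample_verdicts[s.sample_id].severity] += 1

    def make_row(product: str, group: Optional[Group], tally: Sequence[int]) -> OccurrenceRow:
        n_without, n_below, n_above = tally
        n_total = sum(tally)
        return OccurrenceRow(
            product=product,
            group=group,
            n_total=n_total,
            n_without=n_without,
            pct_without=config.percent(n_without, n_total),
            n_below=n_below,
            pct_with=config.percent(n_below + n_above, n_total),
            n_above=n_above,
            pct_above=config.percent(n_above, n_total),
            pct_below=config.percent(n_below, n_total),
        )

    order = {Group.VEGETABLE: 0, Group.FRUIT: 1}
    rows = [
        make_row(product, group, counts[(group, product)])
        for group, product in sorted(counts, key=lambda k: (order[k[0]], k[1]))
    ]
    grand = [0, 0, 0]
    for tally in counts.values():
        for i in range(3):
            grand[i] += tally[i]
    rows.append(make_row(TOTAL_LABEL, None, grand))
    return rows


def incidence_by_pesticide(
    samples: Sequence[SampleRecord],
    measurements: Sequence[ResidueMeasurement],
    verdicts: Sequence[ResidueVerdict],
    config: Optional[AnalysisConfig] = None,
    function_classes: Optional[Mapping[str, FunctionClass]] = None,
) -> List[IncidenceRow]:
    """Per-pesticide incidence table over all detected residues.

    For each pesticide with at least one detection: the detection count and
    its percentage of *all* samples analysed, the violation count, the
    detected concentration range, and the range of MRLs applied across the
    commodities in which it was found.  Rows are alphabetical by pesticide.
    """
    config = config or AnalysisConfig()
    if len(measurements) != len(verdicts):
        raise ValueError("verdicts must align one-to-one with measurements")
    n_samples = len(samples)
    per_pesticide: Dict[str, List[Tuple[ResidueMeasurement, ResidueVerdict]]] = defaultdict(list)
    for m, v in zip(measurements, verdicts):
        if v.value is not Verdict.NOT_DETECTED:
            per_pesticide[m.pesticide].append((m, v))

    rows: List[IncidenceRow] = []
    for pesticide in sorted(per_pesticide):
        hits = per_pesticide[pesticide]
        concs = [m.concentration for m, _ in hits]
        mrls = [v.mrl_used.mrl for _, v in hits]
        n_detected = len(hits)
        n_above = sum(v.value is Verdict.ABOVE_MRL for _, v in hits)
        rows.append(
            IncidenceRow(
                pesticide=pesticide,
                function_class=(function_classes or {}).get(pesticide),
                n_detected=n_detected,
                pct_detected=config.percent(n_detected, n_samples),
                n_above=n_above,
                pct_above=config.percent(n_above, n_samples),
                conc_min=min(concs),
                conc_max=max(concs),
                mrl_min=min(mrls),
                mrl_max=max(mrls),
            )
        )
    return rows


def function_class_breakdown(
    rows: Sequence[IncidenceRow],
    config: Optional[AnalysisConfig] = None,
) -> Dict[FunctionClass, Tuple[int, float]]:
    """Count detected pesticides by function class.

    Returns ``{class: (count, percent of all detected pesticides)}``;
    percentages round-half-up at the configured precision.  A row without a
    valid function class is a validation error.
    """
    config = config or AnalysisConfig()
    counts: Dict[FunctionClass, int] = defaultdict(int)
    for row in rows:
        if row.function_class is None:
            raise ValueError(f"pesticide {row.pesticide!r} has no function class")
        counts[FunctionClass(row.function_class)] += 1
    total = sum(counts.values())
    return {
        cls: (n, config.percent(n, total))
        for cls, n in sorted(counts.items(), key=lambda kv: kv[0].value)
    }
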