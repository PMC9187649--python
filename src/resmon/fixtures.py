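"""Deterministic reconstruction of the 2020 Incheon survey dataset.

The survey publishes only marginal summaries: a per-commodity occurrence
table (samples without residue / with residue at or below the MRL / above
the MRL), a per-pesticide incidence table (detections, violations,
concentration range, MRL range) and a per-pair exposure table (which
pesticide was found in which commodity).  This module rebuilds a concrete
sample-level dataset — 1146 samples, 91 single-residue contaminated
samples — whose classification reproduces every printed marginal exactly.

The split of each pesticide's detections over commodities is not printed;
it is solved here as an integral transportation problem (min-cost flow,
zero costs) in two stages: violations first, then remaining detections with
a mandatory unit on every pesticide x commodity pair appearing in the
exposure table.  The solve is a deterministic function of the tables (no
seed): nodes and edges are inserted in sorted order.

Known reconstruction limits, inherent to the printed marginals:

* one residue per contaminated sample is forced by the count identity
  (91 detections = 91 contaminated samples);
* a pesticide found in a single commodity can realise only one MRL, so
  diazinon's printed MRL range 0.05-0.1 collapses to 0.05 (its only pair
  is winter-grown cabbage);
* LOD/LOQ are set to a uniform 0.005/0.015 mg/kg: published per-pesticide
  LODs cover less than half the detected pesticides and one (fluopyram,
  LOD 0.022) exceeds that pesticide's own minimum detected concentration.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .types import (
    FunctionClass,
    Group,
    MRLEntry,
    MRLSource,
    ResidueMeasurement,
    SampleRecord,
    ToxRef,
)

__all__ = [
    "load_validation_reference",
    "load_occurrence_reference",
    "load_incidence_reference",
    "load_exposure_reference",
    "FixtureSpec",
    "survey_spec",
    "build_survey_dataset",
    "survey_function_classes",
    "survey_tox_table",
    "FIXTURE_LOD",
    "FIXTURE_LOQ",
]

FIXTURE_LOD = 0.005
FIXTURE_LOQ = 0.015


def _load(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("resmon.data").joinpath(name)
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, comment="#")


def load_validation_reference() -> pd.DataFrame:
    """QC summary for the 15 validated pesticides (R^2, LOD, LOQ, recovery, RSD)."""
    return _load("validation_reference.csv")


def load_occurrence_reference() -> pd.DataFrame:
    """Per-commodity occurrence marginals (20 commodities, 1146 samples)."""
    return _load("occurrence_reference.csv")


def load_incidence_reference() -> pd.DataFrame:
    """Per-pesticide incidence marginals (32 pesticides, 91 detections)."""
    return _load("incidence_reference.csv")


def load_exposure_reference() -> pd.DataFrame:
    """Printed exposure cells (ESTI/aHQ/EDI/HQ) for all 62 pesticide x commodity
    pairs; absent ARfD/ESTI/aHQ appear as NaN."""
    return _load("exposure_reference.csv")


@dataclass
class FixtureSpec:
    """The marginal tables a sample-level dataset must reproduce."""

    occurrence: pd.DataFrame  # product, group, n_total, n_without, n_below, n_above
    incidence: pd.DataFrame  # pesticide, n_detected, n_above, conc/mrl ranges
    allowed_pairs: List[Tuple[str, str]]  # (pesticide, commodity) with >= 1 detection
    exposure: pd.DataFrame  # printed exposure cells per pair

    def validate(self) -> None:
        occ, inc = self.occurrence, self.incidence
        bad = occ[occ.n_without + occ.n_below + occ.n_above != occ.n_total]
        if len(bad):
            raise ValueError(f"occurrence counts do not sum to n_total for: "
                             f"{bad['product'].tolist()}")
        if int(occ.n_below.sum() + occ.n_above.sum()) != int(inc.n_detected.sum()):
            raise ValueError(
                "contaminated-sample total and detection total disagree "
                f"({int(occ.n_below.sum() + occ.n_above.sum())} vs {int(inc.n_detected.sum())}); "
                "a one-residue-per-sample reconstruction is impossible"
            )
        bad = inc[inc.n_above > inc.n_detected]
        if len(bad):
            raise ValueError(f"violations exceed detections for: {bad.pesticide.tolist()}")
        known_pairs = set(self.allowed_pairs)
        per_p = {p: [c for q, c in self.allowed_pairs if q == p] for p in inc.pesticide}
        for row in inc.itertuples(index=False):
            if not per_p.get(row.pesticide):
                raise ValueError(f"{row.pesticide!r}: detections but no allowed pair")
        for p, c in known_pairs:
            if c not in set(occ["product"]):
                raise ValueError(f"pair ({p!r}, {c!r}): unknown commodity")


def survey_spec() -> FixtureSpec:
    """The packaged survey marginals as a :class:`FixtureSpec`."""
    exposure = load_exposure_reference()
    return FixtureSpec(
        occurrence=load_occurrence_reference(),
        incidence=load_incidence_reference(),
        allowed_pairs=[(r.pesticide, r.commodity) for r in exposure.itertuples(index=False)],
        exposure=exposure,
    )


def survey_function_classes() -> Dict[str, FunctionClass]:
    """Pesticide -> function class map from the incidence reference."""
    inc = load_incidence_reference()
    return {r.pesticide: FunctionClass(r.function_class) for r in inc.itertuples(index=False)}


def survey_tox_table() -> List[ToxRef]:
    """Per-pesticide ADI/ARfD reference doses from the exposure reference.

    ARfD and ADI are constant across a pesticide's commodities; that
    consistency is asserted here.
    """
    exposure = load_exposure_reference()
    refs: Dict[str, ToxRef] = {}
    for r in exposure.itertuples(index=False):
        arfd = None if pd.isna(r.arfd) else float(r.arfd)
        ref = ToxRef(r.pesticide, float(r.adi), arfd)
        if r.pesticide in refs and refs[r.pesticide] != ref:
            raise ValueError(f"inconsistent reference doses for {r.pesticide!r}")
        refs[r.pesticide] = ref
    return [refs[p] for p in sorted(refs)]


def _solve_transport(
    supplies: Dict[str, int],
    demands: Dict[str, int],
    edges: List[Tuple[str, str]],
    label: str,
) -> Dict[Tuple[str, str], int]:
    """Integral transportation solve (zero cost); raises on infeasibility."""
    total_supply, total_demand = sum(supplies.values()), sum(demands.values())
    if total_supply != total_demand:
        raise ValueError(f"{label}: supply {total_supply} != demand {total_demand}")
    if total_supply == 0:
        return {}
    g = nx.DiGraph()
    for p in sorted(supplies):
        g.add_node(("p", p), demand=-supplies[p])
    for c in sorted(demands):
        g.add_node(("c", c), demand=demands[c])
    for p, c in sorted(edges):
        g.add_edge(("p", p), ("c", c), weight=0, capacity=total_supply)
    try:
        flow = nx.min_cost_flow(g)
    except nx.NetworkXUnfeasible as exc:
        raise ValueError(f"{label}: infeasible assignment over the allowed pairs") from exc
    out: Dict[Tuple[str, str], int] = {}
    for p, c in edges:
        units = flow.get(("p", p), {}).get(("c", c), 0)
        if units:
            out[(p, c)] = int(units)
    return out


def _assign_mrls(
    inc: pd.DataFrame,
    pairs_of: Dict[str, List[str]],
    viol_flow: Dict[Tuple[str, str], int],
) -> Dict[Tuple[str, str], float]:
    """One MRL per pair, realising each pesticide's printed MRL range.

    Violation-hosting pairs take the low endpoint (first such pair; further
    violation pairs take the high endpoint so their larger concentrations
    still exceed it); remaining pairs take the high endpoint, except that a
    pesticide with no violations puts the low endpoint on its first pair.
    """
    mrls: Dict[Tuple[str, str], float] = {}
    for row in inc.itertuples(index=False):
        p = row.pesticide
        commodities = sorted(pairs_of[p])
        viol_cs = [c for c in commodities if viol_flow.get((p, c), 0) > 0]
        lo, hi = float(row.mrl_min), float(row.mrl_max)
        low_host = viol_cs[0] if viol_cs else commodities[0]
        for c in commodities:
            mrls[(p, c)] = lo if c == low_host else hi
    return mrls


def _place_concentrations(
    row,
    slots: List[Tuple[str, str, float]],  # (commodity, kind, mrl)
) -> List[Tuple[str, float, str]]:
    """Concrete concentrations for one pesticide's detection slots.

    Realises the printed range endpoints exactly: the maximum goes to the
    first slot that admits it, the minimum to the last, and interior slots
    take the geometric midpoint of the range clipped to the slot's
    (verdict-determined) feasible interval.
    """
    p = row.pesticide
    cmin, cmax = float(row.conc_min), float(row.conc_max)

    def admits(kind: str, mrl: float, value: float) -> bool:
        return value > mrl if kind == "above" else value <= mrl

    # above slots first, larger MRLs first, so the largest concentrations
    # land on the hardest constraints
    ordered = sorted(
        enumerate(slots),
        key=lambda kv: (0 if kv[1][1] == "above" else 1, -kv[1][2], kv[1][0]),
    )
    values: Dict[int, float] = {}
    i_max = next((i for i, (_, kind, mrl) in ordered if admits(kind, mrl, cmax)), None)
    if i_max is None:
        raise ValueError(f"{p!r}: no slot admits the maximum concentration {cmax}")
    values[i_max] = cmax
    if len(slots) > 1 or cmin != cmax:
        candidates = [i for i, (_, kind, mrl) in reversed(ordered)
                      if i != i_max and admits(kind, mrl, cmin)]
        if len(slots) > 1:
            if not candidates:
                raise ValueError(f"{p!r}: no slot admits the minimum concentration {cmin}")
            values[candidates[0]] = cmin
        elif cmin != cmax:
            raise ValueError(f"{p!r}: one detection cannot realise range {cmin}-{cmax}")
    mid = float(np.sqrt(cmin * cmax)) if cmin > 0 else cmax / 2
    for i, (_, kind, mrl) in ordered:
        if i in values:
            continue
        if kind == "above":
            v = min(cmax, max(cmin, mid))
            if v <= mrl:
                v = min(cmax, np.nextafter(mrl, np.inf) + (cmax - mrl) / 2)
            if not (mrl < v <= cmax):
                raise ValueError(f"{p!r}: cannot place a violating residue above MRL {mrl}")
        else:
            v = min(min(mrl, cmax), max(cmin, mid))
            if not (cmin <= v <= min(mrl, cmax)):
                raise ValueError(f"{p!r}: cannot place a compliant residue under MRL {mrl}")
        values[i] = float(v)
    return [(slots[i][0], values[i], slots[i][1]) for i in range(len(slots))]


def build_survey_dataset(
    spec: Optional[FixtureSpec] = None,
) -> Tuple[List[SampleRecord], List[ResidueMeasurement], List[MRLEntry],
           List[ToxRef], pd.DataFrame]:
    """Rebuild a sample-level dataset reproducing the survey marginals.

    Returns ``(samples, measurements, mrl_table, tox_table, exposure_cells)``.
    ``mrl_table`` holds only registered entries; pairs whose assigned MRL
    equals the Positive List System default (0.01 mg/kg) are left to the
    fallback, mirroring how an unregistered pesticide is handled.
    Deterministic: two calls return identical datasets.
    """
    spec = spec or survey_spec()
    spec.validate()
    occ, inc = spec.occurrence, spec.incidence

    pairs_of: Dict[str, List[str]] = {}
    for p, c in spec.allowed_pairs:
        pairs_of.setdefault(p, []).append(c)

    # stage 1: violations
    viol_supplies = {r.pesticide: int(r.n_above) for r in inc.itertuples(index=False)
                     if r.n_above > 0}
    viol_demands = {r.product: int(r.n_above) for r in occ.itertuples(index=False)
                    if r.n_above > 0}
    viol_edges = [
        (p, c) for p in viol_supplies for c in pairs_of[p]
        if c in viol_demands
        and float(inc.set_index("pesticide").loc[p, "conc_max"])
        > float(inc.set_index("pesticide").loc[p, "mrl_min"])
    ]
    viol_flow = _solve_transport(viol_supplies, viol_demands, viol_edges, "violations")

    mrls = _assign_mrls(inc, pairs_of, viol_flow)

    # stage 2: compliant detections, one mandatory unit on every pair not
    # already covered by a violation
    inc_ix = inc.set_index("pesticide")
    mandatory: Dict[Tuple[str, str], int] = {}
    for p, c in spec.allowed_pairs:
        if viol_flow.get((p, c), 0) == 0:
            if mrls[(p, c)] < float(inc_ix.loc[p, "conc_min"]):
                raise ValueError(
                    f"pair ({p!r}, {c!r}): assigned MRL {mrls[(p, c)]} admits no "
                    f"compliant residue in range"
                )
            mandatory[(p, c)] = 1
    below_supplies = {
        r.pesticide: int(r.n_detected - r.n_above)
        - sum(n for (p, _), n in mandatory.items() if p == r.pesticide)
        for r in inc.itertuples(index=False)
    }
    below_demands = {
        r.product: int(r.n_below) - sum(n for (_, c), n in mandatory.items() if c == r.product)
        for r in occ.itertuples(index=False)
    }
    for name, residuals in (("pesticide", below_supplies), ("commodity", below_demands)):
        bad = sorted(k for k, v in residuals.items() if v < 0)
        if bad:
            raise ValueError(f"infeasible {name} rows (mandatory pair coverage exceeds "
                             f"printed counts): {bad}")
    below_edges = [
        (p, c) for p in below_supplies for c in pairs_of.get(p, [])
        if mrls[(p, c)] >= float(inc_ix.loc[p, "conc_min"])
    ]
    below_flow = _solve_transport(
        {k: v for k, v in below_supplies.items() if v > 0},
        {k: v for k, v in below_demands.items() if v > 0},
        [(p, c) for p, c in below_edges if below_supplies.get(p, 0) > 0
         and below_demands.get(c, 0) > 0],
        "compliant detections",
    )
    for pair, n in mandatory.items():
        below_flow[pair] = below_flow.get(pair, 0) + n

    # concentrations per pesticide
    detections: Dict[str, List[Tuple[str, float, str]]] = {}
    for row in inc.itertuples(index=False):
        p = row.pesticide
        slots: List[Tuple[str, str, float]] = []
        for c in sorted(pairs_of[p]):
            slots += [(c, "above", mrls[(p, c)])] * viol_flow.get((p, c), 0)
            slots += [(c, "below", mrls[(p, c)])] * below_flow.get((p, c), 0)
        if len(slots) != int(row.n_detected):
            raise ValueError(f"{p!r}: assigned {len(slots)} slots for "
                             f"{int(row.n_detected)} detections")
        detections[p] = _place_concentrations(row, slots)

    # assemble samples: contaminated ones first (one residue each), then clean
    group_of = {r.product: Group(r.group) for r in occ.itertuples(index=False)}
    per_commodity: Dict[str, List[Tuple[str, float]]] = {c: [] for c in occ["product"]}
    for p in sorted(detections):
        for commodity, conc, _kind in detections[p]:
            per_commodity[commodity].append((p, conc))

    samples: List[SampleRecord] = []
    measurements: List[ResidueMeasurement] = []
    for r in occ.itertuples(index=False):
        commodity = r.product
        slug = commodity.lower().replace(" ", "-")
        hits = sorted(per_commodity[commodity])
        if len(hits) != int(r.n_below + r.n_above):
            raise ValueError(f"{commodity!r}: assigned {len(hits)} residues for "
                             f"{int(r.n_below + r.n_above)} contaminated samples")
        for i in range(int(r.n_total)):
            sid = f"{slug}-{i + 1:04d}"
            samples.append(SampleRecord(sid, commodity, group_of[commodity]))
            if i < len(hits):
                pesticide, conc = hits[i]
                measurements.append(
                    ResidueMeasurement(sid, pesticide, conc, FIXTURE_LOD, FIXTURE_LOQ)
                )

    pls_default = 0.01
    mrl_table = [
        MRLEntry(p, c, m, MRLSource.REGISTERED)
        for (p, c), m in sorted(mrls.items())
        if m != pls_default
    ]
    return samples, measurements, mrl_table, survey_tox_table(), spec.exposure.copy()
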