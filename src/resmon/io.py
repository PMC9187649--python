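"""CSV readers and writers for monitoring data and reference tables.

The measurement file is *long* format: one row per sample x pesticide
quantification.  Samples in which nothing was detected appear once with an
empty ``pesticide`` cell, so the same file carries the full sample
denominator needed for occurrence percentages.

All files are UTF-8 CSV with a header row; lines starting with ``#`` are
treated as comments.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .types import (
    ConsumptionEntry,
    Group,
    MRLEntry,
    MRLSource,
    ResidueMeasurement,
    SampleRecord,
    ToxRef,
)

__all__ = [
    "read_measurements",
    "write_measurements",
    "read_reference_tables",
    "write_report",
    "SchemaError",
]

#: Cell values understood as "absent" for optional numeric columns (ARfD).
ABSENT_MARKERS = {"", "-", "–", "—", "na", "n/a", "none"}

MEASUREMENT_COLUMNS = ("sample_id", "commodity", "group", "pesticide", "concentration")


class SchemaError(ValueError):
    """A required column is missing from an input table."""


def _read_csv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", skip_blank_lines=True, dtype=str, **kw)


def _require(df: pd.DataFrame, columns: Iterable[str], path: str | Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _is_absent(cell) -> bool:
    return cell is None or (isinstance(cell, float) and pd.isna(cell)) or (
        isinstance(cell, str) and cell.strip().lower() in ABSENT_MARKERS
    )


def read_measurements(
    path: str | Path,
    schema: Optional[Mapping[str, str]] = None,
) -> Tuple[List[SampleRecord], List[ResidueMeasurement]]:
    """Read a long-format measurement CSV.

    Parameters
    ----------
    path
        CSV with columns ``sample_id, commodity, group, pesticide,
        concentration`` and optional ``lod, loq``.  A row with an empty
        pesticide cell declares a residue-free sample.
    schema
        Optional mapping from the canonical column names above to the names
        actually used in the file.

    Returns
    -------
    (samples, measurements)
        Validated records.  Duplicate ``(sample_id, pesticide)`` rows and
        samples listed under conflicting commodities are rejected; every
        measurement's sample id is checked to exist among the samples.
    """
    df = _read_csv(path)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    _require(df, MEASUREMENT_COLUMNS, path)

    samples: dict[str, SampleRecord] = {}
    measurements: List[ResidueMeasurement] = []
    seen_pairs: set[tuple[str, str]] = set()

    for i, row in enumerate(df.itertuples(index=False), start=2):
        sid = str(row.sample_id).strip()
        commodity = str(row.commodity).strip()
        group = Group(str(row.group).strip().lower())
        rec = SampleRecord(sid, commodity, group)
        prev = samples.get(sid)
        if prev is None:
            samples[sid] = rec
        elif prev != rec:
            raise ValueError(
                f"{path}, line {i}: sample {sid!r} re-declared with a different "
                f"commodity/group ({prev.commodity!r} vs {commodity!r})"
            )
        if _is_absent(row.pesticide):
            continue  # residue-free sample row
        pesticide = str(row.pesticide).strip()
        if (sid, pesticide) in seen_pairs:
            raise ValueError(f"{path}, line {i}: duplicate measurement ({sid!r}, {pesticide!r})")
        seen_pairs.add((sid, pesticide))
        try:
            conc = float(row.concentration)
            lod = float(getattr(row, "lod", 0.0) or 0.0)
            loq = float(getattr(row, "loq", 0.0) or 0.0)
            measurements.append(ResidueMeasurement(sid, pesticide, conc, lod, loq))
        except ValueError as exc:
            raise ValueError(f"{path}, line {i}: {exc}") from exc

    return list(samples.values()), measurements


def write_measurements(
    samples: Sequence[SampleRecord],
    measurements: Sequence[ResidueMeasurement],
    path: str | Path,
) -> None:
    """Write a dataset back to the long measurement format.

    Inverse of :func:`read_measurements`: samples with residues get one row
    per measurement, residue-free samples one row with an empty pesticide
    cell.
    """
    by_sample: dict[str, List[ResidueMeasurement]] = {s.sample_id: [] for s in samples}
    for m in measurements:
        if m.sample_id not in by_sample:
            raise ValueError(f"measurement references unknown sample {m.sample_id!r}")
        by_sample[m.sample_id].append(m)
    rows = []
    for s in samples:
        hits = by_sample[s.sample_id]
        if not hits:
            rows.append({"sample_id": s.sample_id, "commodity": s.commodity,
                         "group": s.group.value, "pesticide": "", "concentration": "",
                         "lod": "", "loq": ""})
        for m in hits:
            rows.append({"sample_id": s.sample_id, "commodity": s.commodity,
                         "group": s.group.value, "pesticide": m.pesticide,
                         "concentration": repr(m.concentration),
                         "lod": repr(m.lod), "loq": repr(m.loq)})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_reference_tables(
    mrl_path: str | Path,
    tox_path: str | Path,
    consumption_path: str | Path,
) -> Tuple[List[MRLEntry], List[ToxRef], List[ConsumptionEntry]]:
    """Read registered MRLs, toxicological reference doses and consumption.

    The ARfD column may contain an absence marker ("-", en dash or empty
    cell); it is preserved as ``None``, never coerced to 0.  An ADI <= 0 is a
    validation error.  Commodities in the consumption table that never occur
    in monitoring data are allowed.
    """
    mrl_df = _read_csv(mrl_path)
    _require(mrl_df, ("pesticide", "commodity", "mrl"), mrl_path)
    mrls = [
        MRLEntry(str(r.pesticide).strip(), str(r.commodity).strip(), float(r.mrl),
                 MRLSource.REGISTERED)
        for r in mrl_df.itertuples(index=False)
    ]

    tox_df = _read_csv(tox_path)
    _require(tox_df, ("pesticide", "adi"), tox_path)
    tox: List[ToxRef] = []
    for i, r in enumerate(tox_df.itertuples(index=False), start=2):
        arfd_cell = getattr(r, "arfd", None)
        arfd = None if _is_absent(arfd_cell) else float(arfd_cell)
        try:
            tox.append(ToxRef(str(r.pesticide).strip(), float(r.adi), arfd))
        except ValueError as exc:
            raise ValueError(f"{tox_path}, line {i}: {exc}") from exc

    cons_df = _read_csv(consumption_path)
    _require(cons_df, ("commodity", "daily_intake"), consumption_path)
    consumption = [
        ConsumptionEntry(str(r.commodity).strip(), float(r.daily_intake))
        for r in cons_df.itertuples(index=False)
    ]
    return mrls, tox, consumption


def _rows_to_frame(rows: Sequence) -> pd.DataFrame:
    if isinstance(rows, pd.DataFrame):
        return rows.copy()
    rows = list(rows)
    if not rows:
        return pd.DataFrame()
    first = rows[0]
    if dataclasses.is_dataclass(first):
        kinds = {type(r) for r in rows}
        if len(kinds) > 1:
            raise TypeError(f"heterogeneous rows: {sorted(k.__name__ for k in kinds)}")
        return pd.DataFrame([dataclasses.asdict(r) for r in rows])
    if isinstance(first, Mapping):
        return pd.DataFrame(list(rows))
    raise TypeError(f"unsupported row type {type(first).__name__}")


def write_report(rows: Sequence, path: str | Path, format: str = "csv",
                 columns: Optional[Sequence[str]] = None) -> None:
    """Write homogeneous summary rows as CSV or a markdown pipe table.

    Numbers already rounded for presentation round-trip bit-exactly through
    the CSV form.  An empty row list yields a header-only file (CSV) or an
    empty table.
    """
    df = _rows_to_frame(rows)
    if columns is not None and not df.empty:
        df = df[list(columns)]
    path = Path(path)
    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "markdown":
        cols = list(df.columns)
        lines = []
        if cols:
            lines.append("| " + " | ".join(cols) + " |")
            lines.append("| " + " | ".join("---" for _ in cols) + " |")
        for row in df.itertuples(index=False):
            lines.append("| " + " | ".join("" if pd.isna(v) else str(v) for v in row) + " |")
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    else:
        raise ValueError(f"unknown format {format!r} (expected 'csv' or 'markdown')")
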