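"""Delimited-text curve tables and structured fit reports.

A curve file is a comma-separated table preceded by a ``# key: value``
comment block carrying at least the concentration unit declaration and,
depending on the curve kind, the total protein concentration, a label
and the generating seed.  Concentration-like columns are normalized to
molar on read; everything round-trips exactly.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fret import DilutionSeries, FretCurvePoint, FretDataset
from .kinetics import KineticDataset, RatePoint

UNIT_SCALE = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "μM": 1e-6, "nM": 1e-9}

#: columns holding concentrations, rescaled by the declared unit on read
CONC_COLUMNS = ("I_total", "S_total", "E_dimer")
CONC_META = ("E_mono",)


class CurveFormatError(ValueError):
    pass


@dataclass
class CurveTable:
    """In-memory form of a curve file: data frame plus comment metadata.

    After :func:`read_curve` all concentration columns and metadata are
    in molar regardless of the declared unit.
    """

    df: pd.DataFrame
    meta: dict[str, str] = field(default_factory=dict)

    def __eq__(self, other):
        if not isinstance(other, CurveTable):
            return NotImplemented
        return self.meta == other.meta and self.df.equals(other.df)


def write_curve(path, table: CurveTable) -> None:
    """Write a curve table; the unit declaration is mandatory."""
    unit = table.meta.get("units")
    if unit is None or unit not in UNIT_SCALE:
        raise CurveFormatError(f"meta['units'] must be one of {sorted(UNIT_SCALE)}")
    scale = UNIT_SCALE[unit]
    df = table.df.copy()
    for col in CONC_COLUMNS:
        if col in df.columns:
            df[col] = df[col] / scale
    buf = _io.StringIO()
    for key, value in table.meta.items():
        if key in CONC_META:
            value = repr(float(value) / scale)
        buf.write(f"# {key}: {value}\n")
    df.to_csv(buf, index=False, float_format="%.17g")
    Path(path).write_text(buf.getvalue())


def read_curve(path) -> CurveTable:
    """Read a curve table, normalizing concentrations to molar."""
    lines = Path(path).read_text().splitlines()
    meta: dict[str, str] = {}
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            payload = line.lstrip("#").strip()
            if ":" not in payload:
                raise CurveFormatError(f"malformed metadata line {i + 1}: {line!r}")
            key, value = payload.split(":", 1)
            meta[key.strip()] = value.strip()
            body_start = i + 1
        else:
            break
    unit = meta.get("units")
    if unit is None:
        raise CurveFormatError("missing unit declaration ('# units: ...')")
    if unit not in UNIT_SCALE:
        raise CurveFormatError(f"unknown unit {unit!r}; expected one of {sorted(UNIT_SCALE)}")
    scale = UNIT_SCALE[unit]
    try:
        df = pd.read_csv(_io.StringIO("\n".join(lines[body_start:])),
                         float_precision="round_trip")
    except Exception as exc:
        raise CurveFormatError(f"cannot parse table body: {exc}") from exc
    for col in CONC_COLUMNS:
        if col in df.columns:
            bad = np.flatnonzero(df[col].to_numpy() < 0)
            if bad.size:
                raise CurveFormatError(
                    f"negative concentration in column {col!r}, data row {bad[0] + 1}"
                )
            df[col] = df[col] * scale
    for key in CONC_META:
        if key in meta:
            meta[key] = repr(float(meta[key]) * scale)
    meta["units"] = "M"
    return CurveTable(df=df, meta=meta)


# ---------------------------------------------------------------------------
# dataset converters


def fret_to_table(ds: FretDataset, extra_meta: dict | None = None) -> CurveTable:
    df = pd.DataFrame({
        "I_total": [p.I_total for p in ds.points],
        "phi": [p.phi for p in ds.points],
    })
    if ds.sigma is not None:
        df["sigma"] = ds.sigma
    meta = {"kind": "fret", "units": "M", "E_mono": repr(ds.E_mono),
            "e_unit": ds.e_unit, "label": ds.label}
    meta.update(extra_meta or {})
    return CurveTable(df=df, meta=meta)


def table_to_fret(table: CurveTable) -> FretDataset:
    df = table.df
    has_sigma = "sigma" in df.columns
    pts = tuple(
        FretCurvePoint(
            float(r.I_total), float(r.phi),
            float(r.sigma) if has_sigma and pd.notna(r.sigma) else None,
        )
        for r in df.itertuples()
    )
    return FretDataset(
        E_mono=float(table.meta["E_mono"]),
        points=pts,
        label=table.meta.get("label", ""),
        e_unit=table.meta.get("e_unit", "monomer"),
    )


def kinetics_to_table(ds: KineticDataset, extra_meta: dict | None = None) -> CurveTable:
    df = pd.DataFrame({
        "S_total": [p.S_total for p in ds.points],
        "I_total": [p.I_total for p in ds.points],
        "v": [p.v for p in ds.points],
    })
    sig = [p.sigma_rel for p in ds.points]
    if not any(s is None for s in sig):
        df["sigma_rel"] = sig
    meta = {"kind": "kinetics", "units": "M", "E_mono": repr(ds.E_mono), "label": ds.label}
    meta.update(extra_meta or {})
    return CurveTable(df=df, meta=meta)


def table_to_kinetics(table: CurveTable) -> KineticDataset:
    df = table.df
    has_sigma = "sigma_rel" in df.columns
    pts = tuple(
        RatePoint(
            float(r.S_total), float(r.I_total), float(r.v),
            float(r.sigma_rel) if has_sigma and pd.notna(r.sigma_rel) else None,
        )
        for r in df.itertuples()
    )
    return KineticDataset(E_mono=float(table.meta["E_mono"]), points=pts,
                          label=table.meta.get("label", ""))


def dilution_to_table(series: DilutionSeries, extra_meta: dict | None = None) -> CurveTable:
    df = pd.DataFrame({"E_dimer": series.E_dimer, "phi": series.phi})
    meta = {"kind": "dilution", "units": "M", "label": series.label}
    if series.sigma is not None:
        meta["sigma"] = repr(series.sigma)
    meta.update(extra_meta or {})
    return CurveTable(df=df, meta=meta)


def table_to_dilution(table: CurveTable) -> DilutionSeries:
    df = table.df
    sigma = table.meta.get("sigma")
    return DilutionSeries(
        E_dimer=tuple(float(x) for x in df["E_dimer"]),
        phi=tuple(float(x) for x in df["phi"]),
        sigma=float(sigma) if sigma is not None else None,
        label=table.meta.get("label", ""),
    )


def write_report(path, entries: dict) -> None:
    """Key-value fit report, one ``key = value`` line per entry."""
    with open(path, "w") as fh:
        for key, value in entries.items():
            fh.write(f"{key} = {value}\n")


def read_report(path) -> dict[str, str]:
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out
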