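"""Delimited-text and flat key-value readers/writers.

All pipeline inputs and outputs are plain text: kinetic schemes and trace
specs as flat ``key = value`` config files (one rate per key, units in the
key names' documentation), time courses and tables as delimited text with a
mandatory header.  Concentrations are nM, times seconds.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import numpy as np
import pandas as pd

from .gel_quant import LaneQuant
from .mechanism import KineticScheme, TimeCourse
from .repeat_instability import PeakTable
from .synthetic_data import TraceSpec

__all__ = [
    "read_config", "write_config",
    "read_scheme", "write_scheme",
    "read_trace_spec", "write_trace_spec",
    "write_timecourse", "read_timecourse",
    "read_lane_table", "write_lane_table",
    "read_peak_tables",
]

TIMECOURSE_COLUMNS = ["time_s", "S_nM", "I_nM", "P_nM", "bound_nM"]


def read_config(path) -> dict:
    """Parse a flat ``key = value`` config file ('#' starts a comment)."""
    out = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        out[key] = value
    return out


def write_config(path, mapping: dict) -> None:
    lines = [f"{k} = {v}" for k, v in mapping.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def _coerce(value: str, typ):
    if typ is bool or typ == "bool":
        return value.lower() in ("1", "true", "yes", "on")
    return typ(value)


def read_scheme(path) -> KineticScheme:
    """Read a kinetic scheme from flat config (rates per s, k_on per nM per s)."""
    raw = read_config(path)
    kwargs = {}
    for f in fields(KineticScheme):
        if f.name not in raw:
            continue
        value = raw[f.name]
        if f.name == "rebinding":
            kwargs[f.name] = _coerce(value, bool)
        elif f.name == "k_readenylylate":
            kwargs[f.name] = None if value.lower() in ("none", "inf") else float(value)
        else:
            kwargs[f.name] = float(value)
    return KineticScheme(**kwargs)


def write_scheme(path, scheme: KineticScheme) -> None:
    mapping = {f.name: getattr(scheme, f.name) for f in fields(KineticScheme)}
    if mapping["k_readenylylate"] is None:
        mapping["k_readenylylate"] = "none"
    write_config(path, mapping)


def read_trace_spec(path) -> TraceSpec:
    raw = read_config(path)
    kwargs = {}
    for f in fields(TraceSpec):
        if f.name in raw:
            typ = int if f.name in ("inherited_repeat", "bp_per_repeat") else float
            kwargs[f.name] = typ(float(raw[f.name]))
    return TraceSpec(**kwargs)


def write_trace_spec(path, spec: TraceSpec) -> None:
    write_config(path, {f.name: getattr(spec, f.name) for f in fields(TraceSpec)})


def write_timecourse(path, course: TimeCourse, sep: str = "\t") -> None:
    frame = pd.DataFrame({
        "time_s": course.times, "S_nM": course.S, "I_nM": course.I,
        "P_nM": course.P, "bound_nM": course.bound})
    frame.to_csv(path, sep=sep, index=False)


def read_timecourse(path, enzyme_conc: float, substrate_conc: float,
                    sep: str = "\t") -> TimeCourse:
    frame = pd.read_csv(path, sep=sep)
    missing = [c for c in TIMECOURSE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"time-course file missing columns {missing}")
    return TimeCourse(
        times=frame["time_s"].to_numpy(float), S=frame["S_nM"].to_numpy(float),
        I=frame["I_nM"].to_numpy(float), P=frame["P_nM"].to_numpy(float),
        bound=frame["bound_nM"].to_numpy(float),
        enzyme_conc=enzyme_conc, substrate_conc=substrate_conc)


LANE_COLUMNS = ["lane", "enzyme", "substrate_context", "enzyme_conc_nM",
                "substrate_conc_nM", "time_s", "intensity_substrate",
                "intensity_product"]


def read_lane_table(path, sep: str = "\t") -> tuple[pd.DataFrame, list]:
    """Read a gel-lane intensity table; returns (frame, list of LaneQuant).

    An ``intensity_intermediate`` column marks resolved (sequencing-gel)
    lanes; without it lanes are treated as unresolved mini-gel lanes.
    """
    frame = pd.read_csv(path, sep=sep)
    missing = [c for c in LANE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"lane table missing columns {missing}")
    resolved = "intensity_intermediate" in frame.columns
    lanes = []
    for _, r in frame.iterrows():
        inter = r.get("intensity_intermediate", np.nan)
        row_resolved = resolved and not pd.isna(inter)
        lanes.append(LaneQuant(
            lane=str(r["lane"]), enzyme_label=str(r["enzyme"]),
            substrate_label=str(r["substrate_context"]),
            enzyme_conc=float(r["enzyme_conc_nM"]), time_s=float(r["time_s"]),
            intensity_substrate=float(r["intensity_substrate"]),
            intensity_product=float(r["intensity_product"]),
            intensity_intermediate=float(inter) if row_resolved else None,
            resolved_intermediate=row_resolved))
    return frame, lanes


def write_lane_table(path, frame: pd.DataFrame, sep: str = "\t") -> None:
    frame.to_csv(path, sep=sep, index=False)


def read_peak_tables(
    path,
    sep: str = "\t",
    sample_col: str = "sample",
    position_col: str = "size",
    height_col: str = "height",
    units: str = "bp",
    mouse_col: str | None = "mouse",
    tissue_col: str | None = "tissue",
    genotype_col: str | None = "genotype",
    age_col: str | None = "age_months",
) -> list:
    """Read a GeneMapper-style delimited peak export into PeakTables.

    Column names are configurable to match different export layouts; rows
    are grouped by sample id and sorted by position.  Optional metadata
    columns (mouse, tissue, genotype, age) are carried through when
    present.
    """
    frame = pd.read_csv(path, sep=sep)
    for col in (sample_col, position_col, height_col):
        if col not in frame.columns:
            raise ValueError(f"peak table missing column {col!r}")
    tables = []
    for sample, sub in frame.groupby(sample_col):
        sub = sub.sort_values(position_col)
        meta = {}
        for key, col in (("mouse_id", mouse_col), ("tissue", tissue_col),
                         ("genotype", genotype_col)):
            if col and col in sub.columns:
                meta[key] = str(sub[col].iloc[0])
        if age_col and age_col in sub.columns:
            meta["age_months"] = float(sub[age_col].iloc[0])
        tables.append(PeakTable(
            sample_id=str(sample),
            positions=sub[position_col].to_numpy(float),
            heights=sub[height_col].to_numpy(float),
            position_units=units, **meta))
    return tables
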