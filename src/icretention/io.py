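"""Schema-validated CSV/JSON/YAML readers and writers.

Schemas
-------
``effluent.csv``  : run_id, cell_type, injected_dose, minute, flow_ml_min,
                    conc_cells_ml, replicate
``sizes.csv``     : sample_id, population (pre|effluent), bin_lower_um, count
``histology.csv`` : heart_id, level, layer, labeled_cells, area_mm2,
                    heart_mass_mg, injected_dose

Malformed rows are reported with their 1-based file line numbers (header =
line 1).  All writers round-trip losslessly through the readers.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .effluent import EffluentRecord, PerfusionRun
from .histology import HeartStereology, SectionCount
from .simulator import SimulatorParams
from .sizes import SizeHistogram

__all__ = [
    "RunConfig",
    "read_effluent_csv",
    "write_effluent_csv",
    "read_sizes_csv",
    "write_sizes_csv",
    "read_histology_csv",
    "write_histology_csv",
    "params_to_yaml",
    "params_from_yaml",
    "load_config",
    "write_json",
]

EFFLUENT_COLUMNS = ["run_id", "cell_type", "injected_dose", "minute",
                    "flow_ml_min", "conc_cells_ml", "replicate"]
SIZES_COLUMNS = ["sample_id", "population", "bin_lower_um", "count"]
HISTOLOGY_COLUMNS = ["heart_id", "level", "layer", "labeled_cells",
                     "area_mm2", "heart_mass_mg", "injected_dose"]


class SchemaError(ValueError):
    """A file failed schema validation; the message names the offending row."""


def _require_columns(df: pd.DataFrame, required: list[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _line(idx: int) -> int:
    # pandas row index -> 1-based file line (header occupies line 1)
    return int(idx) + 2


def read_effluent_csv(path: str | Path) -> list[PerfusionRun]:
    """Read per-minute effluent records into PerfusionRun objects.

    Replicate concentration reads for the same (run, minute) are collected
    into one record; flow must agree across replicates of a minute.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, EFFLUENT_COLUMNS, path)
    for idx, row in df.iterrows():
        if row["conc_cells_ml"] < 0:
            raise SchemaError(
                f"{path} line {_line(idx)}: negative concentration "
                f"{row['conc_cells_ml']}"
            )
        if row["flow_ml_min"] < 0:
            raise SchemaError(f"{path} line {_line(idx)}: negative flow")
        if row["injected_dose"] <= 0:
            raise SchemaError(f"{path} line {_line(idx)}: non-positive dose")
        if row["minute"] < 1 or row["minute"] != int(row["minute"]):
            raise SchemaError(
                f"{path} line {_line(idx)}: minute must be a positive integer"
            )
    dup = df.duplicated(subset=["run_id", "minute", "replicate"])
    if dup.any():
        idx = df.index[dup][0]
        key = tuple(df.loc[idx, ["run_id", "minute", "replicate"]])
        raise SchemaError(
            f"{path} line {_line(idx)}: duplicate (run_id, minute, replicate) key {key}"
        )

    runs: list[PerfusionRun] = []
    for run_id, g in df.groupby("run_id", sort=True):
        doses = g["injected_dose"].unique()
        types = g["cell_type"].unique()
        if len(doses) > 1 or len(types) > 1:
            raise SchemaError(
                f"{path}: run {run_id!r} has inconsistent dose or cell_type"
            )
        records = []
        for minute, gm in g.groupby("minute", sort=True):
            flows = gm["flow_ml_min"].unique()
            if len(flows) > 1:
                raise SchemaError(
                    f"{path}: run {run_id!r} minute {minute}: replicates "
                    f"disagree on flow ({flows.tolist()})"
                )
            reads = tuple(
                float(r) for r in gm.sort_values("replicate")["conc_cells_ml"]
            )
            records.append(
                EffluentRecord(int(minute), float(flows[0]), reads)
            )
        runs.append(
            PerfusionRun(
                injected_dose=float(doses[0]),
                cell_type=str(types[0]),
                effluent_series=tuple(records),
                run_id=str(run_id),
            )
        )
    if not runs:
        raise SchemaError(f"{path}: no runs found")
    return runs


def write_effluent_csv(runs: Iterable[PerfusionRun], path: str | Path) -> None:
    rows = []
    for run in runs:
        for rec in run.effluent_series:
            for i, read in enumerate(rec.concentration_reads, start=1):
                rows.append(
                    {
                        "run_id": run.run_id,
                        "cell_type": run.cell_type,
                        "injected_dose": run.injected_dose,
                        "minute": rec.minute_index,
                        "flow_ml_min": rec.flow_volume,
                        "conc_cells_ml": read,
                        "replicate": i,
                    }
                )
    pd.DataFrame(rows, columns=EFFLUENT_COLUMNS).to_csv(path, index=False)


def read_sizes_csv(path: str | Path) -> dict[tuple[str, str], SizeHistogram]:
    """Read size histograms keyed by (sample_id, population)."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, SIZES_COLUMNS, path)
    for idx, row in df.iterrows():
        if row["count"] < 0:
            raise SchemaError(f"{path} line {_line(idx)}: negative count")
        if row["population"] not in ("pre", "effluent"):
            raise SchemaError(
                f"{path} line {_line(idx)}: population must be 'pre' or "
                f"'effluent', got {row['population']!r}"
            )
    dup = df.duplicated(subset=["sample_id", "population", "bin_lower_um"])
    if dup.any():
        idx = df.index[dup][0]
        raise SchemaError(
            f"{path} line {_line(idx)}: duplicate bin for "
            f"({df.loc[idx, 'sample_id']!r}, {df.loc[idx, 'population']!r})"
        )
    out: dict[tuple[str, str], SizeHistogram] = {}
    for (sid, pop), g in df.groupby(["sample_id", "population"], sort=True):
        bins = {int(b): float(c) for b, c in zip(g["bin_lower_um"], g["count"])}
        out[(str(sid), str(pop))] = SizeHistogram.from_dict(bins)
    return out


def write_sizes_csv(
    hists: Mapping[tuple[str, str], SizeHistogram], path: str | Path
) -> None:
    rows = [
        {"sample_id": sid, "population": pop, "bin_lower_um": int(d), "count": c}
        for (sid, pop), h in hists.items()
        for d, c in zip(h.lower_edges, h.counts)
    ]
    pd.DataFrame(rows, columns=SIZES_COLUMNS).to_csv(path, index=False)


def read_histology_csv(
    path: str | Path, section_thickness_mm: float = 0.0075
) -> list[HeartStereology]:
    """Read section-count tables into per-heart stereology objects."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, HISTOLOGY_COLUMNS, path)
    for idx, row in df.iterrows():
        if row["labeled_cells"] < 0:
            raise SchemaError(f"{path} line {_line(idx)}: negative labeled_cells")
        if row["area_mm2"] <= 0:
            raise SchemaError(f"{path} line {_line(idx)}: non-positive area_mm2")
        if row["heart_mass_mg"] <= 0:
            raise SchemaError(f"{path} line {_line(idx)}: non-positive heart_mass_mg")
    hearts: list[HeartStereology] = []
    for heart_id, g in df.groupby("heart_id", sort=True):
        masses = g["heart_mass_mg"].unique()
        doses = g["injected_dose"].unique()
        if len(masses) > 1 or len(doses) > 1:
            raise SchemaError(
                f"{path}: heart {heart_id!r} has inconsistent mass or dose"
            )
        sections = tuple(
            SectionCount(
                heart_id=str(heart_id),
                level=str(r["level"]),
                layer=str(r["layer"]),
                labeled_cells=float(r["labeled_cells"]),
                examined_area=float(r["area_mm2"]),
            )
            for _, r in g.iterrows()
        )
        hearts.append(
            HeartStereology(
                heart_id=str(heart_id),
                heart_mass=float(masses[0]),
                injected_dose=float(doses[0]),
                sections=sections,
                section_thickness=section_thickness_mm,
            )
        )
    if not hearts:
        raise SchemaError(f"{path}: no hearts found")
    return hearts


def write_histology_csv(hearts: Iterable[HeartStereology], path: str | Path) -> None:
    rows = [
        {
            "heart_id": h.heart_id,
            "level": s.level,
            "layer": s.layer,
            "labeled_cells": s.labeled_cells,
            "area_mm2": s.examined_area,
            "heart_mass_mg": h.heart_mass,
            "injected_dose": h.injected_dose,
        }
        for h in hearts
        for s in h.sections
    ]
    pd.DataFrame(rows, columns=HISTOLOGY_COLUMNS).to_csv(path, index=False)


def params_to_yaml(params: SimulatorParams, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(params.to_dict(), sort_keys=True))


def params_from_yaml(path: str | Path) -> SimulatorParams:
    return SimulatorParams.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Top-level configuration for the end-to-end report pipeline."""

    cell_type: str = "BMMNC"
    dose: float = 1e6
    n_hearts: int = 8
    window_minutes: int = 5
    seed: int = 0
    clamp: bool = True
    section_thickness_mm: float = 0.0075
    out_dir: str | None = None
    params: SimulatorParams | None = None  # defaults to calibrated cell-type params

    def __post_init__(self) -> None:
        if self.n_hearts < 1:
            raise ValueError("n_hearts must be >= 1")
        if self.dose < 1:
            raise ValueError("dose must be >= 1")
        if self.window_minutes < 1:
            raise ValueError("window_minutes must be >= 1")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an explicit integer")


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    params = raw.pop("params", None)
    cfg = RunConfig(
        **{k: v for k, v in raw.items() if k in RunConfig.__dataclass_fields__},
        **({"params": SimulatorParams.from_dict(params)} if params else {}),
    )
    return cfg


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(doc: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(doc), indent=2) + "\n")
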