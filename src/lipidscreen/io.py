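"""CSV/TIFF/YAML interchange and run configuration.

All tabular data travels as CSV; well images as single-channel 16-bit
TIFFs named ``<plate_id>_<well>_<hoechst|bodipy>.tiff``; one YAML file
drives a run.  Floating-point CSV output uses 6 significant digits, so a
fixed seed yields byte-identical files.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .models import (
    CHANNEL_LIPID,
    CHANNEL_NUCLEAR,
    ROLE_COMPOUND,
    ROLE_EMPTY,
    VALID_ROLES,
    CompoundResult,
    PlateLayout,
    PlateStats,
    ScoredWell,
    SimulationConfig,
    Well,
    WellImage,
    WellQuant,
    well_label,
)
from .plate_stats import MIN_SCORING_WELLS, SCOPE_COMPOUND_ONLY
from .quantify import QuantParams

FLOAT_FORMAT = "%.6g"

_LABEL_RE = re.compile(r"^([A-Za-z])0*([1-9][0-9]*)$")


def normalize_well_label(label: str) -> str:
    """Canonical well label: upper-case row letter, zero-padded column (A1 -> A01)."""
    m = _LABEL_RE.match(label.strip())
    if not m:
        raise ValueError(f"malformed well label {label!r}")
    return f"{m.group(1).upper()}{int(m.group(2)):02d}"


# ---------------------------------------------------------------------------
# plate maps


def read_plate_map(path: str | Path, n_rows: int = 16, n_cols: int = 24) -> list[PlateLayout]:
    """Read a plate-map CSV (plate_id,replicate_id,well,role,compound_id).

    Wells absent from the file are filled in as ``empty``.  Labels are
    normalized; duplicate or malformed rows raise with their row number.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["plate_id", "replicate_id", "well", "role", "compound_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"plate map {path}: missing columns {missing}")

    plates: dict[tuple[str, int], dict[str, Well]] = {}
    for idx, row in df.iterrows():
        rowno = idx + 2  # header is row 1
        try:
            label = normalize_well_label(row["well"])
        except ValueError as exc:
            raise ValueError(f"plate map row {rowno}: {exc}") from exc
        role = row["role"].strip()
        if role not in VALID_ROLES:
            raise ValueError(
                f"plate map row {rowno}: unknown role {role!r}; allowed: {sorted(VALID_ROLES)}"
            )
        try:
            rep = int(row["replicate_id"])
        except ValueError as exc:
            raise ValueError(f"plate map row {rowno}: bad replicate_id") from exc
        key = (row["plate_id"], rep)
        wells = plates.setdefault(key, {})
        if label in wells:
            raise ValueError(
                f"plate map row {rowno}: duplicate well {label} on plate {key[0]}"
            )
        cid = row["compound_id"].strip() or None
        if role == ROLE_COMPOUND and cid is None:
            raise ValueError(f"plate map row {rowno}: compound well {label} lacks compound_id")
        wells[label] = Well(label, role, cid)

    layouts = []
    all_labels = [well_label(r, c) for r in range(n_rows) for c in range(n_cols)]
    for (plate_id, rep), wells in plates.items():
        unknown = set(wells) - set(all_labels)
        if unknown:
            raise ValueError(
                f"plate {plate_id}: wells {sorted(unknown)} outside the {n_rows}x{n_cols} grid"
            )
        ordered = [wells.get(lab, Well(lab, ROLE_EMPTY)) for lab in all_labels]
        layout = PlateLayout(plate_id, rep, n_rows, n_cols, ordered)
        layout.validate()
        layouts.append(layout)
    return layouts


def write_plate_map(layouts: Sequence[PlateLayout], path: str | Path) -> None:
    rows = [
        {
            "plate_id": lay.plate_id,
            "replicate_id": lay.replicate_id,
            "well": w.label,
            "role": w.role,
            "compound_id": w.compound_id or "",
        }
        for lay in layouts
        for w in lay.wells
        if w.role != ROLE_EMPTY
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# quant / scored / stats / hits tables

_QUANT_COLS = [
    "plate_id",
    "replicate_id",
    "well",
    "role",
    "compound_id",
    "total_cells",
    "positive_cells",
    "percent_positive",
    "low_cell_flag",
]


def quants_to_frame(quants: Sequence[WellQuant]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "plate_id": q.plate_id,
                "replicate_id": q.replicate_id,
                "well": q.well_label,
                "role": q.role,
                "compound_id": q.compound_id or "",
                "total_cells": q.total_cells,
                "positive_cells": q.positive_cells,
                "percent_positive": q.percent_positive,
                "low_cell_flag": q.low_cell_flag,
            }
            for q in quants
        ],
        columns=_QUANT_COLS,
    )


def write_quants(quants: Sequence[WellQuant], path: str | Path) -> None:
    quants_to_frame(quants).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_quants(path: str | Path) -> list[WellQuant]:
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    return [
        WellQuant(
            plate_id=str(r.plate_id),
            replicate_id=int(r.replicate_id),
            well_label=str(r.well),
            role=str(r.role),
            compound_id=str(r.compound_id) or None,
            total_cells=int(r.total_cells),
            positive_cells=int(r.positive_cells),
            percent_positive=float(r.percent_positive),
            low_cell_flag=str(r.low_cell_flag) == "True",
        )
        for r in df.itertuples()
    ]


def write_scored(
    scored: Sequence[ScoredWell], stats_by_plate: dict[tuple[str, int], PlateStats], path: str | Path
) -> None:
    rows = []
    for sw in scored:
        st = stats_by_plate[(sw.plate_id, sw.replicate_id)]
        rows.append(
            {
                "plate_id": sw.plate_id,
                "replicate_id": sw.replicate_id,
                "well": sw.well_label,
                "role": sw.role,
                "compound_id": sw.compound_id or "",
                "total_cells": sw.total_cells,
                "positive_cells": sw.positive_cells,
                "percent_positive": sw.percent_positive,
                "low_cell_flag": sw.low_cell_flag,
                "z": sw.z,
                "plate_median": st.median,
                "plate_mad": st.mad,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_scored(path: str | Path) -> list[ScoredWell]:
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    return [
        ScoredWell(
            plate_id=str(r.plate_id),
            replicate_id=int(r.replicate_id),
            well_label=str(r.well),
            role=str(r.role),
            compound_id=str(r.compound_id) or None,
            total_cells=int(r.total_cells),
            positive_cells=int(r.positive_cells),
            percent_positive=float(r.percent_positive),
            low_cell_flag=str(r.low_cell_flag) == "True",
            z=float(r.z),
        )
        for r in df.itertuples()
    ]


def write_plate_stats(
    stats: Sequence[PlateStats], path: str | Path
) -> None:
    pd.DataFrame([dataclasses.asdict(s) for s in stats]).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def write_hit_tables(
    results: Sequence[CompoundResult], out_dir: str | Path
) -> tuple[Path, Path]:
    """Write ``hits.csv`` (hits only, ranked) and ``all_compounds.csv``."""
    from .hit_calling import compound_table

    out_dir = Path(out_dir)
    full = compound_table(results)
    hits = full[full["is_hit"]].sort_values("rank")
    hits_path = out_dir / "hits.csv"
    all_path = out_dir / "all_compounds.csv"
    hits.to_csv(hits_path, index=False, float_format=FLOAT_FORMAT)
    full.to_csv(all_path, index=False, float_format=FLOAT_FORMAT)
    return hits_path, all_path


def read_annotations(path: str | Path) -> dict[str, str]:
    """Two-column CSV (compound_id, annotation) -> mapping."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = list(df.columns[:2])
    return dict(zip(df[cols[0]], df[cols[1]]))


# ---------------------------------------------------------------------------
# well images

_STAIN_BY_CHANNEL = {CHANNEL_NUCLEAR: "hoechst", CHANNEL_LIPID: "bodipy"}


def read_well_image(images_dir: str | Path, plate_id: str, well: str) -> WellImage:
    """Load the two single-channel TIFFs of one well by filename convention."""
    import tifffile

    images_dir = Path(images_dir)
    channels = {}
    for channel, stain in _STAIN_BY_CHANNEL.items():
        path = images_dir / f"{plate_id}_{well}_{stain}.tiff"
        if not path.exists():
            raise FileNotFoundError(path)
        channels[channel] = tifffile.imread(path)
    img = WellImage(well_label=well, plate_id=plate_id, channels=channels)
    img.validate()
    return img


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class ScreenDesign:
    """Plate geometry and content of a simulated screen."""

    n_compounds: int = 320
    controls_per_role: int = 16
    n_replicates: int = 2
    n_rows: int = 16
    n_cols: int = 24


@dataclass
class StatsParams:
    scope: str = SCOPE_COMPOUND_ONLY
    mad_zero: str = "raise"
    min_scoring_wells: int = MIN_SCORING_WELLS


@dataclass
class HitParams:
    z_threshold: float = 5.0
    min_replicates: int = 2
    death_cutoff: float = 0.60


@dataclass
class RunConfig:
    """Fully-resolved configuration of one end-to-end run.

    Defaults reproduce the screen's printed rule set: robust Z with the
    1.4826 MAD scale, hit threshold Z > 5 in 2 replicates, exclusion above
    60% cell death.
    """

    mode: str = "summary"  # "summary" or "image"
    seed: int = 0
    output_dir: Optional[str] = None
    images_dir: Optional[str] = None  # ingest pre-existing images instead of simulating
    plate_map: Optional[str] = None
    write_images: bool = False
    log_level: str = "INFO"
    screen: ScreenDesign = field(default_factory=ScreenDesign)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    quant: QuantParams = field(default_factory=QuantParams)
    stats: StatsParams = field(default_factory=StatsParams)
    hits: HitParams = field(default_factory=HitParams)


def _dataclass_from_dict(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def config_from_dict(data: dict) -> RunConfig:
    data = dict(data)
    sub = {
        "screen": ScreenDesign,
        "simulation": SimulationConfig,
        "quant": QuantParams,
        "stats": StatsParams,
        "hits": HitParams,
    }
    kwargs: dict = {}
    for key, cls in sub.items():
        if key in data:
            kwargs[key] = _dataclass_from_dict(cls, data.pop(key) or {})
    sim = kwargs.get("simulation")
    if sim is not None:
        sim.image_size = tuple(sim.image_size)
        sim.planted_hits = tuple(sim.planted_hits)
    cfg = _dataclass_from_dict(RunConfig, {**data, **kwargs})
    if cfg.mode not in ("summary", "image"):
        raise ValueError(f"mode must be 'summary' or 'image', got {cfg.mode!r}")
    return cfg


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    data = dataclasses.asdict(config)
    data["simulation"]["image_size"] = list(config.simulation.image_size)
    data["simulation"]["planted_hits"] = list(config.simulation.planted_hits)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
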