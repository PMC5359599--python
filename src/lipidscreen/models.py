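"""Shared data containers for the screening pipeline.

The screen readout is a per-well statistic: the percentage of nuclei
(Hoechst-positive objects) whose perinuclear neutral-lipid (Bodipy) signal
exceeds a calibrated threshold.  Everything downstream — plate statistics,
robust Z scores, hit calls — is computed from :class:`WellQuant` rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

ROLE_NEGATIVE = "negative_control"
ROLE_POSITIVE = "positive_control"
ROLE_COMPOUND = "compound"
ROLE_EMPTY = "empty"
VALID_ROLES = frozenset({ROLE_NEGATIVE, ROLE_POSITIVE, ROLE_COMPOUND, ROLE_EMPTY})

#: Channel keys used throughout: DNA stain marks nuclei, neutral-lipid stain
#: marks droplets.
CHANNEL_NUCLEAR = "nuclear"
CHANNEL_LIPID = "lipid"

_ROW_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def well_label(row: int, col: int) -> str:
    """0-based (row, col) -> plate label, e.g. (0, 0) -> 'A01'."""
    if row < 0 or row >= len(_ROW_LETTERS) or col < 0:
        raise ValueError(f"well position out of range: ({row}, {col})")
    return f"{_ROW_LETTERS[row]}{col + 1:02d}"


@dataclass(frozen=True)
class Well:
    label: str
    role: str
    compound_id: Optional[str] = None


@dataclass
class PlateLayout:
    """Well-to-role/compound assignment for one physical plate.

    Replicate plates are independent layouts that share compound identities
    but not necessarily well positions.
    """

    plate_id: str
    replicate_id: int
    n_rows: int = 16
    n_cols: int = 24
    wells: list[Well] = field(default_factory=list)

    def validate(self) -> None:
        if self.replicate_id < 1:
            raise ValueError("replicate_id must be a positive integer")
        if len(self.wells) != self.n_rows * self.n_cols:
            raise ValueError(
                f"plate {self.plate_id}: expected {self.n_rows * self.n_cols} "
                f"wells, got {len(self.wells)}"
            )
        labels = [w.label for w in self.wells]
        if len(set(labels)) != len(labels):
            raise ValueError(f"plate {self.plate_id}: duplicate well labels")
        compound_ids = []
        for w in self.wells:
            if w.role not in VALID_ROLES:
                raise ValueError(f"unknown role {w.role!r}; allowed: {sorted(VALID_ROLES)}")
            if w.role == ROLE_COMPOUND:
                if not w.compound_id:
                    raise ValueError(f"compound well {w.label} lacks a compound_id")
                compound_ids.append(w.compound_id)
        if len(set(compound_ids)) != len(compound_ids):
            raise ValueError(f"plate {self.plate_id}: repeated compound_id")
        n_neg = sum(w.role == ROLE_NEGATIVE for w in self.wells)
        n_pos = sum(w.role == ROLE_POSITIVE for w in self.wells)
        if n_neg < 4 or n_pos < 4:
            raise ValueError(
                f"plate {self.plate_id}: need >=4 wells per control role "
                f"(got {n_neg} negative, {n_pos} positive)"
            )

    def wells_by_role(self, role: str) -> list[Well]:
        return [w for w in self.wells if w.role == role]

    def well(self, label: str) -> Well:
        for w in self.wells:
            if w.label == label:
                return w
        raise KeyError(label)


@dataclass(frozen=True)
class CellRecord:
    """Ground-truth record for one simulated surviving cell."""

    x: float
    y: float
    is_responder: bool
    n_droplets: int


@dataclass
class WellTruth:
    """Simulation ground truth for one well (unknown to the quantifier)."""

    well_label: str
    n_cells_seeded: int
    death_fraction: float
    responder_fraction: float
    cells: list[CellRecord] = field(default_factory=list)

    @property
    def n_surviving(self) -> int:
        return len(self.cells)

    @property
    def n_responders(self) -> int:
        return sum(c.is_responder for c in self.cells)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic screen.

    Defaults are desk-scale: 300 cells per well on 512x512 px images (the
    assay plates the generator emulates seed 1500 cells per 384-plate well;
    ``full_scale()`` in :mod:`lipidscreen.simulate` restores that).  A well's
    true responder fraction is set by its role: negative controls sit at
    ``baseline_percent_positive``, positive controls at
    ``positive_control_responder_fraction``, and compound wells at baseline
    unless listed in ``planted_hits``, which adds ``hit_effect``.
    """

    seed: int = 0
    cells_per_well: int = 300
    image_size: tuple[int, int] = (512, 512)
    nucleus_radius_px: float = 5.0
    nucleus_intensity: float = 12000.0
    droplet_count_responder: float = 8.0
    droplet_count_background: float = 0.0
    droplet_intensity: float = 20000.0
    droplet_radius_px: float = 2.0
    droplet_scatter_factor: float = 0.6  # droplet centres within this x nucleus radius
    background_level: float = 400.0
    noise_sd: float = 50.0
    baseline_percent_positive: float = 5.0
    positive_control_responder_fraction: float = 0.6
    hit_effect: float = 0.5
    planted_hits: tuple[str, ...] = ()
    death_by_compound: dict[str, float] = field(default_factory=dict)
    illumination_gradient: float = 0.0  # fractional background slope across the image

    def validate(self) -> None:
        if self.cells_per_well < 0:
            raise ValueError("cells_per_well must be >= 0")
        for name in ("nucleus_intensity", "droplet_intensity", "background_level", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("nucleus_radius_px", "droplet_radius_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.droplet_scatter_factor <= 3.0:
            raise ValueError("droplet_scatter_factor must be in (0, 3]")
        fracs = [
            self.baseline_percent_positive / 100.0,
            self.positive_control_responder_fraction,
            *self.death_by_compound.values(),
        ]
        for f in fracs:
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if not 0.0 <= self.baseline_percent_positive / 100.0 + self.hit_effect <= 1.0:
            raise ValueError("baseline + hit_effect must stay within [0, 1]")


@dataclass
class WellImage:
    """Two-channel intensity raster for one well."""

    well_label: str
    plate_id: str
    channels: dict[str, np.ndarray]
    bit_depth: int = 16

    def validate(self) -> None:
        if set(self.channels) != {CHANNEL_NUCLEAR, CHANNEL_LIPID}:
            raise ValueError(f"channels must be {{{CHANNEL_NUCLEAR}, {CHANNEL_LIPID}}}")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel shape mismatch: {shapes}")
        top = 2**self.bit_depth - 1
        for name, ch in self.channels.items():
            if ch.min() < 0 or ch.max() > top:
                raise ValueError(f"channel {name} outside [0, {top}]")


@dataclass
class Nucleus:
    """One segmented nucleus; lipid fields filled by the measurement pass."""

    label: int
    centroid: tuple[float, float]  # (row, col), 0-based pixels
    area_px: int
    mean_lipid_intensity: Optional[float] = None
    is_positive: Optional[bool] = None


@dataclass
class WellQuant:
    """Per-well readout: total cells, positive cells, percent positive."""

    plate_id: str
    replicate_id: int
    well_label: str
    role: str
    compound_id: Optional[str]
    total_cells: int
    positive_cells: int
    percent_positive: float
    low_cell_flag: bool = False

    def validate(self) -> None:
        if self.positive_cells > self.total_cells:
            raise ValueError("positive_cells > total_cells")
        if not 0.0 <= self.percent_positive <= 100.0:
            raise ValueError("percent_positive outside [0, 100]")


@dataclass
class PlateStats:
    """Per-plate location/scale summary of percent-positive over scoring wells."""

    plate_id: str
    replicate_id: int
    n_scoring_wells: int
    mean: float
    sd: float
    median: float
    mad: float
    scoring_scope: str


@dataclass
class ScoredWell:
    """WellQuant plus its robust Z score on the plate."""

    plate_id: str
    replicate_id: int
    well_label: str
    role: str
    compound_id: Optional[str]
    total_cells: int
    positive_cells: int
    percent_positive: float
    low_cell_flag: bool
    z: float


@dataclass
class CompoundResult:
    """Cross-replicate verdict for one compound."""

    compound_id: str
    z_by_replicate: dict[int, float]
    avg_z: float
    death_fraction_by_replicate: dict[int, float]
    max_death_fraction: float
    is_hit: bool
    is_excluded: bool
    insufficient_replicates: bool = False
    rank: Optional[int] = None
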