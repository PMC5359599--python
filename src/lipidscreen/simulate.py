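"""Synthetic screen generator.

Produces plate layouts, per-well ground truth, rendered two-channel well
images, and a fast summary-level path that draws per-well counts directly
from the binomial model the readout implies.  Every operation is a pure
function of its inputs and the configured seed.
"""

from __future__ import annotations

import zlib
from pathlib import Path
from typing import Optional

import numpy as np

from .models import (
    CHANNEL_LIPID,
    CHANNEL_NUCLEAR,
    ROLE_COMPOUND,
    ROLE_EMPTY,
    ROLE_NEGATIVE,
    ROLE_POSITIVE,
    CellRecord,
    PlateLayout,
    SimulationConfig,
    Well,
    WellImage,
    WellQuant,
    WellTruth,
    well_label,
)

_MIN_CONTROLS_PER_ROLE = 4
_PLACEMENT_RETRY_FACTOR = 50  # total retries = factor * n_cells

# Stream tags keep the truth, summary and rendering draws independent.
_STREAM_TRUTH = 1
_STREAM_RENDER = 2
_STREAM_SUMMARY = 3


def full_scale() -> SimulationConfig:
    """Config preset at the assay's plating density: 1500 cells/well.

    Images grow to 2048x2048 px to keep the cell density (and therefore the
    overlap-free placement feasibility) comparable to the 300-cell default.
    """
    return SimulationConfig(cells_per_well=1500, image_size=(2048, 2048))


def default_compound_ids(n: int) -> list[str]:
    return [f"C{i + 1:04d}" for i in range(n)]


def generate_plate_layout(
    n_compounds: int,
    controls_per_role: int,
    plate_id: str = "P1",
    replicate_id: int = 1,
    seed: int = 0,
    n_rows: int = 16,
    n_cols: int = 24,
    compound_ids: Optional[list[str]] = None,
) -> PlateLayout:
    """Assign compounds, controls and empties to wells by seeded shuffle.

    Replicate plates are generated independently: call again with a
    different ``seed``/``replicate_id`` and the same ``compound_ids``.
    """
    if controls_per_role < _MIN_CONTROLS_PER_ROLE:
        raise ValueError(
            f"controls_per_role={controls_per_role} below minimum {_MIN_CONTROLS_PER_ROLE}"
        )
    capacity = n_rows * n_cols
    needed = n_compounds + 2 * controls_per_role
    if needed > capacity:
        raise ValueError(
            f"cannot place {n_compounds} compounds + 2x{controls_per_role} controls "
            f"({needed} wells) on a {n_rows}x{n_cols} plate ({capacity} wells)"
        )
    if compound_ids is None:
        compound_ids = default_compound_ids(n_compounds)
    if len(compound_ids) != n_compounds:
        raise ValueError("compound_ids length must equal n_compounds")

    labels = [well_label(r, c) for r in range(n_rows) for c in range(n_cols)]
    rng = np.random.default_rng(seed)
    order = rng.permutation(capacity)

    wells: dict[str, Well] = {}
    pos = 0
    for cid in compound_ids:
        wells[labels[order[pos]]] = Well(labels[order[pos]], ROLE_COMPOUND, cid)
        pos += 1
    for _ in range(controls_per_role):
        wells[labels[order[pos]]] = Well(labels[order[pos]], ROLE_NEGATIVE)
        pos += 1
    for _ in range(controls_per_role):
        wells[labels[order[pos]]] = Well(labels[order[pos]], ROLE_POSITIVE)
        pos += 1
    ordered = [wells.get(lab, Well(lab, ROLE_EMPTY)) for lab in labels]

    layout = PlateLayout(plate_id, replicate_id, n_rows, n_cols, ordered)
    layout.validate()
    return layout


def true_well_parameters(well: Well, config: SimulationConfig) -> Optional[tuple[float, float]]:
    """(responder_fraction, death_fraction) implied by a well's role, or None for empty."""
    baseline = config.baseline_percent_positive / 100.0
    if well.role == ROLE_NEGATIVE:
        return baseline, 0.0
    if well.role == ROLE_POSITIVE:
        return config.positive_control_responder_fraction, 0.0
    if well.role == ROLE_COMPOUND:
        p = baseline
        if well.compound_id in config.planted_hits:
            p = baseline + config.hit_effect
        d = config.death_by_compound.get(well.compound_id, 0.0)
        return p, d
    return None


def _rng_for(config: SimulationConfig, layout: PlateLayout, stream: int) -> np.random.Generator:
    plate_tag = zlib.crc32(layout.plate_id.encode())
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, layout.replicate_id, plate_tag, stream])
    )


def _place_cells(
    n: int, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Uniform cell centres with pairwise distance >= 2 x nucleus radius.

    Rejection sampling with a bounded retry budget; the margin keeps each
    nucleus and its droplet halo inside the frame.
    """
    h, w = config.image_size
    margin = 3.0 * config.nucleus_radius_px + config.droplet_radius_px + 1.0
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise ValueError("image too small for the configured nucleus radius")
    min_d2 = (2.0 * config.nucleus_radius_px) ** 2
    placed = np.empty((n, 2))
    budget = _PLACEMENT_RETRY_FACTOR * max(n, 1)
    k = 0
    while k < n:
        if budget <= 0:
            raise RuntimeError(
                f"could not place {n} cells without overlap; lower cells_per_well "
                "or enlarge image_size"
            )
        budget -= 1
        cand = np.array([rng.uniform(margin, w - margin), rng.uniform(margin, h - margin)])
        if k == 0 or np.min(np.sum((placed[:k] - cand) ** 2, axis=1)) >= min_d2:
            placed[k] = cand
            k += 1
    return placed


def simulate_well_truth(
    layout: PlateLayout, config: SimulationConfig
) -> dict[str, WellTruth]:
    """Draw per-cell ground truth for every non-empty well of a plate.

    Surviving cells = round(seeded x (1 - death)); each surviving cell is a
    responder with probability p_true; droplet counts are Poisson with the
    responder/background mean.  Responders always carry at least one droplet
    so that a noise-free image faithfully encodes the truth.
    """
    layout.validate()
    config.validate()
    rng = _rng_for(config, layout, _STREAM_TRUTH)
    truths: dict[str, WellTruth] = {}
    for well in layout.wells:
        params = true_well_parameters(well, config)
        if params is None:
            continue
        p_true, d_true = params
        n_surv = int(round(config.cells_per_well * (1.0 - d_true)))
        xy = _place_cells(n_surv, config, rng)
        is_resp = rng.random(n_surv) < p_true
        counts = np.where(
            is_resp,
            rng.poisson(config.droplet_count_responder, n_surv),
            rng.poisson(config.droplet_count_background, n_surv),
        )
        counts = np.where(is_resp & (counts == 0), 1, counts)
        cells = [
            CellRecord(x=float(x), y=float(y), is_responder=bool(r), n_droplets=int(c))
            for (x, y), r, c in zip(xy, is_resp, counts)
        ]
        truths[well.label] = WellTruth(
            well_label=well.label,
            n_cells_seeded=config.cells_per_well,
            death_fraction=d_true,
            responder_fraction=p_true,
            cells=cells,
        )
    return truths


def _add_spot(img: np.ndarray, cy: float, cx: float, radius: float, peak: float) -> None:
    """Add a radially symmetric parabolic bump with compact support r < radius."""
    h, w = img.shape
    y0 = max(int(np.floor(cy - radius)), 0)
    y1 = min(int(np.ceil(cy + radius)) + 1, h)
    x0 = max(int(np.floor(cx - radius)), 0)
    x1 = min(int(np.ceil(cx + radius)) + 1, w)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    mask = r2 < radius**2
    img[y0:y1, x0:x1][mask] += peak * (1.0 - r2[mask] / radius**2)


def render_well_image(
    truth: WellTruth,
    config: SimulationConfig,
    plate_id: str = "P1",
    replicate_id: int = 1,
) -> WellImage:
    """Render ground truth into a two-channel 16-bit well image.

    Channel 1 (nuclear): one bright spot per surviving cell.  Channel 2
    (lipid): the cell's droplets, placed uniformly within
    ``droplet_scatter_factor`` nucleus radii of its centre (default 0.6, a
    tight juxtanuclear cluster; at most 3, the perinuclear halo).  The tight
    default keeps every droplet inside its owner's measured perinuclear
    region, so a noise-free image encodes the truth exactly.  Both channels
    get the flat background, optional linear illumination gradient, and
    additive Gaussian noise, then are clipped to [0, 65535].
    """
    config.validate()
    h, w = config.image_size
    plate_tag = zlib.crc32(plate_id.encode())
    well_tag = zlib.crc32(truth.well_label.encode())
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, replicate_id, plate_tag, well_tag, _STREAM_RENDER])
    )

    nuclear = np.full((h, w), float(config.background_level))
    lipid = np.full((h, w), float(config.background_level))
    if config.illumination_gradient:
        ramp = config.background_level * config.illumination_gradient
        grad = np.linspace(-ramp / 2, ramp / 2, w)[None, :]
        nuclear += grad
        lipid += grad

    R = config.nucleus_radius_px
    for cell in truth.cells:
        if not (0 <= cell.x < w and 0 <= cell.y < h):
            raise ValueError(f"cell at ({cell.x}, {cell.y}) outside image bounds")
        _add_spot(nuclear, cell.y, cell.x, R, config.nucleus_intensity)
        r_max = config.droplet_scatter_factor * R
        for _ in range(cell.n_droplets):
            rad = r_max * np.sqrt(rng.random())
            theta = rng.uniform(0.0, 2.0 * np.pi)
            dy, dx = rad * np.sin(theta), rad * np.cos(theta)
            _add_spot(
                lipid, cell.y + dy, cell.x + dx, config.droplet_radius_px, config.droplet_intensity
            )

    if config.noise_sd > 0:
        nuclear += rng.normal(0.0, config.noise_sd, size=(h, w))
        lipid += rng.normal(0.0, config.noise_sd, size=(h, w))

    channels = {
        CHANNEL_NUCLEAR: np.clip(np.rint(nuclear), 0, 65535).astype(np.uint16),
        CHANNEL_LIPID: np.clip(np.rint(lipid), 0, 65535).astype(np.uint16),
    }
    image = WellImage(well_label=truth.well_label, plate_id=plate_id, channels=channels)
    image.validate()
    return image


def simulate_summary_plate(
    layout: PlateLayout, config: SimulationConfig
) -> list[WellQuant]:
    """Fast image-free path: draw the per-well readout from its count model.

    Surviving n ~ Binomial(cells_per_well, 1 - d_true), positive
    k ~ Binomial(n, p_true), percent positive = 100 k / n (zero, flagged,
    when no cells survive).
    """
    layout.validate()
    config.validate()
    rng = _rng_for(config, layout, _STREAM_SUMMARY)
    quants: list[WellQuant] = []
    for well in layout.wells:
        params = true_well_parameters(well, config)
        if params is None:
            continue
        p_true, d_true = params
        n = int(rng.binomial(config.cells_per_well, 1.0 - d_true))
        k = int(rng.binomial(n, p_true)) if n > 0 else 0
        quants.append(
            WellQuant(
                plate_id=layout.plate_id,
                replicate_id=layout.replicate_id,
                well_label=well.label,
                role=well.role,
                compound_id=well.compound_id,
                total_cells=n,
                positive_cells=k,
                percent_positive=100.0 * k / n if n > 0 else 0.0,
                low_cell_flag=n == 0,
            )
        )
    return quants


def write_well_images(
    images: list[WellImage], out_dir: str | Path
) -> list[Path]:
    """Write each channel as ``<plate_id>_<well>_<hoechst|bodipy>.tiff`` (16-bit)."""
    import tifffile

    stain = {CHANNEL_NUCLEAR: "hoechst", CHANNEL_LIPID: "bodipy"}
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for img in images:
        for channel, arr in img.channels.items():
            path = out_dir / f"{img.plate_id}_{img.well_label}_{stain[channel]}.tiff"
            tifffile.imwrite(path, arr)
            written.append(path)
    return written


def replicate_layouts(
    n_compounds: int,
    controls_per_role: int,
    n_replicates: int = 2,
    seed: int = 0,
    plate_prefix: str = "P",
    n_rows: int = 16,
    n_cols: int = 24,
    compound_ids: Optional[list[str]] = None,
) -> list[PlateLayout]:
    """Independent replicate plates sharing one compound set."""
    if compound_ids is None:
        compound_ids = default_compound_ids(n_compounds)
    return [
        generate_plate_layout(
            n_compounds,
            controls_per_role,
            plate_id=f"{plate_prefix}{rep}",
            replicate_id=rep,
            seed=int(np.random.SeedSequence([seed, rep]).generate_state(1)[0] % (2**31)),
            n_rows=n_rows,
            n_cols=n_cols,
            compound_ids=compound_ids,
        )
        for rep in range(1, n_replicates + 1)
    ]
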