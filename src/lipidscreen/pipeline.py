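"""End-to-end screen runs: simulate/ingest -> quantify -> score -> call hits."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .hit_calling import call_hits
from .io import (
    RunConfig,
    read_plate_map,
    read_well_image,
    save_config,
    write_hit_tables,
    write_plate_map,
    write_plate_stats,
    write_quants,
    write_scored,
)
from .models import (
    ROLE_NEGATIVE,
    CompoundResult,
    PlateLayout,
    PlateStats,
    ScoredWell,
    WellQuant,
)
from .plate_stats import compute_plate_stats, score_plate
from .quantify import (
    calibrate_positivity_threshold,
    classify_well,
    measure_well,
)
from .simulate import (
    render_well_image,
    replicate_layouts,
    simulate_summary_plate,
    simulate_well_truth,
    write_well_images,
)

logger = logging.getLogger(__name__)


@dataclass
class ScreenResult:
    """Everything one run computed, ready to write or inspect."""

    layouts: list[PlateLayout]
    quants: list[WellQuant]
    stats_by_plate: dict[tuple[str, int], PlateStats]
    scored: list[ScoredWell]
    results: list[CompoundResult]
    tau_by_plate: dict[tuple[str, int], float] = field(default_factory=dict)

    @property
    def hits(self) -> list[CompoundResult]:
        return sorted((r for r in self.results if r.is_hit), key=lambda r: r.rank)


def _quantify_plate_images(
    layout: PlateLayout, config: RunConfig, images_dir: Optional[Path]
) -> tuple[list[WellQuant], float]:
    """Render (or load) every well image of one plate and quantify it.

    The positivity threshold is calibrated per plate from that plate's own
    pooled negative-control cells.
    """
    sim = config.simulation
    truths = None
    if images_dir is None:
        truths = simulate_well_truth(layout, sim)

    measured = {}
    for well in layout.wells:
        if well.role == "empty":
            continue
        if images_dir is None:
            image = render_well_image(
                truths[well.label], sim, plate_id=layout.plate_id, replicate_id=layout.replicate_id
            )
        else:
            image = read_well_image(images_dir, layout.plate_id, well.label)
        nuclei = measure_well(image, config.quant)
        measured[well.label] = (well, image, nuclei)
        if config.write_images and images_dir is None and config.output_dir:
            write_well_images([image], Path(config.output_dir) / "images")

    neg_intensities = [
        n.mean_lipid_intensity
        for well, _, nuclei in measured.values()
        if well.role == ROLE_NEGATIVE
        for n in nuclei
    ]
    tau = calibrate_positivity_threshold(neg_intensities, k=config.quant.positivity_k)
    logger.info(
        "plate %s rep %d: tau=%.3f from %d negative-control cells",
        layout.plate_id,
        layout.replicate_id,
        tau,
        len(neg_intensities),
    )

    quants = [
        classify_well(
            image,
            nuclei,
            tau,
            replicate_id=layout.replicate_id,
            role=well.role,
            compound_id=well.compound_id,
        )
        for well, image, nuclei in measured.values()
    ]
    return quants, tau


def run_screen(config: RunConfig) -> ScreenResult:
    """Execute one full screen per the configuration and return all tables."""
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    config = dataclasses.replace(config, simulation=sim)

    if config.plate_map:
        layouts = read_plate_map(
            config.plate_map, n_rows=config.screen.n_rows, n_cols=config.screen.n_cols
        )
    else:
        layouts = replicate_layouts(
            config.screen.n_compounds,
            config.screen.controls_per_role,
            n_replicates=config.screen.n_replicates,
            seed=config.seed,
            n_rows=config.screen.n_rows,
            n_cols=config.screen.n_cols,
        )

    quants: list[WellQuant] = []
    tau_by_plate: dict[tuple[str, int], float] = {}
    for layout in layouts:
        if config.mode == "summary":
            plate_quants = simulate_summary_plate(layout, sim)
        elif config.mode == "image":
            images_dir = Path(config.images_dir) if config.images_dir else None
            plate_quants, tau = _quantify_plate_images(layout, config, images_dir)
            tau_by_plate[(layout.plate_id, layout.replicate_id)] = tau
        else:
            raise ValueError(f"unknown mode {config.mode!r}")
        quants.extend(plate_quants)
        logger.info(
            "plate %s rep %d: quantified %d wells", layout.plate_id, layout.replicate_id, len(plate_quants)
        )

    stats_by_plate: dict[tuple[str, int], PlateStats] = {}
    scored: list[ScoredWell] = []
    for layout in layouts:
        key = (layout.plate_id, layout.replicate_id)
        plate_quants = [q for q in quants if (q.plate_id, q.replicate_id) == key]
        st = compute_plate_stats(
            plate_quants,
            scope=config.stats.scope,
            min_scoring_wells=config.stats.min_scoring_wells,
        )
        stats_by_plate[key] = st
        scored.extend(score_plate(plate_quants, st, mad_zero=config.stats.mad_zero))

    results = call_hits(
        scored,
        z_threshold=config.hits.z_threshold,
        min_replicates=config.hits.min_replicates,
        death_cutoff=config.hits.death_cutoff,
    )
    n_hits = sum(r.is_hit for r in results)
    logger.info("called %d hits among %d compounds", n_hits, len(results))
    return ScreenResult(
        layouts=layouts,
        quants=quants,
        stats_by_plate=stats_by_plate,
        scored=scored,
        results=results,
        tau_by_plate=tau_by_plate,
    )


def write_outputs(result: ScreenResult, config: RunConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write the five output tables plus the resolved config."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "plate_map": out_dir / "plate_map.csv",
        "quants": out_dir / "quants.csv",
        "plate_stats": out_dir / "plate_stats.csv",
        "scored": out_dir / "scored.csv",
        "config": out_dir / "resolved_config.yaml",
    }
    write_plate_map(result.layouts, paths["plate_map"])
    write_quants(result.quants, paths["quants"])
    write_plate_stats(list(result.stats_by_plate.values()), paths["plate_stats"])
    write_scored(result.scored, result.stats_by_plate, paths["scored"])
    paths["hits"], paths["all_compounds"] = write_hit_tables(result.results, out_dir)
    save_config(config, paths["config"])
    return paths
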