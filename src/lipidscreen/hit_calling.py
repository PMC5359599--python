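"""Replicate-consensus hit calling with a cell-death exclusion.

A compound is a hit when its MAD-based Z score strictly exceeds the
threshold (default 5) in at least ``min_replicates`` replicate plates
(default 2) and its associated cell death never strictly exceeds the
exclusion cutoff (default 60%) in any replicate.  Hits are ranked by
average Z over all replicates, sub-threshold replicates included.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .models import (
    ROLE_COMPOUND,
    ROLE_NEGATIVE,
    CompoundResult,
    ScoredWell,
    WellQuant,
)

Z_THRESHOLD = 5.0
MIN_REPLICATES = 2
DEATH_CUTOFF = 0.60
_MIN_DEATH_CONTROLS = 4


def estimate_cell_death(
    quant: WellQuant | ScoredWell,
    negative_controls: Sequence[WellQuant | ScoredWell],
    min_controls: int = _MIN_DEATH_CONTROLS,
) -> float:
    """Cell-death fraction of a well relative to its plate's DMSO wells.

    d = clamp(1 - total_cells / median(negative-control total_cells), 0, 1).
    Negative-control wells with zero cells are unusable and dropped.
    """
    totals = [q.total_cells for q in negative_controls if q.total_cells > 0]
    if len(totals) < min_controls:
        raise ValueError(
            f"need >= {min_controls} usable negative-control wells, got {len(totals)}"
        )
    reference = float(np.median(totals))
    return float(np.clip(1.0 - quant.total_cells / reference, 0.0, 1.0))


def call_hits(
    scored: Sequence[ScoredWell],
    z_threshold: float = Z_THRESHOLD,
    min_replicates: int = MIN_REPLICATES,
    death_cutoff: float = DEATH_CUTOFF,
    min_death_controls: int = _MIN_DEATH_CONTROLS,
) -> list[CompoundResult]:
    """Apply the hit rule across replicate plates.

    ``scored`` holds every scored well from every replicate, controls
    included (negative controls are needed as the death reference).
    Compounds seen in fewer than ``min_replicates`` replicates are flagged
    ``insufficient_replicates`` and can never be hits.  Both comparisons are
    strict: Z must exceed ``z_threshold``, death must exceed
    ``death_cutoff``, to flip the respective flag.
    """
    neg_by_plate: dict[tuple[str, int], list[ScoredWell]] = defaultdict(list)
    for sw in scored:
        if sw.role == ROLE_NEGATIVE:
            neg_by_plate[(sw.plate_id, sw.replicate_id)].append(sw)

    by_compound: dict[str, dict[int, ScoredWell]] = defaultdict(dict)
    for sw in scored:
        if sw.role != ROLE_COMPOUND:
            continue
        if sw.replicate_id in by_compound[sw.compound_id]:
            raise ValueError(
                f"compound {sw.compound_id} appears twice in replicate {sw.replicate_id}"
            )
        by_compound[sw.compound_id][sw.replicate_id] = sw

    results: list[CompoundResult] = []
    for cid in sorted(by_compound):
        reps = by_compound[cid]
        z_by_rep = {rep: sw.z for rep, sw in sorted(reps.items())}
        death_by_rep = {
            rep: estimate_cell_death(
                sw, neg_by_plate[(sw.plate_id, sw.replicate_id)], min_controls=min_death_controls
            )
            for rep, sw in sorted(reps.items())
        }
        max_death = max(death_by_rep.values())
        insufficient = len(reps) < min_replicates
        excluded = max_death > death_cutoff
        n_over = sum(z > z_threshold for z in z_by_rep.values())
        is_hit = (not insufficient) and (not excluded) and n_over >= min_replicates
        results.append(
            CompoundResult(
                compound_id=cid,
                z_by_replicate=z_by_rep,
                avg_z=float(np.mean(list(z_by_rep.values()))),
                death_fraction_by_replicate=death_by_rep,
                max_death_fraction=max_death,
                is_hit=is_hit,
                is_excluded=excluded,
                insufficient_replicates=insufficient,
            )
        )

    # Rank hits by decreasing average Z; ties break lexicographically.
    hits = sorted(
        (r for r in results if r.is_hit), key=lambda r: (-r.avg_z, r.compound_id)
    )
    for rank, r in enumerate(hits, start=1):
        r.rank = rank
    return results


def hit_report(
    results: Sequence[CompoundResult],
    annotations: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Ranked hit table: compound, average MAD-based Z, optional annotation."""
    hits = sorted((r for r in results if r.is_hit), key=lambda r: r.rank)
    rows = [
        {
            "rank": r.rank,
            "compound_id": r.compound_id,
            "avg_z": r.avg_z,
            "annotation": (annotations or {}).get(r.compound_id, ""),
        }
        for r in hits
    ]
    return pd.DataFrame(rows, columns=["rank", "compound_id", "avg_z", "annotation"])


def compound_table(results: Sequence[CompoundResult]) -> pd.DataFrame:
    """Companion table with every compound's scores and flags."""
    replicate_ids = sorted({rep for r in results for rep in r.z_by_replicate})
    rows = []
    for r in sorted(results, key=lambda r: (-r.avg_z, r.compound_id)):
        row: dict = {"compound_id": r.compound_id, "avg_z": r.avg_z}
        for rep in replicate_ids:
            row[f"z_rep{rep}"] = r.z_by_replicate.get(rep, np.nan)
        row.update(
            max_death_fraction=r.max_death_fraction,
            is_hit=r.is_hit,
            is_excluded=r.is_excluded,
            insufficient_replicates=r.insufficient_replicates,
            rank=r.rank if r.rank is not None else pd.NA,
        )
        rows.append(row)
    return pd.DataFrame(rows)
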