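"""Per-plate robust statistics and the MAD-based Z score.

The per-well statistic x is the percentage of lipid-positive cells.  Each
plate is summarized by the mean, sample SD, median m and MAD of x over its
scoring wells, and every well is scored as

    z = (x - m) / (MAD * 1.4826)

where 1.4826 makes the MAD a consistent estimator of the standard
deviation under normality.  Scoring wells default to compound wells only,
so that strong positive controls cannot inflate the plate's scale estimate;
``scope="all_non_empty"`` includes controls instead.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .models import ROLE_COMPOUND, ROLE_EMPTY, PlateStats, ScoredWell, WellQuant

logger = logging.getLogger(__name__)

#: Consistency factor relating the MAD to the Gaussian standard deviation.
MAD_SCALE = 1.4826

SCOPE_COMPOUND_ONLY = "compound_only"
SCOPE_ALL_NON_EMPTY = "all_non_empty"

#: Default minimum number of scoring wells for a meaningful scale estimate.
MIN_SCORING_WELLS = 8


def mad(values: Sequence[float]) -> float:
    """Median absolute deviation: median(|x - median(x)|), unscaled.

    The median of an even-length sample is the midpoint of the two central
    order statistics.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("mad() of an empty sequence")
    return float(np.median(np.abs(arr - np.median(arr))))


def _scoring_values(quants: Sequence[WellQuant], scope: str) -> list[float]:
    if scope == SCOPE_COMPOUND_ONLY:
        pool = [q for q in quants if q.role == ROLE_COMPOUND]
    elif scope == SCOPE_ALL_NON_EMPTY:
        pool = [q for q in quants if q.role != ROLE_EMPTY]
    else:
        raise ValueError(
            f"unknown scope {scope!r}; expected {SCOPE_COMPOUND_ONLY!r} or {SCOPE_ALL_NON_EMPTY!r}"
        )
    return [q.percent_positive for q in pool if not q.low_cell_flag]


def compute_plate_stats(
    quants: Sequence[WellQuant],
    scope: str = SCOPE_COMPOUND_ONLY,
    min_scoring_wells: int = MIN_SCORING_WELLS,
) -> PlateStats:
    """Mean, sample SD, median and MAD of percent positive over scoring wells."""
    plates = {(q.plate_id, q.replicate_id) for q in quants}
    if len(plates) != 1:
        raise ValueError(f"quants must come from a single plate, got {sorted(plates)}")
    ((plate_id, replicate_id),) = plates
    x = _scoring_values(quants, scope)
    if len(x) < min_scoring_wells:
        raise ValueError(
            f"plate {plate_id}: only {len(x)} scoring wells "
            f"(floor {min_scoring_wells}) under scope {scope!r}"
        )
    arr = np.asarray(x, dtype=float)
    return PlateStats(
        plate_id=plate_id,
        replicate_id=replicate_id,
        n_scoring_wells=len(x),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
        median=float(np.median(arr)),
        mad=mad(arr),
        scoring_scope=scope,
    )


def robust_z(x: float, stats: PlateStats, mad_zero: str = "raise") -> float:
    """MAD-based Z score of a percent-positive value against its plate.

    ``mad_zero`` controls the degenerate-plate policy: ``"raise"`` (default)
    errors out, ``"sd_fallback"`` scores (x - mean)/sd with a warning.
    """
    if stats.mad > 0:
        return (x - stats.median) / (stats.mad * MAD_SCALE)
    if mad_zero == "sd_fallback":
        if stats.sd == 0:
            raise ZeroDivisionError(
                f"plate {stats.plate_id}: MAD and SD both zero; cannot score"
            )
        logger.warning(
            "plate %s: MAD is 0, falling back to (x - mean)/sd", stats.plate_id
        )
        return (x - stats.mean) / stats.sd
    raise ZeroDivisionError(
        f"plate {stats.plate_id}: MAD is 0 (degenerate plate); "
        "set mad_zero='sd_fallback' to score anyway"
    )


def score_plate(
    quants: Sequence[WellQuant], stats: PlateStats, mad_zero: str = "raise"
) -> list[ScoredWell]:
    """Attach a robust Z to every non-empty well (controls included).

    Controls are scored for inspection but are never hit-eligible
    downstream.
    """
    scored = []
    for q in quants:
        if q.role == ROLE_EMPTY:
            continue
        if (q.plate_id, q.replicate_id) != (stats.plate_id, stats.replicate_id):
            raise ValueError("stats were computed from a different plate")
        scored.append(
            ScoredWell(
                plate_id=q.plate_id,
                replicate_id=q.replicate_id,
                well_label=q.well_label,
                role=q.role,
                compound_id=q.compound_id,
                total_cells=q.total_cells,
                positive_cells=q.positive_cells,
                percent_positive=q.percent_positive,
                low_cell_flag=q.low_cell_flag,
                z=robust_z(q.percent_positive, stats, mad_zero=mad_zero),
            )
        )
    return scored
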