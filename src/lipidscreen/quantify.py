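"""Per-well image quantification.

Turns a two-channel well image into the screen readout: total cell count
(nuclear-stain positive objects) and positive cell count (objects whose
perinuclear lipid signal exceeds a threshold calibrated on negative-control
wells).  Segmentation is deliberately simple and deterministic: Gaussian
smoothing, a global threshold (Otsu by default), 8-connected components,
and an area filter.  Touching nuclei are not split; the synthetic
generator's overlap-free placement makes that sound on simulated data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from skimage import filters, measure, segmentation

from .models import CHANNEL_LIPID, CHANNEL_NUCLEAR, Nucleus, WellImage, WellQuant
from .plate_stats import mad

logger = logging.getLogger(__name__)


@dataclass
class QuantParams:
    """Segmentation and measurement parameters.

    ``threshold`` is ``"otsu"`` or a fixed intensity; areas are in pixels;
    ``dilation_radius_px`` grows each nucleus mask into the perinuclear
    region where cytoplasmic lipid droplets sit.
    """

    sigma: float = 1.0
    threshold: Union[str, float] = "otsu"
    min_area: int = 8
    max_area: int = 2000
    dilation_radius_px: int = 3
    positivity_k: float = 3.0
    split_touching: bool = False  # watershed split; off by default, for real images


def segment_nuclei(
    nuclear_channel: np.ndarray, params: Optional[QuantParams] = None
) -> list[Nucleus]:
    """Segment nuclei from the DNA-stain channel; lipid fields left unset."""
    nuclei, _ = _segment_labeled(nuclear_channel, params or QuantParams())
    return nuclei


def _segment_labeled(
    nuclear_channel: np.ndarray, params: QuantParams
) -> tuple[list[Nucleus], np.ndarray]:
    if nuclear_channel.size == 0:
        raise ValueError("empty nuclear channel")
    img = nuclear_channel.astype(float)
    smoothed = filters.gaussian(img, sigma=params.sigma, preserve_range=True)
    if isinstance(params.threshold, str):
        if params.threshold != "otsu":
            raise ValueError(f"unknown threshold method {params.threshold!r}")
        if np.ptp(smoothed) == 0:
            logger.warning("constant image: Otsu undefined, returning no nuclei")
            return [], np.zeros(img.shape, dtype=int)
        thr = filters.threshold_otsu(smoothed)
    else:
        thr = float(params.threshold)
    binary = smoothed > thr
    if params.split_touching:
        labeled = _watershed_split(binary)
    else:
        labeled = measure.label(binary, connectivity=2)
    nuclei: list[Nucleus] = []
    keep = np.zeros(labeled.max() + 1, dtype=bool)
    for region in measure.regionprops(labeled):
        if params.min_area <= region.area <= params.max_area:
            keep[region.label] = True
            nuclei.append(
                Nucleus(
                    label=region.label,
                    centroid=(float(region.centroid[0]), float(region.centroid[1])),
                    area_px=int(region.area),
                )
            )
    labeled[~keep[labeled]] = 0
    return nuclei, labeled


def _watershed_split(binary: np.ndarray) -> np.ndarray:
    """Split touching nuclei by watershed on the distance transform."""
    from scipy import ndimage
    from skimage.feature import peak_local_max
    from skimage.segmentation import watershed

    distance = ndimage.distance_transform_edt(binary)
    peaks = peak_local_max(distance, min_distance=3, labels=binary)
    markers = np.zeros_like(binary, dtype=int)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    return watershed(-distance, markers, mask=binary)


def measure_well(image: WellImage, params: Optional[QuantParams] = None) -> list[Nucleus]:
    """Segment nuclei and measure each one's perinuclear mean lipid intensity.

    The perinuclear region is the nucleus mask expanded by
    ``dilation_radius_px``; where expansions compete, each pixel goes to the
    nearest nucleus, so no lipid pixel is counted toward two cells.
    """
    params = params or QuantParams()
    image.validate()
    nuclear = image.channels[CHANNEL_NUCLEAR]
    lipid = image.channels[CHANNEL_LIPID].astype(float)
    nuclei, labeled = _segment_labeled(nuclear, params)
    expanded = segmentation.expand_labels(labeled, distance=params.dilation_radius_px)
    means = {
        region.label: float(region.intensity_mean)
        for region in measure.regionprops(expanded, intensity_image=lipid)
    }
    for nuc in nuclei:
        nuc.mean_lipid_intensity = means[nuc.label]
    return nuclei


def calibrate_positivity_threshold(
    negative_control_intensities: Sequence[float],
    k: float = 3.0,
    min_cells: int = 50,
) -> float:
    """Positivity threshold from pooled negative-control per-cell intensities.

    tau = median + k * MAD.  When the controls are perfectly uniform
    (MAD = 0, as in idealized noise-free simulations) tau degrades to the
    median and a warning is logged; positivity remains a strict ``>`` test,
    so uniform-background cells are still counted negative.
    """
    vals = np.asarray(list(negative_control_intensities), dtype=float)
    if vals.size < min_cells:
        raise ValueError(
            f"need >= {min_cells} pooled negative-control cells, got {vals.size}"
        )
    med = float(np.median(vals))
    scale = mad(vals)
    if scale == 0:
        logger.warning("negative-control MAD is 0; threshold degrades to the median")
    return med + k * scale


def quantify_well(
    image: WellImage,
    tau: float,
    params: Optional[QuantParams] = None,
    replicate_id: int = 1,
    role: str = "compound",
    compound_id: Optional[str] = None,
) -> WellQuant:
    """Full per-well readout at positivity threshold ``tau``."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    nuclei = measure_well(image, params)
    return classify_well(
        image, nuclei, tau, replicate_id=replicate_id, role=role, compound_id=compound_id
    )


def classify_well(
    image: WellImage,
    nuclei: list[Nucleus],
    tau: float,
    replicate_id: int = 1,
    role: str = "compound",
    compound_id: Optional[str] = None,
) -> WellQuant:
    """Apply a positivity threshold to already-measured nuclei."""
    for nuc in nuclei:
        nuc.is_positive = nuc.mean_lipid_intensity is not None and nuc.mean_lipid_intensity > tau
    total = len(nuclei)
    positive = sum(bool(n.is_positive) for n in nuclei)
    quant = WellQuant(
        plate_id=image.plate_id,
        replicate_id=replicate_id,
        well_label=image.well_label,
        role=role,
        compound_id=compound_id,
        total_cells=total,
        positive_cells=positive,
        percent_positive=100.0 * positive / total if total > 0 else 0.0,
        low_cell_flag=total == 0,
    )
    quant.validate()
    return quant
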