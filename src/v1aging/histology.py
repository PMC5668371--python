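"""Quantification of double-label histology and western blots.

Mirrors the image-analysis workflow used for GABAergic-marker
quantification: threshold-plus-area-filter cell segmentation, centroid
matching of double-labelled cells across channels, per-AOI counting and
density calculation, the per-layer density/proportion table that feeds the
age x layer ANOVA, mean fluorescence intensity over randomly placed AOIs,
and blot optical-density normalization to GAPDH.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage import measure

from .synthetic import AoiPoints, BlotLane

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectedObject:
    """One segmented cell: centroid in calibrated um, area in um^2."""

    x_um: float
    y_um: float
    area_um2: float
    mean_intensity: float
    channel: int = 0


def segment_cells(
    channel_image: np.ndarray,
    intensity_threshold: float,
    area_min_um2: float = 10.0,
    area_max_um2: float = 500.0,
    pixel_size_um: float = 1.0,
    channel: int = 0,
) -> list[DetectedObject]:
    """Connected-component segmentation with an area filter.

    Pixels above ``intensity_threshold`` are labelled; components whose
    calibrated area falls outside [area_min, area_max] um^2 are discarded.
    Centroids are returned in um.  A blank (nothing above threshold) image
    yields an empty list with a warning.
    """
    img = np.asarray(channel_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("segment_cells expects a single-channel 2-D image")
    if area_min_um2 >= area_max_um2:
        raise ValueError("area_min_um2 must be below area_max_um2")
    mask = img > intensity_threshold
    if not mask.any():
        logger.warning("no pixels above threshold: blank or saturated image?")
        return []
    labels = measure.label(mask, connectivity=2)
    px_area = pixel_size_um**2
    out = []
    for region in measure.regionprops(labels, intensity_image=img):
        area = region.area * px_area
        if not (area_min_um2 <= area <= area_max_um2):
            continue
        cy, cx = region.centroid
        out.append(
            DetectedObject(
                x_um=cx * pixel_size_um,
                y_um=cy * pixel_size_um,
                area_um2=float(area),
                mean_intensity=float(region.intensity_mean),
                channel=channel,
            )
        )
    return out


def match_double_label(
    objects_a: list[DetectedObject],
    objects_b: list[DetectedObject],
    max_dist_um: float = 5.0,
) -> list[tuple[int, int]]:
    """Greedy nearest-neighbour matching of centroids across two channels.

    Candidate pairs within the distance cap are accepted in order of
    increasing distance; each object participates in at most one pair.
    Returns (index_a, index_b) pairs.
    """
    if not objects_a or not objects_b:
        return []
    xa = np.array([[o.x_um, o.y_um] for o in objects_a])
    xb = np.array([[o.x_um, o.y_um] for o in objects_b])
    tree = cKDTree(xb)
    pairs = tree.query_ball_point(xa, r=max_dist_um)
    candidates = [
        (float(np.hypot(*(xa[i] - xb[j]))), i, j)
        for i, js in enumerate(pairs)
        for j in js
    ]
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched = []
    for _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched.append((i, j))
    return matched


def count_aoi(
    xy_um: np.ndarray,
    aoi_origin_um: tuple[float, float],
    aoi_side_um: float,
) -> tuple[int, float]:
    """Count centroids inside a square AOI and convert to cells/mm^2.

    The left/top edges are inclusive and the right/bottom edges exclusive,
    so AOIs tiling a section count every cell exactly once.
    """
    if aoi_side_um <= 0:
        raise ValueError("AOI side must be positive")
    xy = np.asarray(xy_um, dtype=float).reshape(-1, 2)
    x0, y0 = aoi_origin_um
    inside = (
        (xy[:, 0] >= x0)
        & (xy[:, 0] < x0 + aoi_side_um)
        & (xy[:, 1] >= y0)
        & (xy[:, 1] < y0 + aoi_side_um)
    )
    count = int(np.count_nonzero(inside))
    area_mm2 = (aoi_side_um / 1000.0) ** 2
    return count, count / area_mm2


def aoi_counts_from_map(aois: list[AoiPoints]) -> pd.DataFrame:
    """Exact per-AOI NeuN/GABA counts and densities from planted points."""
    rows = []
    for aoi in aois:
        neun, neun_density = count_aoi(aoi.xy_um, (0.0, 0.0), aoi.side_um)
        gaba = int(np.count_nonzero(aoi.gaba))
        rows.append(
            {
                "layer": aoi.layer,
                "aoi": aoi.index,
                "neun_count": neun,
                "gaba_count": gaba,
                "neun_density": neun_density,
                "gaba_density": gaba / aoi.area_mm2,
            }
        )
    return pd.DataFrame(rows)


def layer_density_table(per_aoi: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(group, layer) density and proportion summary from per-AOI counts.

    ``per_aoi`` needs columns group, layer, neun_density, gaba_density (and
    implicitly one row per AOI).  The per-AOI GABA/NeuN proportion is
    100 * gaba/neun; AOIs with zero NeuN count are excluded with a warning.
    Returns (summary table, per-AOI long table for the ANOVA).
    """
    df = per_aoi.copy()
    zero = df["neun_density"] == 0
    if zero.any():
        logger.warning("%d AOIs with zero NeuN count excluded from proportions",
                       int(zero.sum()))
        df = df[~zero]
    df["proportion_pct"] = 100.0 * df["gaba_density"] / df["neun_density"]
    if (df["gaba_density"] > df["neun_density"]).any():
        raise ValueError("GABA+ density exceeds total density in some AOI")
    summary = (
        df.groupby(["group", "layer"], sort=False)
        .agg(
            neun_mean=("neun_density", "mean"),
            neun_sd=("neun_density", lambda s: s.std(ddof=1)),
            gaba_mean=("gaba_density", "mean"),
            gaba_sd=("gaba_density", lambda s: s.std(ddof=1)),
            proportion_mean=("proportion_pct", "mean"),
            proportion_sd=("proportion_pct", lambda s: s.std(ddof=1)),
            n_aois=("proportion_pct", "size"),
        )
        .reset_index()
    )
    return summary, df


def fluorescence_intensity(
    image: np.ndarray,
    aois: list[tuple[float, float, float]],
    pixel_size_um: float = 1.0,
    background_mode: str = "lowest-decile",
    background_value: float = 0.0,
) -> float:
    """Background-corrected mean intensity over a set of AOIs.

    ``aois`` is a list of (x0_um, y0_um, side_um) squares.  Background is
    the mean of the lowest-decile pixels of the whole image (default) or a
    fixed constant; it is subtracted before averaging, and the result is
    the mean over AOIs of the per-AOI mean intensity, floored at 0.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expects a single-channel 2-D image")
    if not aois:
        raise ValueError("at least one AOI required")
    if background_mode == "lowest-decile":
        flat = np.sort(img.ravel())
        bg = float(flat[: max(len(flat) // 10, 1)].mean())
    elif background_mode == "fixed":
        bg = background_value
    else:
        raise ValueError("background_mode must be 'lowest-decile' or 'fixed'")
    means = []
    for x0, y0, side in aois:
        c0, c1 = int(round(x0 / pixel_size_um)), int(round((x0 + side) / pixel_size_um))
        r0, r1 = int(round(y0 / pixel_size_um)), int(round((y0 + side) / pixel_size_um))
        patch = img[r0:r1, c0:c1]
        if patch.size == 0:
            raise ValueError("AOI lies outside the image")
        means.append(patch.mean() - bg)
    value = float(np.mean(means))
    if value < 0:
        logger.warning("background exceeds signal: intensity clamped to 0")
        return 0.0
    return value


def blot_od_ratio(lane: BlotLane) -> float:
    """Optical density of the target band normalized to the GAPDH band."""
    if lane.target_od <= 0 or lane.gapdh_od <= 0:
        raise ValueError("band optical densities must be positive")
    return lane.target_od / lane.gapdh_od
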