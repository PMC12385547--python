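"""Cord ellipse fitting, angular FA profiling and tract-ROI extraction.

The cord outline on the FA/b0 maps is modelled as an ellipse fitted from
image moments of a cord mask.  A 600-point angular profile of FA sampled
along a scaled ellipse locates the posterior gray-matter horns (FA minima),
whose exit angles guide the lateral placement of the pyramidal-tract ROIs.
Six circular ROIs of 1.05 mm diameter (pyramidal tracts, dorsal columns,
anterior horns; left/right mirror pairs) yield left/right-averaged mean
metrics per region.

Angle convention: 0 deg at the posterior midline, increasing toward the
anatomical left (+x); left/right pairs sit at +theta / -theta.  Coordinates
are continuous mm with pixel centers at (i + 0.5) * spacing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .phantom import REGION_LABELS, TRACT_REGIONS
from .tensor import MetricMaps

__all__ = [
    "EllipseModel",
    "AngularProfile",
    "CircularROI",
    "ROISet",
    "ROIPlacement",
    "TractMetrics",
    "segment_cord",
    "fit_ellipse",
    "sample_profile",
    "adjust_exit_angles",
    "place_rois",
    "extract",
]


@dataclass(frozen=True)
class EllipseModel:
    """Cord ellipse in mm coordinates.

    ``rotation`` is the angle (degrees) of the semi-axis ``semi_x`` from the
    +x (right-left) axis; for the near-axis-aligned cord it stays close to
    0 and ``semi_x >= semi_y``.  ``exit_angles`` are the posterior-horn exit
    angles (left, right), positive degrees from the posterior midline.
    """

    center: tuple[float, float]  # (x, y) mm
    semi_x: float  # mm, along the rotated x axis (major for the cord)
    semi_y: float  # mm
    rotation: float = 0.0  # degrees
    exit_angles: tuple[float, float] = (35.0, 35.0)

    def __post_init__(self) -> None:
        if not (self.semi_x > 0 and self.semi_y > 0):
            raise ValueError("semi-axes must be positive")

    def point_at(self, angle_deg, frac: float = 1.0):
        """Point(s) on the ellipse scaled by ``frac`` at parametric angle(s)
        measured from the posterior midline."""
        from .phantom import ellipse_point

        return ellipse_point(
            self.center, (self.semi_x, self.semi_y), self.rotation, angle_deg, frac
        )

    def contains(self, x: float, y: float, frac: float = 1.0) -> bool:
        rot = np.deg2rad(self.rotation)
        dx, dy = x - self.center[0], y - self.center[1]
        u = dx * np.cos(rot) + dy * np.sin(rot)
        v = -dx * np.sin(rot) + dy * np.cos(rot)
        return (u / (frac * self.semi_x)) ** 2 + (v / (frac * self.semi_y)) ** 2 <= 1.0


@dataclass(frozen=True)
class AngularProfile:
    """Metric values sampled along a scaled ellipse path."""

    angles: np.ndarray  # degrees in [0, 360), strictly increasing
    values: np.ndarray
    radial_fraction: float

    def __post_init__(self) -> None:
        if len(self.angles) != len(self.values):
            raise ValueError("angles and values must align")
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")


@dataclass(frozen=True)
class CircularROI:
    label: str  # e.g. "PT_L"
    center: tuple[float, float]  # mm
    diameter: float  # mm


@dataclass(frozen=True)
class ROISet:
    rois: tuple[CircularROI, ...]

    def __post_init__(self) -> None:
        if len(self.rois) != 6:
            raise ValueError("expected exactly 6 ROIs")

    def __iter__(self):
        return iter(self.rois)

    def by_label(self) -> dict[str, CircularROI]:
        return {r.label: r for r in self.rois}


@dataclass(frozen=True)
class ROIPlacement:
    """Angular position / radial fraction of each tract ROI pair.

    The pyramidal-tract angle is expressed as an offset lateral of the
    posterior-horn exit angle.  All parameters are tunable; left/right
    symmetry is enforced by construction.
    """

    dc_angle: float = 15.0
    dc_frac: float = 0.72
    pt_offset: float = 25.0  # degrees lateral of the exit angle
    pt_frac: float = 0.70
    ah_angle: float = 150.0
    ah_frac: float = 0.45
    diameter: float = 1.05  # mm


@dataclass
class TractMetrics:
    """Left/right-averaged region means and per-ROI bookkeeping."""

    region_means: pd.DataFrame  # region x metric
    roi_means: pd.DataFrame  # roi label x metric
    pixel_counts: dict[str, int]


def segment_cord(
    b0: np.ndarray,
    spacing: tuple[float, float],
    background_fraction: float = 0.10,
    csf_fraction: float = 0.60,
    percentile: float = 98.0,
) -> np.ndarray:
    """Binary cord mask: tissue brighter than background, darker than CSF.

    Thresholds are fractions of the 98th-percentile b0 intensity.  The
    largest connected component is kept and interior holes are filled.
    """
    ref = np.percentile(b0, percentile)
    cand = (b0 > background_fraction * ref) & (b0 < csf_fraction * ref)
    if not np.any(cand):
        raise ValueError("cord segmentation produced an empty mask")
    lab, n = ndimage.label(cand)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    mask = lab == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask)


def fit_ellipse(mask: np.ndarray, spacing: tuple[float, float]) -> EllipseModel:
    """Moment-based ellipse fit of a binary mask.

    Center = mask centroid; orientation and axis ratio come from the second
    central moments of the pixel centers; the axes are then scaled so the
    ellipse area equals the mask area.  A (near-)circular mask reports
    rotation 0 by convention.
    """
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty mask")
    y = (rows + 0.5) * spacing[0]
    x = (cols + 0.5) * spacing[1]
    cx, cy = float(x.mean()), float(y.mean())
    cov = np.cov(np.vstack([x, y]))
    if rows.size < 3 or np.linalg.matrix_rank(cov) < 2:
        raise ValueError("degenerate mask: cannot fit an ellipse")
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[0] <= 0:
        raise ValueError("degenerate (collinear) mask")
    # uniform filled ellipse: variance along an axis = (semi-axis)^2 / 4
    a = 2.0 * np.sqrt(evals[1])  # larger
    b = 2.0 * np.sqrt(evals[0])
    area = rows.size * spacing[0] * spacing[1]
    scale = np.sqrt(area / (np.pi * a * b))
    a, b = a * scale, b * scale
    if (a - b) / a < 1e-3:
        rotation = 0.0
    else:
        vx, vy = evecs[:, 1]
        rotation = float(np.rad2deg(np.arctan2(vy, vx)))
        if rotation > 90.0:
            rotation -= 180.0
        elif rotation <= -90.0:
            rotation += 180.0
    return EllipseModel(center=(cx, cy), semi_x=a, semi_y=b, rotation=rotation)


def sample_profile(
    map_arr: np.ndarray,
    spacing: tuple[float, float],
    ellipse: EllipseModel,
    radial_fraction: float = 0.72,
    n: int = 600,
) -> AngularProfile:
    """Bilinear samples at ``n`` equally spaced angles (default 600, 0.6 deg)."""
    angles = np.arange(n) * (360.0 / n)
    x, y = ellipse.point_at(angles, radial_fraction)
    rows = y / spacing[0] - 0.5
    cols = x / spacing[1] - 0.5
    ny, nx = map_arr.shape
    if (
        rows.min() < -0.5
        or cols.min() < -0.5
        or rows.max() > ny - 0.5
        or cols.max() > nx - 0.5
    ):
        raise ValueError("sampling ellipse extends outside the map")
    values = ndimage.map_coordinates(
        np.asarray(map_arr, dtype=float), [rows, cols], order=1, mode="nearest"
    )
    return AngularProfile(angles=angles, values=values, radial_fraction=radial_fraction)


def adjust_exit_angles(
    ellipse: EllipseModel,
    fa_profile: AngularProfile,
    search_window: tuple[float, float] = (10.0, 70.0),
    flat_tolerance: float = 1e-6,
) -> EllipseModel:
    """Set the posterior-horn exit angles to the FA-profile minima.

    One minimum is sought per side within ``search_window`` degrees of the
    posterior midline (left side: +window; right side: equivalent negative
    angles).  A flat profile leaves the prior angles unchanged with a
    warning.
    """
    ang, val = fa_profile.angles, fa_profile.values
    if np.ptp(val) < flat_tolerance:
        warnings.warn(
            "flat FA profile: posterior-horn exit angles left unchanged",
            stacklevel=2,
        )
        return ellipse
    lo, hi = search_window
    left_sel = (ang >= lo) & (ang <= hi)
    right_ang = 360.0 - ang  # degrees from midline on the right side
    right_sel = (right_ang >= lo) & (right_ang <= hi)
    if not np.any(left_sel) or not np.any(right_sel):
        warnings.warn("no samples in the search window", stacklevel=2)
        return ellipse
    left = float(ang[left_sel][np.argmin(val[left_sel])])
    right = float(right_ang[right_sel][np.argmin(val[right_sel])])
    return replace(ellipse, exit_angles=(left, right))


def place_rois(
    ellipse: EllipseModel, placement: ROIPlacement = ROIPlacement()
) -> ROISet:
    """Six mirror-symmetric circular ROIs positioned on the cord ellipse."""
    exit_l, exit_r = ellipse.exit_angles
    spec = {
        "DC": (placement.dc_angle, placement.dc_angle, placement.dc_frac),
        "PT": (exit_l + placement.pt_offset, exit_r + placement.pt_offset, placement.pt_frac),
        "AH": (placement.ah_angle, placement.ah_angle, placement.ah_frac),
    }
    rois = []
    for region, (ang_l, ang_r, frac) in spec.items():
        for side, ang in (("L", ang_l), ("R", -ang_r)):
            x, y = ellipse.point_at(ang, frac)
            if not ellipse.contains(float(x), float(y)):
                raise ValueError(f"ROI {region}_{side} falls outside the cord ellipse")
            rois.append(
                CircularROI(
                    label=f"{region}_{side}",
                    center=(float(x), float(y)),
                    diameter=placement.diameter,
                )
            )
    return ROISet(rois=tuple(rois))


def roi_pixel_mask(
    roi: CircularROI, shape: tuple[int, int], spacing: tuple[float, float]
) -> np.ndarray:
    """Pixels whose centers lie within the ROI circle."""
    ny, nx = shape
    y = (np.arange(ny) + 0.5) * spacing[0]
    x = (np.arange(nx) + 0.5) * spacing[1]
    yy, xx = np.meshgrid(y, x, indexing="ij")
    return np.hypot(xx - roi.center[0], yy - roi.center[1]) <= roi.diameter / 2.0


def extract(maps: MetricMaps, roiset: ROISet) -> TractMetrics:
    """Per-ROI means and left/right-averaged region means of all metrics.

    Pixel membership is center-in-circle; the raw map values are averaged
    without normalisation.  An ROI containing no pixel centers at the map
    resolution is an error.
    """
    shape = maps.fa.shape
    metric_maps = maps.as_dict()
    roi_rows, counts = {}, {}
    for roi in roiset:
        sel = roi_pixel_mask(roi, shape, maps.spacing)
        n_px = int(sel.sum())
        if n_px == 0:
            raise ValueError(f"ROI {roi.label} contains no pixels at this resolution")
        counts[roi.label] = n_px
        roi_rows[roi.label] = {
            m: float(arr[sel].mean()) for m, arr in metric_maps.items()
        }
    roi_means = pd.DataFrame(roi_rows).T
    region_rows = {}
    for region in TRACT_REGIONS:
        region_rows[region] = (
            roi_means.loc[f"{region}_L"] + roi_means.loc[f"{region}_R"]
        ) / 2.0
    region_means = pd.DataFrame(region_rows).T
    region_means.index.name = "region"
    return TractMetrics(
        region_means=region_means, roi_means=roi_means, pixel_counts=counts
    )


def majority_labels(
    roiset: ROISet,
    label_map: np.ndarray,
    spacing: tuple[float, float],
    sample_spacing: float = 0.2,
) -> dict[str, str]:
    """Ground-truth label receiving the most area of each ROI (phantom QC).

    The label map is sampled nearest-neighbour on a fine grid (default
    0.2 mm) restricted to each ROI circle, so the vote reflects area rather
    than the few native-resolution pixel centers a 1.05 mm circle covers.
    """
    code_to_name = {v: k for k, v in REGION_LABELS.items()}
    out = {}
    ny, nx = label_map.shape
    for roi in roiset:
        r = roi.diameter / 2.0
        xs = np.arange(roi.center[0] - r, roi.center[0] + r + 1e-9, sample_spacing)
        ys = np.arange(roi.center[1] - r, roi.center[1] + r + 1e-9, sample_spacing)
        yy, xx = np.meshgrid(ys, xs, indexing="ij")
        sel = np.hypot(xx - roi.center[0], yy - roi.center[1]) <= r
        rows = np.clip(np.round(yy[sel] / spacing[0] - 0.5).astype(int), 0, ny - 1)
        cols = np.clip(np.round(xx[sel] / spacing[1] - 0.5).astype(int), 0, nx - 1)
        codes, freq = np.unique(label_map[rows, cols], return_counts=True)
        out[roi.label] = code_to_name[int(codes[np.argmax(freq)])]
    return out
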