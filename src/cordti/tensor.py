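"""Diffusion tensor estimation and scalar metric maps.

Implements the six-direction log-linear tensor fit of the Stejskal-Tanner
signal model S_i = S0 * exp(-b * g_i^T D g_i), eigenvalue-derived metrics
(FA, MD, AD, RD), and interpolation of the metric maps to a finer grid.

With exactly six non-collinear encoding directions the linear system is
square, so the noise-free fit is an interpolation: the generating tensor is
recovered to numerical precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "DEFAULT_DIRECTIONS",
    "DiffusionScheme",
    "TensorField",
    "MetricMaps",
    "design_matrix",
    "fit_pixel",
    "fit_tensors",
    "eigen_metrics",
    "compute_maps",
    "interpolate_maps",
]

#: The six encoding directions of the axial cervical-cord protocol, as listed
#: in the acquisition scheme (norm sqrt(2); normalised before use).
DEFAULT_DIRECTIONS = np.array(
    [
        (1.0, 0.0, 1.0),
        (-1.0, 0.0, 1.0),
        (0.0, 1.0, 1.0),
        (0.0, 1.0, -1.0),
        (1.0, 1.0, 0.0),
        (-1.0, 1.0, 0.0),
    ]
)


@dataclass(frozen=True)
class DiffusionScheme:
    """Diffusion encoding: b-value, gradient directions and b0 count.

    ``b`` is in s/mm^2.  ``raw_directions`` may have any non-zero norm; the
    attenuation model always uses the unit-normalised copies, so listing
    directions scaled by any constant changes nothing.
    """

    b: float = 750.0
    raw_directions: np.ndarray = field(
        default_factory=lambda: DEFAULT_DIRECTIONS.copy()
    )
    n_b0: int = 1

    def __post_init__(self) -> None:
        dirs = np.atleast_2d(np.asarray(self.raw_directions, dtype=float))
        if dirs.shape[1] != 3:
            raise ValueError("directions must be 3-vectors")
        if dirs.shape[0] < 6:
            raise ValueError("at least 6 encoding directions are required")
        norms = np.linalg.norm(dirs, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero direction vector in scheme")
        if self.b < 0:
            raise ValueError("b-value must be non-negative")
        object.__setattr__(self, "raw_directions", dirs)

    @property
    def n_directions(self) -> int:
        return self.raw_directions.shape[0]

    @property
    def unit_directions(self) -> np.ndarray:
        dirs = self.raw_directions
        return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def design_matrix(scheme: DiffusionScheme) -> np.ndarray:
    """Linearised Stejskal-Tanner design matrix, one row per direction.

    Row i is ``b * [gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz]`` for unit
    direction g_i, so that ``A @ d = ln(S0 / S_i)`` with d the tensor
    six-vector (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) in mm^2/s.

    Raises
    ------
    ValueError
        If the scheme does not determine all six tensor components
        (design matrix rank below 6).
    """
    g = scheme.unit_directions
    a = scheme.b * np.column_stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ]
    )
    rank = np.linalg.matrix_rank(a)
    if rank < 6:
        raise ValueError(
            f"rank-deficient encoding scheme: design matrix rank {rank} < 6; "
            "the directions do not determine all tensor components"
        )
    return a


def tensor6_to_matrix(d: np.ndarray) -> np.ndarray:
    """Expand (..., 6) tensor vectors to (..., 3, 3) symmetric matrices."""
    d = np.asarray(d, dtype=float)
    m = np.empty(d.shape[:-1] + (3, 3))
    m[..., 0, 0] = d[..., 0]
    m[..., 1, 1] = d[..., 1]
    m[..., 2, 2] = d[..., 2]
    m[..., 0, 1] = m[..., 1, 0] = d[..., 3]
    m[..., 0, 2] = m[..., 2, 0] = d[..., 4]
    m[..., 1, 2] = m[..., 2, 1] = d[..., 5]
    return m


def fit_tensors(
    signals: np.ndarray,
    s0: np.ndarray,
    scheme: DiffusionScheme,
    signal_floor: float = 1e-12,
) -> np.ndarray:
    """Least-squares tensor fit for an array of pixels.

    Parameters
    ----------
    signals : ndarray, shape (..., n_directions)
        Diffusion-weighted signals in scheme order.
    s0 : ndarray, shape (...)
        Baseline (b0) signal per pixel, > 0.
    scheme : DiffusionScheme

    Returns
    -------
    ndarray, shape (..., 6)
        Tensor six-vectors in units of 1e-3 mm^2/s.  Scaling signals and s0
        by a common factor leaves the fit unchanged (ratio invariance).
    """
    signals = np.asarray(signals, dtype=float)
    s0 = np.asarray(s0, dtype=float)
    if np.any(~np.isfinite(signals)) or np.any(~np.isfinite(s0)):
        raise ValueError("non-finite signal values")
    a = design_matrix(scheme)
    y = np.log(np.maximum(s0[..., None], signal_floor) / np.maximum(signals, signal_floor))
    # square system for 6 directions -> exact solve; least squares otherwise
    d, *_ = np.linalg.lstsq(a, y.reshape(-1, a.shape[0]).T, rcond=None)
    return 1e3 * d.T.reshape(signals.shape[:-1] + (6,))


def fit_pixel(
    signals: np.ndarray, s0: float, scheme: DiffusionScheme
) -> np.ndarray:
    """Tensor six-vector (1e-3 mm^2/s) for a single pixel."""
    signals = np.asarray(signals, dtype=float)
    if np.all(signals == 0):
        raise ValueError("all-zero signals: undefined pixel")
    return fit_tensors(signals[None, :], np.array([s0]), scheme)[0]


@dataclass
class TensorField:
    """Per-pixel fitted tensors with sorted eigenvalues and fit residuals."""

    tensor6: np.ndarray  # (..., 6) in 1e-3 mm^2/s
    eigenvalues: np.ndarray  # (..., 3), descending
    residual: np.ndarray  # per-pixel RMS residual of the log-signal fit
    n_clamped: int = 0  # pixels with negative eigenvalues clamped


def eigen_metrics(
    tensor6: np.ndarray, eigenvalue_floor: float = 0.0
) -> dict[str, np.ndarray]:
    """Eigenvalues and the scalar diffusion metrics of a tensor array.

    Eigenvalues are sorted descending and floored at ``eigenvalue_floor``
    (default 0: negative values, which arise from noise, are clamped to 0
    before the metric formulas).  Returns a dict with keys ``lambda1``,
    ``lambda2``, ``lambda3``, ``fa``, ``md``, ``ad``, ``rd``, ``n_clamped``.

    FA = sqrt(3/2) * sqrt(sum (li - lmean)^2) / sqrt(sum li^2), defined as 0
    for an all-zero tensor; MD = (l1+l2+l3)/3; AD = l1; RD = (l2+l3)/2.
    """
    m = tensor6_to_matrix(tensor6)
    if np.any(~np.isfinite(m)):
        raise ValueError("non-finite tensor")
    lam = np.linalg.eigvalsh(m)[..., ::-1]  # descending
    n_clamped = int(np.sum(np.any(lam < eigenvalue_floor, axis=-1)))
    lam = np.maximum(lam, eigenvalue_floor)
    l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2]
    md = (l1 + l2 + l3) / 3.0
    ad = l1
    rd = (l2 + l3) / 2.0
    num = np.sqrt((l1 - md) ** 2 + (l2 - md) ** 2 + (l3 - md) ** 2)
    den = np.sqrt(l1**2 + l2**2 + l3**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    fa = np.clip(fa, 0.0, 1.0)
    return {
        "lambda1": l1,
        "lambda2": l2,
        "lambda3": l3,
        "fa": fa,
        "md": md,
        "ad": ad,
        "rd": rd,
        "n_clamped": n_clamped,
    }


def radial_diffusivity_printed_variant(lam: np.ndarray) -> np.ndarray:
    """RD computed as (lambda1 + lambda2)/2.

    Audit-only variant reproducing a typographic definition sometimes seen in
    print; the standard perpendicular diffusivity (lambda2 + lambda3)/2 is
    the default everywhere else in this package.
    """
    return (lam[..., 0] + lam[..., 1]) / 2.0


@dataclass
class MetricMaps:
    """FA/MD/AD/RD scalar maps plus validity mask and grid spacing.

    Diffusivities are in 1e-3 mm^2/s; FA is unitless in [0, 1].  ``mask``
    marks pixels where the fit is defined (foreground).
    """

    fa: np.ndarray
    md: np.ndarray
    ad: np.ndarray
    rd: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float]
    interpolated: bool = False

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"fa": self.fa, "md": self.md, "ad": self.ad, "rd": self.rd}


def background_mask(
    b0: np.ndarray, threshold_fraction: float = 0.10, percentile: float = 98.0
) -> np.ndarray:
    """Foreground mask: b0 above ``threshold_fraction`` of its 98th percentile."""
    thr = threshold_fraction * np.percentile(b0, percentile)
    return b0 > thr


def compute_maps(
    stack,
    scheme: DiffusionScheme,
    eigenvalue_floor: float = 0.0,
    mask_threshold_fraction: float = 0.10,
    rd_printed_variant: bool = False,
) -> tuple[MetricMaps, TensorField]:
    """Fit the tensor per pixel of a repetition-averaged stack and map metrics.

    The stack must contain exactly one volume per diffusion direction plus a
    b0.  Background pixels (mean b0 below 10% of the 98th percentile by
    default) are excluded via the validity mask and carry zero metrics.
    """
    from .stack import DWIStack  # local import to avoid cycle at import time

    assert isinstance(stack, DWIStack)
    counts = stack.repetition_counts()
    if 0 not in counts:
        raise ValueError("stack has no b0 volume")
    if any(c != 1 for c in counts.values()):
        raise ValueError("compute_maps expects a repetition-averaged stack")

    b0 = stack.mean_b0()
    mask = background_mask(b0, mask_threshold_fraction)
    n_dir = scheme.n_directions
    sig = np.empty(b0.shape + (n_dir,))
    for j in range(1, n_dir + 1):
        idx = stack.direction_indices(j)
        if idx.size != 1:
            raise ValueError(f"direction {j} missing from stack")
        sig[:, :, j - 1] = stack.voxels[:, :, idx[0]]

    a = design_matrix(scheme)
    safe_s0 = np.where(mask, b0, 1.0)
    safe_sig = np.where(mask[..., None], np.maximum(sig, 1e-12), 1.0)
    d6 = fit_tensors(safe_sig, safe_s0, scheme)
    # residual of the log-linear system (zero for 6 directions)
    y = np.log(safe_s0[..., None] / safe_sig)
    resid = y - (d6 * 1e-3) @ a.T
    rms_resid = np.sqrt(np.mean(resid**2, axis=-1))

    met = eigen_metrics(d6, eigenvalue_floor)
    lam = np.stack([met["lambda1"], met["lambda2"], met["lambda3"]], axis=-1)
    rd = (
        radial_diffusivity_printed_variant(lam)
        if rd_printed_variant
        else met["rd"]
    )
    maps = MetricMaps(
        fa=np.where(mask, met["fa"], 0.0),
        md=np.where(mask, met["md"], 0.0),
        ad=np.where(mask, met["ad"], 0.0),
        rd=np.where(mask, rd, 0.0),
        mask=mask,
        spacing=stack.spacing,
        interpolated=False,
    )
    field_ = TensorField(
        tensor6=d6,
        eigenvalues=lam,
        residual=rms_resid,
        n_clamped=met["n_clamped"],
    )
    return maps, field_


def _resample(arr: np.ndarray, in_spacing, out_spacing, out_shape, order: int) -> np.ndarray:
    """Resample with pixel centers at (i + 0.5) * spacing in mm."""
    rows = (np.arange(out_shape[0]) + 0.5) * out_spacing[0] / in_spacing[0] - 0.5
    cols = (np.arange(out_shape[1]) + 0.5) * out_spacing[1] / in_spacing[1] - 0.5
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return ndimage.map_coordinates(
        arr, [rr, cc], order=order, mode="nearest"
    )


def interpolate_maps(
    maps: MetricMaps, target_spacing: float = 0.2, order: int = 3
) -> MetricMaps:
    """Resample the metric maps onto a finer grid (default 0.2 x 0.2 mm^2).

    The metric maps themselves are interpolated (cubic spline by default),
    not the raw DWIs.  FA is clipped back to [0, 1]; the validity mask is
    resampled with nearest-neighbour assignment.
    """
    if target_spacing <= 0:
        raise ValueError("target spacing must be positive")
    if target_spacing >= min(maps.spacing):
        raise ValueError("target spacing must be finer than the native spacing")
    in_sp = maps.spacing
    out_sp = (target_spacing, target_spacing)
    out_shape = (
        int(round(maps.fa.shape[0] * in_sp[0] / target_spacing)),
        int(round(maps.fa.shape[1] * in_sp[1] / target_spacing)),
    )
    out = {
        k: _resample(v, in_sp, out_sp, out_shape, order)
        for k, v in maps.as_dict().items()
    }
    mask = _resample(maps.mask.astype(float), in_sp, out_sp, out_shape, 0) > 0.5
    return MetricMaps(
        fa=np.clip(out["fa"], 0.0, 1.0),
        md=out["md"],
        ad=out["ad"],
        rd=out["rd"],
        mask=mask,
        spacing=out_sp,
        interpolated=True,
    )
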