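"""Multi-volume axial DWI stack container.

A :class:`DWIStack` holds a single axial slice acquired repeatedly: one
non-diffusion-weighted (b0) image plus several diffusion-encoded images,
each possibly repeated many times.  The first array axis is the
anterior-posterior (AP, phase-encode) axis with row index increasing from
posterior to anterior; the second axis is right-left.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["VolumeInfo", "DWIStack"]


@dataclass(frozen=True)
class VolumeInfo:
    """Per-volume acquisition metadata.

    ``direction_index`` 0 denotes the b0 reference; diffusion directions are
    numbered from 1 in scheme order.  ``shift_applied`` records any simulated
    AP displacement in pixels (phantom provenance, 0 for real data).
    """

    b: float
    direction_index: int
    repetition: int
    shift_applied: float = 0.0


@dataclass
class DWIStack:
    """2-D multi-volume diffusion-weighted image stack.

    Parameters
    ----------
    voxels : ndarray, shape (n_rows, n_cols, n_volumes)
        Non-negative magnitude images; rows run posterior -> anterior.
    spacing : (float, float)
        Pixel spacing in mm along (row/AP, col/RL).
    volumes : list of VolumeInfo
        One record per volume, aligned with the last array axis.
    provenance : list of str
        Log of operations applied to the stack.
    """

    voxels: np.ndarray
    spacing: tuple[float, float]
    volumes: list[VolumeInfo]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be 3-D [row, col, volume]")
        if self.voxels.shape[2] != len(self.volumes):
            raise ValueError(
                f"{self.voxels.shape[2]} volumes in array but "
                f"{len(self.volumes)} metadata records"
            )
        if np.any(self.voxels < 0):
            raise ValueError("intensities must be non-negative")
        if not any(v.direction_index == 0 for v in self.volumes):
            raise ValueError("stack must contain at least one b0 volume")

    # -- convenience accessors -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_directions(self) -> int:
        return len({v.direction_index for v in self.volumes if v.direction_index > 0})

    def b0_indices(self) -> np.ndarray:
        return np.array(
            [i for i, v in enumerate(self.volumes) if v.direction_index == 0]
        )

    def direction_indices(self, direction_index: int) -> np.ndarray:
        return np.array(
            [i for i, v in enumerate(self.volumes) if v.direction_index == direction_index]
        )

    def mean_b0(self) -> np.ndarray:
        """Mean image over all b0 volumes."""
        return self.voxels[:, :, self.b0_indices()].mean(axis=2)

    def repetition_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for v in self.volumes:
            counts[v.direction_index] = counts.get(v.direction_index, 0) + 1
        return counts

    def with_voxels(self, voxels: np.ndarray, note: str) -> "DWIStack":
        """Copy of the stack with new voxel data and a provenance entry."""
        return DWIStack(
            voxels=voxels,
            spacing=self.spacing,
            volumes=list(self.volumes),
            provenance=self.provenance + [note],
        )

    def copy(self) -> "DWIStack":
        return DWIStack(
            voxels=self.voxels.copy(),
            spacing=self.spacing,
            volumes=list(self.volumes),
            provenance=list(self.provenance),
        )
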