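"""Core voxel-volume container shared across the package.

A :class:`PETVolume` is a 3-D voxel array (axial slices along axis 0)
plus geometry and a tag saying which value space the voxels live in:

``counts``
    activity concentration in Bq/mL, straight off the scanner;
``SUV``
    standardized uptake value (body-weight convention), unitless;
``scaled``
    SUV clipped at 100 and divided by 100, i.e. values in [0, 1] —
    the space the networks train in.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

VALUE_SPACES = ("counts", "SUV", "scaled")


@dataclass
class PETVolume:
    """A PET volume with spacing and value-space bookkeeping.

    Parameters
    ----------
    voxels : ndarray, shape (n_slices, ny, nx)
        Voxel values. 2-D arrays are promoted to a single-slice volume.
    spacing : tuple of float
        Voxel size in mm, ordered (slice, y, x).
    value_space : str
        One of ``counts``, ``SUV``, ``scaled``.
    origin : tuple of float
        World position of voxel (0, 0, 0) in mm.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (3.27, 2.73, 2.73)
    value_space: str = "SUV"
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=np.float64)
        if vox.ndim == 2:
            vox = vox[np.newaxis]
        if vox.ndim != 3:
            raise ValueError(f"voxels must be 2-D or 3-D, got ndim={vox.ndim}")
        if not np.all(np.isfinite(vox)):
            raise ValueError("voxels must be finite")
        if self.value_space not in VALUE_SPACES:
            raise ValueError(
                f"value_space must be one of {VALUE_SPACES}, got {self.value_space!r}"
            )
        if self.value_space == "scaled" and (vox.min() < 0 or vox.max() > 1 + 1e-9):
            raise ValueError("scaled volumes must lie in [0, 1]")
        self.voxels = vox
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    def with_voxels(self, voxels: np.ndarray, value_space: str | None = None) -> "PETVolume":
        """Return a copy carrying new voxels (geometry preserved)."""
        return replace(
            self,
            voxels=np.asarray(voxels, dtype=np.float64),
            value_space=value_space or self.value_space,
        )

    def same_grid(self, other: "PETVolume", tol: float = 1e-6) -> bool:
        return self.shape == other.shape and all(
            abs(a - b) <= tol for a, b in zip(self.spacing, other.spacing)
        )
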