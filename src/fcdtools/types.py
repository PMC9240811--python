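"""Core in-memory containers shared across the pipeline.

Every volume carries its voxel-to-world affine so that downstream tables can
report world (MNI, mm) coordinates without ambiguity about voxel indexing;
indices are 0-based internally and only world coordinates are user-facing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class InputError(ValueError):
    """Invalid data handed to an operation (wrong shape, empty mask, ...)."""


class ConfigurationError(ValueError):
    """Invalid configuration or cohort specification."""


class GeometryError(InputError):
    """Volumes that must share a grid do not."""


def make_affine(grid_shape, voxel_size_mm=3.0) -> np.ndarray:
    """RAS affine for an isotropic grid with the world origin at its center."""
    vs = float(voxel_size_mm)
    aff = np.diag([vs, vs, vs, 1.0])
    aff[:3, 3] = -vs * (np.asarray(grid_shape, dtype=float) - 1.0) / 2.0
    return aff


def voxel_sizes(affine: np.ndarray) -> np.ndarray:
    """Per-axis voxel edge lengths (mm) from the affine's column norms."""
    return np.sqrt((np.asarray(affine)[:3, :3] ** 2).sum(axis=0))


@dataclass(frozen=True)
class VolumeGeometry:
    """Grid shape plus voxel-to-world transform; equality is bit-exact."""

    shape: tuple
    affine: np.ndarray

    def __post_init__(self):
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise InputError(f"affine must be 4x4, got {aff.shape}")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise InputError("affine is not invertible")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "affine", aff)

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return voxel_sizes(self.affine)

    def matches(self, other: "VolumeGeometry") -> bool:
        return self.shape == other.shape and np.array_equal(self.affine, other.affine)

    def require_match(self, other: "VolumeGeometry", what: str = "volume"):
        if not self.matches(other):
            raise GeometryError(
                f"geometry mismatch for {what}: shape {self.shape} vs {other.shape}, "
                f"affine\n{self.affine}\nvs\n{other.affine}"
            )


@dataclass
class BoldSeries:
    """A subject's 4D BOLD grid (x, y, z, t) with geometry and TR (seconds)."""

    data: np.ndarray
    affine: np.ndarray
    tr_s: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise InputError(f"BOLD data must be 4D, got {self.data.ndim}D")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.tr_s <= 0:
            raise InputError("tr_s must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple:
        return self.data.shape[:3]

    @property
    def geometry(self) -> VolumeGeometry:
        return VolumeGeometry(self.grid_shape, self.affine)


@dataclass
class VolumeMap:
    """A 3D scalar per-voxel map sharing the BOLD grid geometry."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise InputError(f"map data must be 3D, got {self.data.ndim}D")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def grid_shape(self) -> tuple:
        return self.data.shape

    @property
    def geometry(self) -> VolumeGeometry:
        return VolumeGeometry(self.grid_shape, self.affine)


@dataclass
class FCDMap(VolumeMap):
    """gFCD map: integer connection counts (raw) or real values after
    smoothing/rescaling; ``mask_size`` is the in-mask voxel count V, so raw
    counts lie in [0, V-1]."""

    mask_size: int = 0


class GMVMap(VolumeMap):
    """Gray-matter-volume map (arbitrary tissue-volume units, nonnegative)."""


@dataclass
class MotionTrace:
    """Per-volume rigid-motion parameters: 3 translations (mm) then 3
    rotations (radians), one row per volume (SPM rp_*.txt column order)."""

    params: np.ndarray

    def __post_init__(self):
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise InputError(
                f"motion parameters must be (n_volumes, 6), got {self.params.shape}"
            )

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]

    @property
    def translations_mm(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations_rad(self) -> np.ndarray:
        return self.params[:, 3:]

    def discard_initial(self, n_discard: int) -> "MotionTrace":
        if n_discard >= self.n_volumes:
            raise InputError(
                f"cannot discard {n_discard} of {self.n_volumes} motion rows"
            )
        return MotionTrace(self.params[n_discard:].copy())


@dataclass
class NuisanceDesign:
    """Named per-volume regressor matrix (motion, derivatives, tissue means,
    spike indicators, intercept)."""

    matrix: np.ndarray
    names: list

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.names):
            raise InputError("design matrix / column-name mismatch")

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @property
    def spike_columns(self) -> list:
        return [n for n in self.names if n.startswith("spike_")]


@dataclass
class GroupStatResult:
    """Voxel-wise group-contrast result: t, two-sided p, BH q, the
    FDR-significant mask, and the group-coefficient (adjusted patient-minus-
    control mean difference) effect map, all on the analysis grid (zero
    outside mask)."""

    t_map: np.ndarray
    p_map: np.ndarray
    q_map: np.ndarray
    sig_mask: np.ndarray
    df: int
    affine: np.ndarray
    mask: np.ndarray
    alpha: float = 0.05
    effect_map: np.ndarray | None = None
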