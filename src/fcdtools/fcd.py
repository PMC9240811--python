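"""Global functional connectivity density (gFCD) mapping.

gFCD at a voxel x0 is the number of other in-mask voxels whose time-series
Pearson correlation with x0 exceeds a threshold (default R > 0.6) — the
voxel-level degree of the thresholded whole-brain correlation graph.
Computation is restricted to a gray-matter mask, and the raw count map is
typically Gaussian-smoothed (6 mm FWHM) and, for hub display, rescaled to
unit in-mask mean.

The all-pairs correlation is evaluated in chunked matrix products over
standardized series; chunking affects memory use only, never the counts.
Correlations are compared against ``r_threshold + 1e-12``: the guard makes
the strict inequality well defined under floating-point rounding (a pair
whose true correlation equals the threshold exactly is never counted) while
sitting far below any statistically meaningful resolution.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

from .types import FCDMap, InputError, VolumeMap, voxel_sizes

#: see module docstring — guard making "r > threshold" robust at the boundary
THRESHOLD_GUARD = 1e-12

#: FWHM of a Gaussian equals sigma * 2*sqrt(2*ln 2)
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclasses.dataclass(frozen=True)
class FcdParams:
    r_threshold: float = 0.6
    chunk_size: int = 1024

    def validate(self):
        if not (-1.0 < self.r_threshold < 1.0):
            raise InputError(f"r_threshold must be in (-1, 1), got {self.r_threshold}")
        if self.chunk_size < 1:
            raise InputError("chunk_size must be >= 1")


@dataclasses.dataclass(frozen=True)
class SmoothingSpec:
    """Gaussian kernel FWHM in mm (scalar or per-axis 3-vector)."""

    fwhm_mm: tuple = (6.0, 6.0, 6.0)

    def __post_init__(self):
        f = np.atleast_1d(np.asarray(self.fwhm_mm, dtype=float))
        if f.size == 1:
            f = np.repeat(f, 3)
        if f.size != 3 or np.any(f <= 0):
            raise InputError(f"fwhm_mm must be 3 positive lengths, got {self.fwhm_mm}")
        object.__setattr__(self, "fwhm_mm", tuple(f))

    def sigma_vox(self, affine: np.ndarray) -> np.ndarray:
        return np.asarray(self.fwhm_mm) / FWHM_PER_SIGMA / voxel_sizes(affine)


def _standardize(series: np.ndarray):
    """Demean and unit-normalize rows so that Z @ Z.T gives Pearson r.

    Zero-variance rows are mapped to all-zero rows (correlation undefined ->
    treated as uncorrelated with everything) and reported back.
    """
    degenerate = np.ptp(series, axis=1) == 0.0  # constant series
    Z = series - series.mean(axis=1, keepdims=True)
    Z[degenerate] = 0.0
    norms = np.linalg.norm(Z, axis=1)
    norms[degenerate] = 1.0
    Z /= norms[:, None]
    return Z, degenerate


def compute_gfcd(bold, mask: np.ndarray, params: FcdParams | None = None) -> FCDMap:
    """Per-voxel count of other in-mask voxels correlated above threshold.

    Self-pairs are excluded; zero-variance voxels count as connected to
    nothing (and contribute to no one's count). The result is independent of
    ``chunk_size``.
    """
    params = params or FcdParams()
    params.validate()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != bold.grid_shape:
        raise InputError(f"mask grid {mask.shape} != BOLD grid {bold.grid_shape}")
    if not mask.any():
        raise InputError("analysis mask is empty")
    if bold.n_volumes < 3:
        raise InputError("need at least 3 time points for correlation")

    X = np.ascontiguousarray(bold.data[mask], dtype=np.float64)  # (V, t)
    Z, degenerate = _standardize(X)
    if degenerate.all():
        raise InputError("all in-mask voxel series are constant")
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance voxel(s) treated as unconnected",
            RuntimeWarning,
            stacklevel=2,
        )
    thr = params.r_threshold + THRESHOLD_GUARD
    V = Z.shape[0]
    counts = np.zeros(V, dtype=np.int64)
    for start in range(0, V, params.chunk_size):
        block = Z[start : start + params.chunk_size] @ Z.T
        counts[start : start + params.chunk_size] = (block > thr).sum(axis=1)
    counts[~degenerate] -= 1  # remove the self-pair (r == 1)

    out = np.zeros(mask.shape, dtype=np.int64)
    out[mask] = counts
    return FCDMap(out, bold.affine.copy(), mask_size=int(mask.sum()))


def smooth_map(vmap: VolumeMap, spec: SmoothingSpec | None = None, mask=None):
    """Separable Gaussian smoothing (zero-padded boundary), optionally
    re-masked to the analysis mask afterwards."""
    spec = spec or SmoothingSpec()
    sigma = spec.sigma_vox(vmap.affine)
    sm = ndimage.gaussian_filter(
        np.asarray(vmap.data, dtype=float), sigma=sigma, mode="constant", cval=0.0
    )
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != vmap.grid_shape:
            raise InputError("mask grid does not match map grid")
        sm = np.where(mask, sm, 0.0)
    cls = type(vmap)
    if cls is FCDMap:
        return FCDMap(sm, vmap.affine.copy(), mask_size=getattr(vmap, "mask_size", 0))
    return cls(sm, vmap.affine.copy())


def rescale_map(vmap: FCDMap, mask: np.ndarray) -> FCDMap:
    """Divide by the in-mask mean, so the rescaled in-mask mean is 1."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vmap.grid_shape:
        raise InputError("mask grid does not match map grid")
    m = float(np.asarray(vmap.data, dtype=float)[mask].mean())
    if m <= 0:
        raise InputError(f"in-mask mean must be positive to rescale, got {m}")
    out = np.where(mask, np.asarray(vmap.data, dtype=float) / m, 0.0)
    return FCDMap(out, vmap.affine.copy(), mask_size=int(mask.sum()))


def group_hub_map(maps, mask: np.ndarray) -> FCDMap:
    """Voxel-wise mean of mean-rescaled gFCD maps: the group hub map."""
    maps = list(maps)
    if not maps:
        raise InputError("need at least one map")
    geom = maps[0].geometry
    acc = np.zeros(maps[0].grid_shape)
    for m in maps:
        geom.require_match(m.geometry, "gFCD map")
        acc += rescale_map(m, mask).data
    return FCDMap(acc / len(maps), maps[0].affine.copy(), mask_size=int(np.asarray(mask, bool).sum()))


class GFCDMapper(BaseEstimator, TransformerMixin):
    """Transformer computing a subject's gFCD map from preprocessed BOLD.

    Parameters mirror the analysis choices: correlation threshold, smoothing
    FWHM (``None`` to return raw counts), and the shared gray-matter mask.
    """

    def __init__(self, mask=None, r_threshold: float = 0.6, fwhm_mm=6.0,
                 chunk_size: int = 1024):
        self.mask = mask
        self.r_threshold = r_threshold
        self.fwhm_mm = fwhm_mm
        self.chunk_size = chunk_size

    def fit(self, X=None, y=None):
        if self.mask is None:
            raise InputError("a gray-matter mask is required")
        self.mask_size_ = int(np.asarray(self.mask, bool).sum())
        return self

    def transform(self, X):
        if not hasattr(self, "mask_size_"):
            self.fit()
        params = FcdParams(self.r_threshold, self.chunk_size)
        fcd = compute_gfcd(X, self.mask, params)
        if self.fwhm_mm is not None:
            fcd = smooth_map(fcd, SmoothingSpec(self.fwhm_mm), mask=self.mask)
        return fcd
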