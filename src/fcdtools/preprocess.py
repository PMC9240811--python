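"""Temporal preprocessing of BOLD series.

The in-scope chain (spatial alignment is assumed done — the simulator emits
data on a common grid): discard initial volumes, frame-wise displacement
(Jenkinson RMS form), nuisance regression of motion + motion derivatives +
mean white-matter/CSF signals + one-hot spike regressors for high-motion
volumes, and an ideal Fourier band-pass (default 0.01-0.08 Hz) after linear
detrending.

Spike handling is scrubbing-by-regression rather than volume deletion: a
one-hot column per volume whose FD strictly exceeds the threshold removes
that volume's influence while preserving the uniform temporal grid required
by the Fourier filter.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .types import BoldSeries, InputError, MotionTrace, NuisanceDesign

#: Head-radius convention (mm) of the Jenkinson RMS displacement measure.
JENKINSON_RADIUS_MM = 80.0


@dataclasses.dataclass(frozen=True)
class BandpassSpec:
    """Retained frequency band in Hz; must sit strictly below Nyquist."""

    low_hz: float = 0.01
    high_hz: float = 0.08

    def validate(self, tr_s: float):
        nyquist = 1.0 / (2.0 * tr_s)
        if not (0.0 < self.low_hz < self.high_hz):
            raise InputError(
                f"band limits must satisfy 0 < low < high, got "
                f"({self.low_hz}, {self.high_hz})"
            )
        if self.high_hz >= nyquist:
            raise InputError(
                f"high_hz={self.high_hz} must be below Nyquist "
                f"{nyquist:.4f} Hz for TR={tr_s}s"
            )


@dataclasses.dataclass
class PreprocessConfig:
    n_discard: int = 10
    fd_thresh_mm: float = 0.5
    band: BandpassSpec = dataclasses.field(default_factory=BandpassSpec)
    detrend: bool = True


def discard_initial(bold: BoldSeries, n_discard: int) -> BoldSeries:
    """Drop the first ``n_discard`` volumes (signal-equilibration period)."""
    if n_discard < 0:
        raise InputError("n_discard must be nonnegative")
    if n_discard >= bold.n_volumes:
        raise InputError(
            f"cannot discard {n_discard} of {bold.n_volumes} volumes"
        )
    return BoldSeries(bold.data[..., n_discard:].copy(), bold.affine.copy(), bold.tr_s)


def _rigid_transform(params6: np.ndarray) -> np.ndarray:
    """4x4 rigid transform from (tx, ty, tz, rx, ry, rz); rotations in
    radians applied about x, then y, then z."""
    tx, ty, tz, rx, ry, rz = params6
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    T = np.eye(4)
    T[:3, :3] = Rx @ Ry @ Rz
    T[:3, 3] = (tx, ty, tz)
    return T


def compute_fd(motion: MotionTrace, radius_mm: float = JENKINSON_RADIUS_MM) -> np.ndarray:
    """Frame-wise displacement, Jenkinson variant.

    For each volume i > 0, with M = T_i T_{i-1}^{-1} - I the relative rigid
    transform (A its 3x3 part, b its translation), FD_i is the RMS
    displacement of a solid sphere of radius ``radius_mm``:

        FD_i = sqrt( (R^2 / 5) * trace(A^T A) + b^T b )

    FD_0 is defined as 0. Depends only on relative transforms, so it is
    invariant to a constant offset in the motion parameters.
    """
    p = motion.params
    if not np.all(np.isfinite(p)):
        raise InputError("motion parameters contain non-finite values")
    n = p.shape[0]
    fd = np.zeros(n)
    prev = _rigid_transform(p[0])
    for i in range(1, n):
        cur = _rigid_transform(p[i])
        M = cur @ np.linalg.inv(prev) - np.eye(4)
        A = M[:3, :3]
        b = M[:3, 3]
        fd[i] = np.sqrt(radius_mm**2 / 5.0 * np.trace(A.T @ A) + b @ b)
        prev = cur
    return fd


def build_nuisance(
    motion: MotionTrace,
    bold: BoldSeries,
    wm_mask: np.ndarray,
    csf_mask: np.ndarray,
    fd: np.ndarray,
    fd_thresh_mm: float = 0.5,
) -> NuisanceDesign:
    """Nuisance design: 6 motion, 6 backward-difference derivatives (first
    row 0), mean WM and CSF signals, one one-hot column per volume with
    FD strictly above ``fd_thresh_mm``, and an intercept."""
    n = bold.n_volumes
    if motion.n_volumes != n:
        raise InputError(
            f"motion rows ({motion.n_volumes}) != BOLD volumes ({n})"
        )
    fd = np.asarray(fd, dtype=float)
    if fd.shape != (n,):
        raise InputError(f"FD length {fd.shape} does not match {n} volumes")
    wm_mask = np.asarray(wm_mask, dtype=bool)
    csf_mask = np.asarray(csf_mask, dtype=bool)
    for name, m in (("white-matter", wm_mask), ("CSF", csf_mask)):
        if m.shape != bold.grid_shape:
            raise InputError(f"{name} mask grid {m.shape} != BOLD grid {bold.grid_shape}")
        if not m.any():
            raise InputError(f"{name} mask is empty")

    motion_cols = motion.params
    deriv = np.zeros_like(motion_cols)
    deriv[1:] = np.diff(motion_cols, axis=0)
    wm_sig = bold.data[wm_mask].mean(axis=0)
    csf_sig = bold.data[csf_mask].mean(axis=0)

    cols = [motion_cols, deriv, wm_sig[:, None], csf_sig[:, None]]
    names = [
        "trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z",
        "dtrans_x", "dtrans_y", "dtrans_z", "drot_x", "drot_y", "drot_z",
        "wm_mean", "csf_mean",
    ]
    spike_idx = np.flatnonzero(fd > fd_thresh_mm)  # strict: "exceeded"
    for i in spike_idx:
        col = np.zeros((n, 1))
        col[i, 0] = 1.0
        cols.append(col)
        names.append(f"spike_{i}")
    cols.append(np.ones((n, 1)))
    names.append("intercept")
    return NuisanceDesign(np.hstack(cols), names)


def _check_full_rank(design: NuisanceDesign):
    X = design.matrix
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify the columns that fail to extend the column space
        offending = []
        kept = np.empty((X.shape[0], 0))
        for j, name in enumerate(design.names):
            cand = np.hstack([kept, X[:, j : j + 1]])
            if np.linalg.matrix_rank(cand) > kept.shape[1]:
                kept = cand
            else:
                offending.append(name)
        raise InputError(
            "nuisance design is rank deficient; collinear columns: "
            + ", ".join(offending)
        )


def regress_nuisance(bold: BoldSeries, design: NuisanceDesign) -> BoldSeries:
    """Per-voxel OLS residuals of the time series on the design columns."""
    X = design.matrix
    if X.shape[0] != bold.n_volumes:
        raise InputError(
            f"design rows ({X.shape[0]}) != BOLD volumes ({bold.n_volumes})"
        )
    _check_full_rank(design)
    shape = bold.data.shape
    Y = bold.data.reshape(-1, shape[3]).T  # (t, voxels)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return BoldSeries(resid.T.reshape(shape), bold.affine.copy(), bold.tr_s)


def bandpass(
    bold: BoldSeries, spec: BandpassSpec | None = None, detrend: bool = True
) -> BoldSeries:
    """Ideal (boxcar) Fourier band-pass per voxel, after linear detrend.

    DFT bins with low_hz <= f <= high_hz are retained; all others (including
    DC) are zeroed.
    """
    spec = spec or BandpassSpec()
    spec.validate(bold.tr_s)
    shape = bold.data.shape
    Y = bold.data.reshape(-1, shape[3])
    if detrend:
        Y = signal.detrend(Y, axis=1, type="linear")
    F = np.fft.rfft(Y, axis=1)
    freqs = np.fft.rfftfreq(shape[3], d=bold.tr_s)
    keep = (freqs >= spec.low_hz) & (freqs <= spec.high_hz)
    F[:, ~keep] = 0.0
    out = np.fft.irfft(F, n=shape[3], axis=1)
    return BoldSeries(out.reshape(shape), bold.affine.copy(), bold.tr_s)


def run_preprocess(
    bold: BoldSeries,
    motion: MotionTrace,
    wm_mask: np.ndarray,
    csf_mask: np.ndarray,
    config: PreprocessConfig | None = None,
):
    """Full temporal chain: discard -> FD -> nuisance regression -> band-pass.

    Returns (preprocessed BoldSeries, log dict). The log records the FD
    summary and spike count actually applied, for audit.
    """
    config = config or PreprocessConfig()
    config.band.validate(bold.tr_s)
    if motion.n_volumes != bold.n_volumes:
        raise InputError(
            f"motion rows ({motion.n_volumes}) != BOLD volumes ({bold.n_volumes})"
        )
    bold_d = discard_initial(bold, config.n_discard)
    motion_d = motion.discard_initial(config.n_discard)
    fd = compute_fd(motion_d)
    design = build_nuisance(
        motion_d, bold_d, wm_mask, csf_mask, fd, config.fd_thresh_mm
    )
    resid = regress_nuisance(bold_d, design)
    out = bandpass(resid, config.band, detrend=config.detrend)
    log = {
        "n_discard": config.n_discard,
        "n_volumes_out": out.n_volumes,
        "fd_thresh_mm": config.fd_thresh_mm,
        "fd_mean_mm": float(fd.mean()),
        "fd_max_mm": float(fd.max()),
        "n_spikes": len(design.spike_columns),
        "band_hz": [config.band.low_hz, config.band.high_hz],
        "detrend": config.detrend,
        "design_columns": design.n_columns,
    }
    return out, log


class BoldPreprocessor(BaseEstimator, TransformerMixin):
    """Scikit-learn style transformer wrapping :func:`run_preprocess`.

    ``transform`` takes a ``(BoldSeries, MotionTrace)`` pair and returns the
    preprocessed :class:`BoldSeries`. Tissue masks are constructor
    parameters because they are shared across all subjects of an analysis.
    """

    def __init__(
        self,
        wm_mask=None,
        csf_mask=None,
        n_discard: int = 10,
        fd_thresh_mm: float = 0.5,
        low_hz: float = 0.01,
        high_hz: float = 0.08,
        detrend: bool = True,
    ):
        self.wm_mask = wm_mask
        self.csf_mask = csf_mask
        self.n_discard = n_discard
        self.fd_thresh_mm = fd_thresh_mm
        self.low_hz = low_hz
        self.high_hz = high_hz
        self.detrend = detrend

    def _config(self) -> PreprocessConfig:
        return PreprocessConfig(
            n_discard=self.n_discard,
            fd_thresh_mm=self.fd_thresh_mm,
            band=BandpassSpec(self.low_hz, self.high_hz),
            detrend=self.detrend,
        )

    def fit(self, X=None, y=None):
        if self.wm_mask is None or self.csf_mask is None:
            raise InputError("wm_mask and csf_mask must be provided")
        self.n_fitted_ = 0
        return self

    def transform(self, X):
        if not hasattr(self, "n_fitted_"):
            self.fit()
        bold, motion = X
        out, log = run_preprocess(
            bold, motion, self.wm_mask, self.csf_mask, self._config()
        )
        self.last_log_ = log
        self.n_fitted_ += 1
        return out
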