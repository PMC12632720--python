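"""Static and dynamic functional network connectivity (FNC).

Given per-scan independent-component time courses (T timepoints x C
components, sampling interval TR seconds), this module

* denoises the time courses (polynomial detrending, optional nuisance
  regression, outlier clipping, zero-phase low-pass filtering),
* computes static FNC as the C x C Pearson correlation matrix over the
  whole scan,
* computes dynamic FNC with a tapered sliding window (rectangle of
  length L TRs convolved with a Gaussian kernel), yielding one
  correlation matrix per window position,
* vectorizes matrices to the strict upper triangle (row-major), and
* slices matrices/tensors down to one functional network.

Defaults follow the dFNC literature: L = 20 TR, Gaussian sigma = 3 TR,
stride 1 TR, low-pass cut-off 0.15 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np
from scipy import signal

from .partition import NetworkPartition

__all__ = [
    "DegenerateDataError",
    "Timecourses",
    "CleanOptions",
    "clean_timecourses",
    "pearson",
    "weighted_pearson",
    "ConnectivityMatrix",
    "compute_sfnc",
    "TaperedWindow",
    "make_taper",
    "DFNCTensor",
    "compute_dfnc",
    "vectorize_upper",
    "matrix_from_upper",
    "subnetwork_slice",
    "window_duration_seconds",
    "fisher_z",
]


class DegenerateDataError(ValueError):
    """Raised when an input has no variance where correlation is required."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class Timecourses:
    """One scan's component time courses.

    ``data`` is T x C (rows = timepoints); ``tr`` is the repetition time
    in seconds.
    """

    data: np.ndarray
    tr: float
    subject_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise ValueError("time courses must be a T x C matrix with T >= 2")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time courses contain non-finite values")
        if not (np.isfinite(self.tr) and self.tr > 0):
            raise ValueError(f"TR must be positive and finite, got {self.tr}")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_components(self) -> int:
        return self.data.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric C x C correlation matrix with unit diagonal."""

    values: np.ndarray
    labels: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-8):
            raise ValueError("connectivity matrix must have unit diagonal")
        if np.nanmax(np.abs(v)) > 1 + 1e-8:
            raise ValueError("correlations must lie in [-1, 1]")
        self.values = v
        if self.labels is not None and len(self.labels) != v.shape[0]:
            raise ValueError("labels must align with matrix dimension")

    @property
    def n_components(self) -> int:
        return self.values.shape[0]


@dataclass
class TaperedWindow:
    """Sliding-window taper: rectangle convolved with a Gaussian kernel."""

    length: int
    sigma: float
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if self.length < 3:
            raise ValueError("window length must be >= 3 TRs")
        if w.shape != (self.length,):
            raise ValueError("weights must have length L")
        if np.any(w < 0) or w.max() <= 0:
            raise ValueError("weights must be nonnegative with a positive peak")
        if not np.allclose(w, w[::-1], atol=1e-10):
            raise ValueError("taper weights must be symmetric")
        self.weights = w


@dataclass
class DFNCTensor:
    """Windowed dynamic FNC: W x C x C array of correlation matrices.

    ``starts`` holds each window's 0-based start index; window w covers
    TRs [starts[w], starts[w] + length).
    """

    windows: np.ndarray
    starts: np.ndarray
    stride: int
    length: int
    labels: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        w = np.asarray(self.windows, dtype=float)
        if w.ndim != 3 or w.shape[1] != w.shape[2]:
            raise ValueError("dFNC tensor must be W x C x C")
        self.windows = w
        self.starts = np.asarray(self.starts, dtype=int)
        if self.starts.shape != (w.shape[0],):
            raise ValueError("starts must align with the window axis")

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def n_components(self) -> int:
        return self.windows.shape[1]


# ---------------------------------------------------------------------------
# denoising


@dataclass
class CleanOptions:
    """Switches for :func:`clean_timecourses` (all stages optional)."""

    detrend_order: int = 3              # 0 disables; 1-3 = poly degree removed
    nuisance: Optional[np.ndarray] = None   # T x k regressors (e.g. motion)
    nuisance_derivatives: bool = True   # augment with temporal derivatives
    clip_mad: Optional[float] = 3.5     # clip beyond k scaled-MADs; None disables
    lowpass_hz: Optional[float] = 0.15  # None disables
    filter_order: int = 5               # Butterworth order (zero-phase)


def clean_timecourses(tc: Timecourses, opts: CleanOptions = CleanOptions()) -> Timecourses:
    """Denoise component time courses.

    Stages (each skipped when disabled): least-squares removal of a
    polynomial trend up to cubic order; regression of supplied nuisance
    covariates (plus their temporal derivatives); clipping of samples
    beyond ``clip_mad`` scaled median absolute deviations per column;
    zero-phase Butterworth low-pass below ``lowpass_hz``.
    """
    x = tc.data.copy()
    T = x.shape[0]

    if opts.detrend_order:
        order = int(opts.detrend_order)
        if not 1 <= order <= 3:
            raise ValueError("detrend_order must be in {0,1,2,3}")
        if T <= order + 1:
            raise ValueError(f"need T > {order + 1} timepoints for order-{order} detrending")
        t = np.linspace(-1.0, 1.0, T)
        basis = np.vander(t, order + 1, increasing=True)  # 1, t, ..., t^order
        coef, *_ = np.linalg.lstsq(basis, x, rcond=None)
        x = x - basis @ coef

    if opts.nuisance is not None:
        nuis = np.asarray(opts.nuisance, dtype=float)
        if nuis.ndim == 1:
            nuis = nuis[:, None]
        if nuis.shape[0] != T:
            raise ValueError("nuisance regressors must have one row per timepoint")
        if opts.nuisance_derivatives:
            deriv = np.gradient(nuis, axis=0)
            nuis = np.hstack([nuis, deriv])
        design = np.column_stack([np.ones(T), nuis])
        coef, *_ = np.linalg.lstsq(design, x, rcond=None)
        x = x - design @ coef

    if opts.clip_mad is not None:
        med = np.median(x, axis=0)
        mad = np.median(np.abs(x - med), axis=0) * 1.4826  # consistent for a Gaussian
        ok = mad > 0
        lo = med - opts.clip_mad * mad
        hi = med + opts.clip_mad * mad
        x[:, ok] = np.clip(x[:, ok], lo[ok], hi[ok])

    if opts.lowpass_hz is not None:
        nyquist = 1.0 / (2.0 * tc.tr)
        if opts.lowpass_hz >= nyquist:
            raise ValueError(
                f"low-pass cut-off {opts.lowpass_hz} Hz is at or above the Nyquist "
                f"frequency {nyquist:.4g} Hz for TR={tc.tr} s"
            )
        sos = signal.butter(opts.filter_order, opts.lowpass_hz, btype="low",
                            fs=1.0 / tc.tr, output="sos")
        x = signal.sosfiltfilt(sos, x, axis=0)

    return replace(tc, data=x)


# ---------------------------------------------------------------------------
# correlation primitives


def pearson(x1: np.ndarray, x2: np.ndarray) -> float:
    """Pearson correlation of two equal-length series.

    r = sum((x1-m1)(x2-m2)) / sqrt(sum((x1-m1)^2) sum((x2-m2)^2)),
    the strength of the linear relationship, in [-1, 1].
    """
    x1 = np.asarray(x1, dtype=float).ravel()
    x2 = np.asarray(x2, dtype=float).ravel()
    if x1.shape != x2.shape or x1.size < 2:
        raise ValueError("inputs must be equal-length series with at least 2 samples")
    d1 = x1 - x1.mean()
    d2 = x2 - x2.mean()
    v1 = float(d1 @ d1)
    v2 = float(d2 @ d2)
    if v1 == 0.0 or v2 == 0.0:
        raise DegenerateDataError("zero-variance input: correlation undefined")
    r = float(d1 @ d2) / np.sqrt(v1 * v2)
    return float(np.clip(r, -1.0, 1.0))


def weighted_pearson(x1: np.ndarray, x2: np.ndarray, weights: np.ndarray) -> float:
    """Weighted Pearson correlation; weights enter mean, covariance and
    variances identically. Uniform weights reduce to :func:`pearson`."""
    x1 = np.asarray(x1, dtype=float).ravel()
    x2 = np.asarray(x2, dtype=float).ravel()
    w = np.asarray(weights, dtype=float).ravel()
    if not (x1.shape == x2.shape == w.shape) or x1.size < 2:
        raise ValueError("series and weights must share a length >= 2")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    wn = w / w.sum()
    d1 = x1 - wn @ x1
    d2 = x2 - wn @ x2
    v1 = float(wn @ (d1 * d1))
    v2 = float(wn @ (d2 * d2))
    if v1 == 0.0 or v2 == 0.0:
        raise DegenerateDataError("zero weighted variance: correlation undefined")
    r = float(wn @ (d1 * d2)) / np.sqrt(v1 * v2)
    return float(np.clip(r, -1.0, 1.0))


def _weighted_corr_matrix(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted correlation matrix of columns of x (L x C) under weights (L,)."""
    wn = weights / weights.sum()
    mu = wn @ x
    xc = x - mu
    cov = xc.T @ (xc * wn[:, None])
    var = np.diag(cov).copy()
    # relative floor: constant columns leave only rounding-error variance
    floor = 1e-15 * np.maximum(wn @ (x * x), 1e-300)
    if np.any(var <= floor):
        raise DegenerateDataError("zero weighted variance in at least one component")
    d = 1.0 / np.sqrt(var)
    corr = cov * np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def compute_sfnc(tc: Timecourses, labels: Optional[tuple[str, ...]] = None) -> ConnectivityMatrix:
    """Static FNC: Pearson correlation between every pair of components."""
    x = tc.data
    var = x.var(axis=0)
    if np.any(var == 0):
        bad = int(np.flatnonzero(var == 0)[0])
        raise DegenerateDataError(f"component {bad} has zero variance over the scan")
    corr = _weighted_corr_matrix(x, np.ones(x.shape[0]))
    corr = (corr + corr.T) / 2.0
    return ConnectivityMatrix(values=corr, labels=labels)


# ---------------------------------------------------------------------------
# tapered sliding window


def make_taper(length: int, sigma: float) -> TaperedWindow:
    """Rectangular window of ``length`` TRs convolved with a Gaussian
    kernel of standard deviation ``sigma`` TRs.

    The kernel is truncated at +/- 4 sigma, the central ``length``
    samples of the full convolution are retained and the peak is
    normalized to 1. As sigma -> 0 the taper tends to the rectangle.
    """
    if length < 3:
        raise ValueError("window length must be >= 3 TRs")
    if not (np.isfinite(sigma) and sigma > 0):
        raise ValueError("sigma must be positive")
    rect = np.ones(length)
    radius = max(1, int(np.ceil(4.0 * sigma)))
    t = np.arange(-radius, radius + 1, dtype=float)
    kernel = np.exp(-0.5 * (t / sigma) ** 2)
    kernel /= kernel.sum()
    full = np.convolve(rect, kernel, mode="full")  # length L + 2*radius
    start = (full.size - length) // 2
    w = full[start:start + length]
    w = w / w.max()
    w = (w + w[::-1]) / 2.0  # enforce exact symmetry against fp rounding
    return TaperedWindow(length=length, sigma=float(sigma), weights=w)


def window_duration_seconds(length: int, tr: float) -> float:
    """Duration of an ``length``-TR window in seconds (L * TR)."""
    return float(length) * float(tr)


def compute_dfnc(
    tc: Timecourses,
    window: TaperedWindow,
    stride: int = 1,
    labels: Optional[tuple[str, ...]] = None,
) -> DFNCTensor:
    """Dynamic FNC by tapered sliding-window correlation.

    For each window start s in {0, stride, 2*stride, ...} the weighted
    Pearson correlation of all component pairs is computed over TRs
    [s, s+L), giving W = floor((T - L) / stride) + 1 matrices.
    """
    x = tc.data
    T, C = x.shape
    L = window.length
    if T < L:
        raise ValueError(f"scan has T={T} < window length L={L}")
    if stride < 1:
        raise ValueError("stride must be a positive number of TRs")
    n_win = (T - L) // stride + 1
    starts = np.arange(n_win) * stride
    # (n_positions, C, L) view; subsample by stride
    view = np.lib.stride_tricks.sliding_window_view(x, L, axis=0)[::stride]
    w = window.weights
    wn = w / w.sum()
    mu = np.einsum("wcl,l->wc", view, wn)
    xc = view - mu[:, :, None]
    cov = np.einsum("wcl,wdl,l->wcd", xc, xc, wn, optimize=True)
    var = np.einsum("wcc->wc", cov).copy()
    floor = 1e-15 * np.maximum(np.einsum("wcl,l->wc", view * view, wn), 1e-300)
    bad = np.nonzero(var <= floor)
    if bad[0].size:
        raise DegenerateDataError(
            f"zero weighted variance in window {int(bad[0][0])} "
            f"(component {int(bad[1][0])})"
        )
    d = 1.0 / np.sqrt(var)
    corr = cov * d[:, :, None] * d[:, None, :]
    corr = (corr + corr.transpose(0, 2, 1)) / 2.0
    corr = np.clip(corr, -1.0, 1.0)
    idx = np.arange(C)
    corr[:, idx, idx] = 1.0
    return DFNCTensor(windows=corr, starts=starts, stride=int(stride), length=L,
                      labels=labels)


# ---------------------------------------------------------------------------
# features and slicing


def vectorize_upper(m: Union[ConnectivityMatrix, np.ndarray]) -> np.ndarray:
    """Strict upper triangle in row-major order: (0,1), (0,2), ..., (C-2,C-1).

    Length C(C-1)/2; for the 53-component template this is 1378 features.
    :func:`matrix_from_upper` is the documented inverse.
    """
    v = m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m, dtype=float)
    if v.ndim != 2 or v.shape[0] != v.shape[1]:
        raise ValueError("expected a square matrix")
    iu = np.triu_indices(v.shape[0], k=1)
    return v[iu].copy()


def matrix_from_upper(vec: np.ndarray, diagonal: float = 1.0) -> np.ndarray:
    """Reconstruct the symmetric matrix whose strict upper triangle is ``vec``."""
    vec = np.asarray(vec, dtype=float).ravel()
    # solve p = C(C-1)/2 for C
    c = int(round((1 + np.sqrt(1 + 8 * vec.size)) / 2))
    if c * (c - 1) // 2 != vec.size:
        raise ValueError(f"vector length {vec.size} is not a triangular number")
    out = np.full((c, c), 0.0)
    iu = np.triu_indices(c, k=1)
    out[iu] = vec
    out = out + out.T
    np.fill_diagonal(out, diagonal)
    return out


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Fisher z-transform (arctanh), off by default everywhere in the pipeline."""
    return np.arctanh(np.clip(np.asarray(r, dtype=float), -1 + 1e-12, 1 - 1e-12))


def subnetwork_slice(
    obj: Union[ConnectivityMatrix, DFNCTensor],
    partition: NetworkPartition,
    network: str,
) -> Union[ConnectivityMatrix, DFNCTensor]:
    """Restrict a connectivity matrix or dFNC tensor to one network's
    components (order preserved; applied per window for tensors)."""
    idx = partition.indices(network)  # raises KeyError listing valid labels
    sel = np.asarray(idx)
    if isinstance(obj, ConnectivityMatrix):
        if obj.n_components != partition.n_components:
            raise ValueError("partition size does not match matrix dimension")
        sub = obj.values[np.ix_(sel, sel)]
        labs = tuple(obj.labels[i] for i in idx) if obj.labels else None
        return ConnectivityMatrix(values=sub, labels=labs)
    if isinstance(obj, DFNCTensor):
        if obj.n_components != partition.n_components:
            raise ValueError("partition size does not match tensor dimension")
        sub = obj.windows[:, sel[:, None], sel[None, :]]
        labs = tuple(obj.labels[i] for i in idx) if obj.labels else None
        return DFNCTensor(windows=sub, starts=obj.starts, stride=obj.stride,
                          length=obj.length, labels=labs)
    raise TypeError("expected a ConnectivityMatrix or DFNCTensor")
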