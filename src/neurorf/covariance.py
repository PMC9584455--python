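"""Structured covariance models of sensory receptive fields.

A receptive field is modeled as a sample from a zero-mean Gaussian process
whose covariance encodes the structure seen in a sensory population:

* ``build_stationary_cov`` — a stationary (Toeplitz) covariance built from a
  bandlimited sum of harmonics on [0, L); its eigenbasis is the Fourier basis.
* ``build_sensilla_cov`` — the insect-mechanosensor model: the stationary
  bandlimited process modulated by a decaying exponential envelope
  ``exp(-(t + t') / gamma)`` that localizes fields near t = 0.
* ``build_v1_cov`` — the V1 simple-cell model: a Gaussian (squared-
  exponential) kernel in pixel space, localized to a center c by Gaussian
  envelopes; its eigenbasis consists of single-scale Hermite wavelets.
* ``build_null_cov`` — reference null models (unstructured identity,
  pure Fourier, translation-invariant V1).

All constructors return a :class:`CovarianceModel` holding the matrix, its
grid, the generating parameters and a cached eigendecomposition, and are
trace-normalized so that Tr(C) = d (the grid size) unless stated otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.linalg import eigh, toeplitz

from .grids import Grid1D, Grid2D

__all__ = [
    "SensillaParams",
    "V1Params",
    "CovarianceModel",
    "build_stationary_cov",
    "build_sensilla_cov",
    "build_v1_cov",
    "build_null_cov",
    "normalize_trace",
    "eigendecompose",
    "hermite_eigenbasis",
    "hermite_constants",
    "select_harmonics",
]

# Relative tolerance for PSD repair: eigenvalues in [-PSD_TOL*max, 0) are
# clipped to zero; anything more negative is treated as a genuine error.
PSD_TOL = 1e-8


@dataclass(frozen=True)
class SensillaParams:
    """Parameters of the mechanosensor (campaniform sensilla) covariance.

    f_lo_hz, f_hi_hz : passband edges of the bandlimited spectrum, in Hz.
    gamma_ms : decay constant of the exponential envelope, in ms.
    """

    f_lo_hz: float
    f_hi_hz: float
    gamma_ms: float

    def __post_init__(self) -> None:
        if not (0 <= self.f_lo_hz <= self.f_hi_hz):
            raise ValueError(
                f"require 0 <= f_lo <= f_hi, got ({self.f_lo_hz}, {self.f_hi_hz})"
            )
        if self.gamma_ms <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma_ms}")


@dataclass(frozen=True)
class V1Params:
    """Parameters of the V1 simple-cell covariance.

    size_px : receptive-field size s (Gaussian envelope scale), in pixels.
    freq_px : spatial-frequency bandwidth f (kernel length scale), in pixels.
    center : receptive-field center c as a (row, col) pixel pair.
    """

    size_px: float
    freq_px: float
    center: tuple[float, float]

    def __post_init__(self) -> None:
        if self.size_px <= 0:
            raise ValueError(f"size s must be positive, got {self.size_px}")
        if self.freq_px <= 0:
            raise ValueError(f"frequency f must be positive, got {self.freq_px}")


@dataclass
class CovarianceModel:
    """A d x d PSD covariance with grid metadata and cached eigensystem.

    ``eigenvectors`` columns are orthonormal, ordered by descending
    ``eigenvalues`` (the lambda_i^2 of the Karhunen-Loeve expansion), with
    sign fixed so each column's largest-magnitude entry is positive.
    """

    C: np.ndarray
    grid: Grid1D | Grid2D
    kind: str
    params: dict = field(default_factory=dict)
    _eigvals: np.ndarray | None = None
    _eigvecs: np.ndarray | None = None

    @property
    def d(self) -> int:
        return self.C.shape[0]

    @property
    def trace(self) -> float:
        return float(np.trace(self.C))

    def _ensure_eig(self) -> None:
        if self._eigvals is None:
            vals, vecs = eigendecompose(self.C)
            self._eigvals = vals
            self._eigvecs = vecs

    @property
    def eigenvalues(self) -> np.ndarray:
        self._ensure_eig()
        return self._eigvals

    @property
    def eigenvectors(self) -> np.ndarray:
        self._ensure_eig()
        return self._eigvecs

    def factor(self) -> np.ndarray:
        """Return Phi @ diag(Lambda), the Karhunen-Loeve factor (C = F F^T)."""
        return self.eigenvectors * np.sqrt(self.eigenvalues)


def select_harmonics(grid: Grid1D, f_lo_hz: float, f_hi_hz: float) -> np.ndarray:
    """Indices k of natural harmonics omega_k = 2*pi*k/L inside the passband.

    Band edges are inclusive; the constant term k = 0 is included only when
    f_lo = 0. Raises if the passband selects no harmonic or exceeds Nyquist.
    """
    if f_hi_hz > grid.nyquist_hz:
        raise ValueError(
            f"passband edge {f_hi_hz} Hz exceeds Nyquist {grid.nyquist_hz} Hz"
        )
    df = 1.0 / grid.duration_s  # harmonic spacing in Hz
    k_max = grid.n_samples // 2
    ks = np.arange(0, k_max + 1)
    freqs = ks * df
    mask = (freqs >= f_lo_hz) & (freqs <= f_hi_hz)
    if f_lo_hz > 0:
        mask &= ks > 0
    ks = ks[mask]
    if ks.size == 0:
        raise ValueError(
            f"empty passband: no harmonic of spacing {df:.4g} Hz lies in "
            f"[{f_lo_hz}, {f_hi_hz}] Hz on a {grid.n_samples}-point grid"
        )
    return ks


def _stationary_first_row(
    grid: Grid1D, ks: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """First row c(tau) = sum_k lambda_k^2 cos(omega_k tau) on the grid lags."""
    tau = grid.times_s  # lags 0..(d-1)*dt
    omega = 2.0 * np.pi * ks / grid.duration_s
    return (weights[None, :] * np.cos(tau[:, None] * omega[None, :])).sum(axis=1)


def build_stationary_cov(
    grid: Grid1D,
    passband_hz: tuple[float, float],
    weights: Mapping[int, float] | None = None,
    trace_target: float | None = None,
) -> CovarianceModel:
    """Stationary bandlimited covariance C(t,t') = sum_k lambda_k^2 cos(omega_k (t-t')).

    Harmonics with omega_k/(2*pi) inside ``passband_hz`` (inclusive) get
    lambda_k^2 = 1 by default, or the value supplied in ``weights`` (a mapping
    from harmonic index k to a nonnegative lambda_k^2). The result is exactly
    Toeplitz and trace-normalized to d unless ``trace_target`` overrides it.
    """
    f_lo, f_hi = passband_hz
    ks = select_harmonics(grid, f_lo, f_hi)
    if weights is None:
        lam2 = np.ones(ks.size)
    else:
        lam2 = np.array([float(weights.get(int(k), 0.0)) for k in ks])
        if np.any(lam2 < 0):
            raise ValueError("harmonic weights lambda_k^2 must be nonnegative")
    row = _stationary_first_row(grid, ks, lam2)
    C = toeplitz(row)
    model = CovarianceModel(
        C=C,
        grid=grid,
        kind="stationary",
        params={"f_lo_hz": f_lo, "f_hi_hz": f_hi, "weights": dict(weights or {})},
    )
    return normalize_trace(model, grid.size if trace_target is None else trace_target)


def build_sensilla_cov(
    grid: Grid1D, params: SensillaParams, trace_target: float | None = None
) -> CovarianceModel:
    """Mechanosensor covariance: exponential envelope times bandlimited process.

    C(t,t') = exp(-(t+t')/gamma) * sum_k lambda_k^2 cos(omega_k (t-t')) with
    lambda_k = 1 for f_lo <= omega_k/(2*pi) <= f_hi and 0 outside. gamma acts
    as a decay constant (time window) so the envelope is exp(-(t+t')/gamma).
    Trace-normalized to d by default.
    """
    ks = select_harmonics(grid, params.f_lo_hz, params.f_hi_hz)
    lam2 = np.ones(ks.size)
    row = _stationary_first_row(grid, ks, lam2)
    S = toeplitz(row)
    env = np.exp(-grid.times_ms / params.gamma_ms)
    C = env[:, None] * S * env[None, :]
    model = CovarianceModel(
        C=C,
        grid=grid,
        kind="sensilla",
        params={
            "f_lo_hz": params.f_lo_hz,
            "f_hi_hz": params.f_hi_hz,
            "gamma_ms": params.gamma_ms,
        },
    )
    return normalize_trace(model, grid.size if trace_target is None else trace_target)


def build_v1_cov(
    grid: Grid2D, params: V1Params, trace_target: float | None = None
) -> CovarianceModel:
    """V1 simple-cell covariance on a flattened pixel grid.

    C(t,t') = exp(-||t-t'||^2 / (2 f^2)) * exp(-(||t-c||^2 + ||t'-c||^2) / (2 s^2))

    where t, t' range over pixel coordinates and c is the field center.
    Trace-normalized to the number of pixels by default.
    """
    if not grid.contains(params.center):
        raise ValueError(
            f"center {params.center} outside grid of shape {grid.shape}"
        )
    pts = grid.coords
    c = np.asarray(params.center, dtype=float)
    sq_dist = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=-1)
    K = np.exp(-sq_dist / (2.0 * params.freq_px**2))
    g = np.exp(-((pts - c) ** 2).sum(axis=1) / (2.0 * params.size_px**2))
    C = g[:, None] * K * g[None, :]
    model = CovarianceModel(
        C=C,
        grid=grid,
        kind="v1",
        params={
            "size_px": params.size_px,
            "freq_px": params.freq_px,
            "center": tuple(params.center),
        },
    )
    return normalize_trace(model, grid.size if trace_target is None else trace_target)


def build_null_cov(
    kind: str,
    grid: Grid1D | Grid2D,
    params: dict | None = None,
    trace_target: float | None = None,
) -> CovarianceModel:
    """Null covariance models used as baselines.

    kind = "unstructured": identity (spherical Gaussian weights).
    kind = "fourier": the stationary bandlimited model (1-D grids;
        params must give ``f_lo_hz``/``f_hi_hz``).
    kind = "v1_translation_invariant": the V1 kernel with the localizing
        envelope removed, parameterized by ``freq_px`` alone (2-D grids).
    """
    params = params or {}
    target = trace_target
    if kind == "unstructured":
        d = grid.size
        C = np.eye(d)
        model = CovarianceModel(C=C, grid=grid, kind="unstructured", params={})
        return normalize_trace(model, d if target is None else target)
    if kind == "fourier":
        if not isinstance(grid, Grid1D):
            raise ValueError("fourier null model requires a 1-D grid")
        return build_stationary_cov(
            grid,
            (params["f_lo_hz"], params["f_hi_hz"]),
            trace_target=target,
        )
    if kind == "v1_translation_invariant":
        if not isinstance(grid, Grid2D):
            raise ValueError("v1_translation_invariant null model requires a 2-D grid")
        f = float(params["freq_px"])
        if f <= 0:
            raise ValueError(f"frequency f must be positive, got {f}")
        pts = grid.coords
        sq_dist = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=-1)
        C = np.exp(-sq_dist / (2.0 * f**2))
        model = CovarianceModel(
            C=C, grid=grid, kind="v1_translation_invariant", params={"freq_px": f}
        )
        return normalize_trace(model, grid.size if target is None else target)
    raise ValueError(f"unknown null model kind: {kind!r}")


def normalize_trace(model: CovarianceModel, target: float) -> CovarianceModel:
    """Rescale C so that Tr(C) equals ``target``; eigenvalues scale with it."""
    tr = model.trace
    if tr <= 0:
        raise ValueError(f"cannot normalize: trace is {tr}")
    if target <= 0:
        raise ValueError(f"trace target must be positive, got {target}")
    scale = target / tr
    model._ensure_eig()
    new = replace(model, C=model.C * scale)
    new._eigvals = model._eigvals * scale
    new._eigvecs = model._eigvecs
    new.params = dict(model.params)
    return new


def eigendecompose(C: np.ndarray, sym_tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of a symmetric PSD matrix with fixed conventions.

    Returns (eigenvalues, eigenvectors) with eigenvalues sorted descending,
    small negative values (>= -PSD_TOL * max) clipped to zero with a warning,
    and each eigenvector's sign fixed so its largest-magnitude entry is
    positive. Raises on asymmetry or substantially negative spectrum.
    """
    C = np.asarray(C, dtype=float)
    asym = np.abs(C - C.T).max()
    scale = max(np.abs(C).max(), 1.0)
    if asym > sym_tol * scale:
        raise ValueError(f"matrix is not symmetric (max asymmetry {asym:.3g})")
    Cs = 0.5 * (C + C.T)
    vals, vecs = eigh(Cs)
    vals = vals[::-1].copy()
    vecs = vecs[:, ::-1].copy()
    vmax = max(vals.max(), 0.0)
    floor = -PSD_TOL * max(vmax, 1e-300)
    if vals.min() < floor:
        raise ValueError(
            f"matrix is not PSD: min eigenvalue {vals.min():.3g} below "
            f"tolerance {floor:.3g}"
        )
    if np.any(vals < 0):
        if vals.min() < -1e-12 * max(vmax, 1e-300):
            warnings.warn(
                f"clipping negative eigenvalues (min {vals.min():.3g}) to zero",
                stacklevel=2,
            )
        vals = np.clip(vals, 0.0, None)
    # deterministic sign: largest-|.| entry of each eigenvector positive
    idx = np.abs(vecs).argmax(axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    vecs = vecs * signs
    return vals, vecs


def hermite_constants(size_px: float, freq_px: float) -> tuple[float, float, float]:
    """Closed-form constants (c1, c2, c3) of the Hermite-wavelet eigensystem.

    For the 1-D kernel exp(-(t-t')^2/(2 f^2)) * exp(-(t^2+t'^2)/(2 s^2)),
    write a = 1/(2 s^2) and b = 1/(2 f^2). Substituting phi = exp(-a t^2) psi
    reduces the eigenproblem to the classical Gaussian-kernel/Gaussian-measure
    problem, whose solutions give

        c  = sqrt(a^2 + 2 a b)     (Gaussian decay of the eigenfunctions)
        c1 = c,  c2 = sqrt(2 c),   c3 = b / (a + b + c)  (eigenvalue ratio)

    so phi_k(t) is proportional to exp(-c1 t^2) H_k(c2 t) with eigenvalue
    proportional to c3^k; multidimensional solutions are products over axes.
    """
    a = 1.0 / (2.0 * size_px**2)
    b = 1.0 / (2.0 * freq_px**2)
    c = np.sqrt(a * a + 2.0 * a * b)
    c1 = c
    c2 = np.sqrt(2.0 * c)
    c3 = b / (a + b + c)
    return float(c1), float(c2), float(c3)


def hermite_eigenbasis(
    grid: Grid2D, params: V1Params, k_max: int
) -> tuple[np.ndarray, np.ndarray]:
    """Leading analytic eigenfunctions/eigenvalues of the V1 covariance.

    Returns ``(Phi, lam2)`` where ``Phi`` is (n_pixels, k_max) with columns
    the Hermite wavelets phi_k(t) = prod_i exp(-c1 u_i^2) H_{k_i}(c2 u_i)
    (u = t - c, physicists' Hermite polynomials H) evaluated on the grid and
    normalized to unit grid norm, and ``lam2`` the eigenvalues c3^(k_1+k_2)
    normalized to sum to 1 over the returned set. Ordering is by descending
    eigenvalue (ascending total order), ties broken by k_1.

    The discrete columns are near- but not exactly orthogonal: the analytic
    functions are orthogonal in continuous space and discretization on a
    pixel grid perturbs them.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if k_max > grid.size:
        raise ValueError(f"k_max={k_max} exceeds grid size {grid.size}")
    c1, c2, c3 = hermite_constants(params.size_px, params.freq_px)
    # enumerate multi-indices by total order until we have k_max of them
    indices: list[tuple[int, int]] = []
    order = 0
    while len(indices) < k_max:
        for k1 in range(order + 1):
            indices.append((k1, order - k1))
        order += 1
    indices = indices[:k_max]

    pts = grid.coords - np.asarray(params.center, dtype=float)
    u_r, u_c = pts[:, 0], pts[:, 1]
    env = np.exp(-c1 * (u_r**2 + u_c**2))

    def herm(k: int, u: np.ndarray) -> np.ndarray:
        coeffs = np.zeros(k + 1)
        coeffs[k] = 1.0
        return np.polynomial.hermite.hermval(c2 * u, coeffs)

    cols = []
    lam2 = []
    for k1, k2 in indices:
        col = env * herm(k1, u_r) * herm(k2, u_c)
        nrm = np.linalg.norm(col)
        if nrm == 0:
            raise ValueError(f"eigenfunction ({k1},{k2}) vanishes on this grid")
        cols.append(col / nrm)
        lam2.append(c3 ** (k1 + k2))
    Phi = np.column_stack(cols)
    lam2 = np.asarray(lam2)
    lam2 = lam2 / lam2.sum()
    return Phi, lam2
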