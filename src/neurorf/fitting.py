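"""Fit covariance-model parameters to receptive-field data.

The data covariance is the trace-normalized Gram matrix of the measured
fields. Model parameters are chosen to minimize the normalized Frobenius
distance ||C_data - C_model||_F / ||C_data||_F, with both matrices
normalized to the same trace. The search runs a coarse grid (band edges on
the harmonic lattice for temporal models, log/linear grids for continuous
parameters) followed by a derivative-free local polish of the continuous
parameters.

Spectral diagnostics compare eigenvalue curves (each summing to 1 under
unit-trace normalization), leading eigenvectors, variance-explained
fractions, and principal subspace angles across data, model, and
finite-sample model covariances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import subspace_angles
from scipy.optimize import minimize, minimize_scalar

from .covariance import (
    CovarianceModel,
    SensillaParams,
    V1Params,
    build_null_cov,
    build_sensilla_cov,
    build_stationary_cov,
    build_v1_cov,
    normalize_trace,
)
from .grids import Grid1D, Grid2D
from .sampling import ReceptiveFieldSet, empirical_covariance, sample_weights

__all__ = [
    "FitResult",
    "SpectralReport",
    "center_receptive_fields",
    "frobenius_distance",
    "fit_covariance_params",
    "finite_sample_covariance",
    "spectral_compare",
]


@dataclass
class FitResult:
    """Best-fit parameters with the full evaluation trace."""

    kind: str
    params: dict
    distance: float
    trace: list[tuple[dict, float]] = field(default_factory=list)
    null_distances: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trace and self.distance > min(d for _, d in self.trace) + 1e-12:
            raise ValueError("best distance exceeds a trace entry")


@dataclass
class SpectralReport:
    """Eigen-spectra and leading-subspace comparison of covariance matrices."""

    eigenvalue_curves: dict  # name -> eigenvalues (unit sum)
    leading_eigenvectors: dict  # name -> (d, k) matrix
    variance_explained: np.ndarray  # cumulative, data, length k
    principal_angles_rad: np.ndarray  # data vs model, leading-k subspaces
    k: int


def center_receptive_fields(rfs: ReceptiveFieldSet) -> ReceptiveFieldSet:
    """Translate each 2-D field so its energy center of mass sits at the grid
    center.

    The center of mass is computed with squared-magnitude weights, rounded to
    the nearest pixel, and the field is shifted by an integer offset with
    zero padding (no interpolation, so fields are not smoothed). All-zero
    fields are left in place with a warning. The operation is idempotent.
    """
    grid = rfs.grid
    if not isinstance(grid, Grid2D):
        raise ValueError("centering requires a 2-D grid")
    h, w = grid.shape
    target = np.asarray(grid.center)
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    W_out = np.zeros_like(rfs.W)
    for i, flat in enumerate(rfs.W):
        fld = flat.reshape(h, w)
        energy = fld**2
        tot = energy.sum()
        if tot == 0:
            warnings.warn(f"field {i} is all-zero; left unshifted", stacklevel=2)
            W_out[i] = flat
            continue
        com_r = (energy * rows).sum() / tot
        com_c = (energy * cols).sum() / tot
        shift = target - np.round([com_r, com_c]).astype(int)
        shifted = np.zeros_like(fld)
        src_r = slice(max(0, -shift[0]), min(h, h - shift[0]))
        src_c = slice(max(0, -shift[1]), min(w, w - shift[1]))
        dst_r = slice(max(0, shift[0]), min(h, h + shift[0]))
        dst_c = slice(max(0, shift[1]), min(w, w + shift[1]))
        shifted[dst_r, dst_c] = fld[src_r, src_c]
        W_out[i] = shifted.ravel()
    out = ReceptiveFieldSet(W=W_out, grid=grid, provenance=dict(rfs.provenance))
    out.provenance["centered"] = True
    return out


def frobenius_distance(C_data: np.ndarray | CovarianceModel,
                       C_model: np.ndarray | CovarianceModel) -> float:
    """Normalized Frobenius distance ||C_data - C_model||_F / ||C_data||_F.

    Zero for a perfect fit, exactly one against the zero matrix. Inputs
    should be normalized to the same trace for the value to be meaningful.
    """
    A = C_data.C if isinstance(C_data, CovarianceModel) else np.asarray(C_data)
    B = C_model.C if isinstance(C_model, CovarianceModel) else np.asarray(C_model)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    denom = np.linalg.norm(A)
    if denom == 0:
        raise ValueError("data covariance is identically zero")
    return float(np.linalg.norm(A - B) / denom)


def _sensilla_model(grid: Grid1D, f_lo: float, f_hi: float, gamma: float,
                    target: float) -> CovarianceModel:
    return build_sensilla_cov(
        grid, SensillaParams(f_lo, f_hi, gamma), trace_target=target
    )


def fit_covariance_params(
    C_data: CovarianceModel,
    kind: str,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_grid: int = 15,
) -> FitResult:
    """Fit a covariance model to a data covariance by Frobenius minimization.

    kind = "sensilla": search band edges (f_lo, f_hi) over the harmonic
        lattice of the grid within ``bounds`` and gamma over a log grid,
        then polish gamma with a bounded scalar minimizer.
    kind = "fourier": band edges only.
    kind = "v1": grid over (s, f) then Nelder-Mead polish; the center is
        held fixed at the grid center (data are pre-centered).
    kind = "v1_translation_invariant": f only.
    kind = "unstructured": no parameters; returns the identity distance.

    ``bounds`` maps parameter names ("f_lo_hz", "f_hi_hz", "gamma_ms",
    "size_px", "freq_px") to (low, high). The full evaluation trace is
    returned in the result.
    """
    grid = C_data.grid
    target = C_data.trace
    data = C_data.C
    bounds = dict(bounds or {})
    trace: list[tuple[dict, float]] = []

    def record(params: dict, model: CovarianceModel) -> float:
        dist = frobenius_distance(data, model.C)
        trace.append((params, dist))
        return dist

    if kind == "unstructured":
        model = build_null_cov("unstructured", grid, trace_target=target)
        dist = record({}, model)
        return FitResult(kind=kind, params={}, distance=dist, trace=trace)

    if kind in ("sensilla", "fourier"):
        if not isinstance(grid, Grid1D):
            raise ValueError(f"{kind} fit requires a 1-D grid")
        df = 1.0 / grid.duration_s
        lo_b = bounds.get("f_lo_hz", (df, grid.nyquist_hz / 2))
        hi_b = bounds.get("f_hi_hz", (df, grid.nyquist_hz))
        harmonics = np.arange(1, grid.n_samples // 2 + 1) * df
        lo_cands = harmonics[(harmonics >= lo_b[0]) & (harmonics <= lo_b[1])]
        hi_cands = harmonics[(harmonics >= hi_b[0]) & (harmonics <= hi_b[1])]
        if lo_cands.size == 0 or hi_cands.size == 0:
            raise ValueError("empty search space for band edges")
        if kind == "fourier":
            best = None
            for f_lo in lo_cands:
                for f_hi in hi_cands[hi_cands >= f_lo]:
                    model = build_stationary_cov(
                        grid, (f_lo, f_hi), trace_target=target
                    )
                    p = {"f_lo_hz": float(f_lo), "f_hi_hz": float(f_hi)}
                    dist = record(p, model)
                    if best is None or dist < best[1]:
                        best = (p, dist)
            return FitResult(kind=kind, params=best[0], distance=best[1], trace=trace)
        g_b = bounds.get("gamma_ms", (grid.dt_ms, grid.duration_ms))
        gammas = np.geomspace(g_b[0], g_b[1], n_grid)
        best = None
        for f_lo in lo_cands:
            for f_hi in hi_cands[hi_cands >= f_lo]:
                for gamma in gammas:
                    p = {
                        "f_lo_hz": float(f_lo),
                        "f_hi_hz": float(f_hi),
                        "gamma_ms": float(gamma),
                    }
                    dist = record(p, _sensilla_model(grid, f_lo, f_hi, gamma, target))
                    if best is None or dist < best[1]:
                        best = (p, dist)
        # polish gamma at the winning band
        p0 = best[0]

        def obj(gamma: float) -> float:
            p = dict(p0, gamma_ms=float(gamma))
            return record(
                p, _sensilla_model(grid, p0["f_lo_hz"], p0["f_hi_hz"], gamma, target)
            )

        minimize_scalar(obj, bounds=g_b, method="bounded",
                        options={"xatol": 1e-10 * g_b[1]})
        # second-stage unconstrained Brent polish around the bounded optimum
        g_star = min(((p, d) for p, d in trace), key=lambda t: t[1])[0]["gamma_ms"]
        try:
            minimize_scalar(
                obj,
                bracket=(g_star * (1 - 1e-4), g_star, g_star * (1 + 1e-4)),
                method="brent",
                options={"xtol": 1e-14},
            )
        except (ValueError, RuntimeError):
            pass  # bracket may fail at a boundary optimum; bounded result stands
        best_p, best_d = min(
            ((p, d) for p, d in trace), key=lambda t: t[1]
        )
        return FitResult(kind=kind, params=best_p, distance=best_d, trace=trace)

    if kind == "v1":
        if not isinstance(grid, Grid2D):
            raise ValueError("v1 fit requires a 2-D grid")
        center = grid.center
        s_b = bounds.get("size_px", (0.25, max(grid.shape) / 2))
        f_b = bounds.get("freq_px", (0.25, max(grid.shape) / 2))

        def make(s: float, f: float) -> CovarianceModel:
            return build_v1_cov(grid, V1Params(s, f, center), trace_target=target)

        best = None
        for s in np.geomspace(*s_b, n_grid):
            for f in np.geomspace(*f_b, n_grid):
                p = {"size_px": float(s), "freq_px": float(f)}
                dist = record(p, make(s, f))
                if best is None or dist < best[1]:
                    best = (p, dist)

        def obj2(v: np.ndarray) -> float:
            s, f = np.clip(v, [s_b[0], f_b[0]], [s_b[1], f_b[1]])
            return record({"size_px": float(s), "freq_px": float(f)}, make(s, f))

        minimize(
            obj2,
            x0=[best[0]["size_px"], best[0]["freq_px"]],
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 400},
        )
        best_p, best_d = min(((p, d) for p, d in trace), key=lambda t: t[1])
        return FitResult(kind=kind, params=best_p, distance=best_d, trace=trace)

    if kind == "v1_translation_invariant":
        if not isinstance(grid, Grid2D):
            raise ValueError("v1_translation_invariant fit requires a 2-D grid")
        f_b = bounds.get("freq_px", (0.25, max(grid.shape) / 2))

        def make_ti(f: float) -> CovarianceModel:
            return build_null_cov(
                "v1_translation_invariant", grid, {"freq_px": f}, trace_target=target
            )

        for f in np.geomspace(*f_b, n_grid):
            record({"freq_px": float(f)}, make_ti(f))

        def obj1(f: float) -> float:
            return record({"freq_px": float(f)}, make_ti(f))

        minimize_scalar(obj1, bounds=f_b, method="bounded",
                        options={"xatol": 1e-4 * f_b[1]})
        best_p, best_d = min(((p, d) for p, d in trace), key=lambda t: t[1])
        return FitResult(kind=kind, params=best_p, distance=best_d, trace=trace)

    raise ValueError(f"unknown model kind: {kind!r}")


def finite_sample_covariance(
    cov: CovarianceModel, m: int, seed: int
) -> CovarianceModel:
    """Empirical covariance of m fresh samples from ``cov`` (C_finite).

    Reproduces the bumpy finite-sample structure seen in small measured
    populations; converges to the model covariance at the Monte-Carlo rate
    ~ m^{-1/2}.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    rfs = sample_weights(cov, m, seed)
    out = empirical_covariance(rfs, trace_target=cov.trace)
    out.kind = "finite_" + cov.kind
    return out


def spectral_compare(
    C_data: CovarianceModel,
    C_model: CovarianceModel,
    C_finite: CovarianceModel | None = None,
    k: int = 5,
) -> SpectralReport:
    """Spectral diagnostics across data, model, and finite-sample covariances.

    All inputs are normalized to unit trace so the eigenvalue curves each sum
    to one and are directly comparable. Leading eigenvectors are compared
    via principal subspace angles (data vs model) rather than one-by-one,
    since near-degenerate eigenvalues permute and rotate freely.
    """
    if k > C_data.d:
        raise ValueError(f"k={k} exceeds dimension {C_data.d}")
    mats = {"data": C_data, "model": C_model}
    if C_finite is not None:
        mats["finite"] = C_finite
    curves, vecs = {}, {}
    for name, model in mats.items():
        unit = normalize_trace(model, 1.0)
        vals = unit.eigenvalues
        curves[name] = vals / vals.sum()
        vecs[name] = unit.eigenvectors[:, :k]
    var_explained = np.cumsum(curves["data"][:k])
    angles = subspace_angles(vecs["data"], vecs["model"])
    return SpectralReport(
        eigenvalue_curves=curves,
        leading_eigenvectors=vecs,
        variance_explained=var_explained,
        principal_angles_rad=np.sort(angles),
        k=k,
    )
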