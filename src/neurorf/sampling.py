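"""Sampling receptive fields from a covariance model and kernel evaluation.

Weights are drawn by the Karhunen-Loeve construction w = Phi Lambda z with
z ~ N(0, I), which tolerates the rank-deficient (bandlimited) covariances
that arise by design. The basis change x_tilde = Lambda Phi^T x turns a
projection onto a structured weight into a projection onto a spherical
Gaussian: w^T x = z^T x_tilde, so Var(w^T x) = ||x_tilde||^2 = x^T C x.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .covariance import CovarianceModel, normalize_trace
from .grids import Grid1D, Grid2D

__all__ = [
    "ReceptiveFieldSet",
    "sample_weights",
    "basis_change",
    "relu_arccos_kernel",
    "structured_kernel",
    "empirical_covariance",
]


@dataclass
class ReceptiveFieldSet:
    """m receptive fields as rows of W (m x d) with grid metadata."""

    W: np.ndarray
    grid: Grid1D | Grid2D
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        if self.W.shape[0] < 1:
            raise ValueError("need at least one receptive field")
        if self.W.shape[1] != self.grid.size:
            raise ValueError(
                f"field dimension {self.W.shape[1]} does not match grid size "
                f"{self.grid.size}"
            )

    @property
    def m(self) -> int:
        return self.W.shape[0]

    @property
    def d(self) -> int:
        return self.W.shape[1]


def sample_weights(cov: CovarianceModel, m: int, seed: int) -> ReceptiveFieldSet:
    """Draw m i.i.d. receptive fields w ~ N(0, C) via w = Phi Lambda z.

    The generator stream is row-major over an (m, d) standard-normal block,
    so increasing m extends (never reshuffles) the earlier draws for the
    same seed. Identical (cov, m, seed) gives bit-identical output.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((m, cov.d))
    F = cov.factor()  # Phi @ diag(Lambda)
    W = Z @ F.T
    return ReceptiveFieldSet(
        W=W,
        grid=cov.grid,
        provenance={"kind": cov.kind, "params": dict(cov.params), "seed": seed, "m": m},
    )


def basis_change(cov: CovarianceModel, X: np.ndarray) -> np.ndarray:
    """Transform stimuli into the covariance eigenbasis: rows x_tilde = Lambda Phi^T x.

    For a bandlimited covariance the components outside the passband are
    exactly zero, so the transform filters as well as rotates.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != cov.d:
        raise ValueError(
            f"stimulus dimension {X.shape[1]} does not match covariance size {cov.d}"
        )
    return X @ cov.factor()


def relu_arccos_kernel(x: np.ndarray, x2: np.ndarray) -> float:
    """Closed-form infinite-width ReLU random-feature kernel (arc-cosine, order 1).

    k(x, x') = ||x|| ||x'|| / (2 pi) * (sin(theta) + (pi - theta) cos(theta))

    with theta the angle between x and x'. This is the m -> infinity limit of
    (1/m) sum_j relu(w_j^T x) relu(w_j^T x') for spherical Gaussian w_j.
    Zero inputs return 0.
    """
    x = np.asarray(x, dtype=float).ravel()
    x2 = np.asarray(x2, dtype=float).ravel()
    nx, ny = np.linalg.norm(x), np.linalg.norm(x2)
    if nx == 0.0 or ny == 0.0:
        return 0.0
    cos_t = np.clip(x @ x2 / (nx * ny), -1.0, 1.0)
    theta = np.arccos(cos_t)
    return float(nx * ny / (2.0 * np.pi) * (np.sin(theta) + (np.pi - theta) * cos_t))


def structured_kernel(cov: CovarianceModel, x: np.ndarray, x2: np.ndarray) -> float:
    """Effective kernel of a structured ReLU RFN: the arc-cosine kernel of the
    basis-changed inputs, k_struct(x, x') = k_unstruct(x_tilde, x_tilde')."""
    xt = basis_change(cov, x)[0]
    xt2 = basis_change(cov, x2)[0]
    return relu_arccos_kernel(xt, xt2)


def empirical_covariance(
    rfs: ReceptiveFieldSet, trace_target: float | None = None
) -> CovarianceModel:
    """Second-moment covariance of a receptive-field set, C proportional to W^T W.

    No mean subtraction is performed: receptive fields are treated as draws
    from a zero-mean process, and the covariance is the plain inner-product
    (Gram) matrix of the fields, trace-normalized to d by default.
    """
    if rfs.m < 2:
        raise ValueError("need at least 2 receptive fields")
    C = rfs.W.T @ rfs.W / rfs.m
    tr = np.trace(C)
    if tr <= 0:
        raise ValueError("degenerate receptive-field set: zero covariance trace")
    model = CovarianceModel(
        C=C,
        grid=rfs.grid,
        kind="empirical",
        params={"m": rfs.m, "source": rfs.provenance.get("kind", "measured")},
    )
    return normalize_trace(model, rfs.d if trace_target is None else trace_target)
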