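"""Random feature networks with fixed hidden weights and an SVM readout.

The network is h = relu(W x), y_hat = beta^T h + beta0 with W an m x d bank
of receptive fields frozen after sampling. Only the readout is trained: a
linear SVM with squared hinge loss and l2 penalty, its regularization
strength tuned over a log-spaced grid spanning [1e-3, 1e3] by stratified
5-fold cross-validation on the training set. Hidden neurons carry no
threshold, and features are not standardized — positive rescaling of the
features is absorbed by the readout through ReLU homogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .covariance import CovarianceModel, eigendecompose
from .grids import Grid2D
from .sampling import ReceptiveFieldSet, sample_weights
from .tasks import LabeledDataset

__all__ = [
    "RFNModel",
    "ErrorCurve",
    "hidden_features",
    "fit_readout",
    "evaluate_error",
    "subclass_errors",
    "error_curve_experiment",
    "v1_weight_bank",
]

# Regularization grid: 7 log-spaced values covering the tuning range
# [1e-3, 1e3] at decade resolution, both boundaries included.
DEFAULT_C_GRID = tuple(np.logspace(-3.0, 3.0, 7))


@dataclass
class RFNModel:
    """An RFN: fixed hidden weight bank plus (after fitting) a linear readout."""

    weights: ReceptiveFieldSet
    nonlinearity: str = "relu"
    readout: LinearSVC | None = None
    chosen_C: float | None = None
    cv_scores: dict = field(default_factory=dict)
    feature_scale: float = 1.0

    @property
    def m(self) -> int:
        return self.weights.m

    def features(self, X: np.ndarray) -> np.ndarray:
        return self.feature_scale * hidden_features(self.weights.W, X)

    def fit(self, X: np.ndarray, y: np.ndarray, seed: int = 0) -> "RFNModel":
        # single global rescaling of the feature matrix (absorbed into the
        # readout by ReLU homogeneity); conditions the SVM solve so the
        # fixed regularization grid brackets the optimum for any weight scale
        H0 = hidden_features(self.weights.W, X)
        rms = float(np.sqrt(np.mean(H0**2)))
        self.feature_scale = 1.0 / rms if rms > 0 else 1.0
        H = self.feature_scale * H0
        self.readout, self.chosen_C, self.cv_scores = fit_readout(H, y, seed=seed)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.readout is None:
            raise RuntimeError("readout not fitted")
        return self.readout.predict(self.features(X))


@dataclass
class ErrorCurve:
    """Mean/SEM test error per hidden-layer width, over repeated weight draws."""

    neuron_counts: np.ndarray
    errors: np.ndarray  # (n_counts, repeats)
    seeds: np.ndarray
    repeats: int

    @property
    def mean(self) -> np.ndarray:
        return self.errors.mean(axis=1)

    @property
    def sem(self) -> np.ndarray:
        if self.repeats < 2:
            return np.zeros(len(self.neuron_counts))
        return self.errors.std(axis=1, ddof=1) / np.sqrt(self.repeats)


def hidden_features(W: np.ndarray, X: np.ndarray) -> np.ndarray:
    """ReLU hidden-layer features H = max(0, X W^T), shape (n, m)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != W.shape[1]:
        raise ValueError(
            f"stimulus dimension {X.shape[1]} does not match weight dimension "
            f"{W.shape[1]}"
        )
    return np.maximum(X @ W.T, 0.0)


def fit_readout(
    H: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    c_grid: tuple[float, ...] = DEFAULT_C_GRID,
    n_folds: int = 5,
) -> tuple[LinearSVC, float, dict]:
    """Train the linear SVM readout with cross-validated regularization.

    Squared hinge loss, l2 penalty; candidate inverse regularization values
    ``c_grid``; stratified ``n_folds``-fold CV with deterministic fold
    assignment from ``seed``. Ties are broken toward the weakest penalty
    (smallest regularization strength, i.e. largest C). Multiclass problems
    use the one-vs-rest reduction native to LinearSVC. Returns the refitted
    readout, the chosen C and the per-C mean CV accuracies.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least two classes to fit a readout")
    if counts.min() < max(n_folds, 10):
        raise ValueError(
            f"need at least {max(n_folds, 10)} examples per class, "
            f"smallest class has {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(H, y))
    # descending C: ties resolve to the smallest regularization strength
    order = sorted(c_grid, reverse=True)
    scores: dict[float, float] = {}
    best_C, best_score = None, -np.inf
    for C in order:
        accs = []
        for tr, va in folds:
            clf = _svc(C, seed)
            clf.fit(H[tr], y[tr])
            accs.append(clf.score(H[va], y[va]))
        scores[C] = float(np.mean(accs))
        if scores[C] > best_score:
            best_score, best_C = scores[C], C
    final = _svc(best_C, seed)
    final.fit(H, y)
    return final, float(best_C), scores


def _svc(C: float, seed: int) -> LinearSVC:
    return LinearSVC(
        C=C,
        loss="squared_hinge",
        penalty="l2",
        dual=False,
        tol=1e-3,
        max_iter=2000,
        random_state=seed,
    )


def evaluate_error(model: RFNModel, X_test: np.ndarray, y_test: np.ndarray) -> float:
    """Misclassification fraction of a fitted RFN on a test set."""
    pred = model.predict(X_test)
    return float(np.mean(pred != np.asarray(y_test)))


def subclass_errors(
    model: RFNModel, test: LabeledDataset
) -> dict[str, float]:
    """Per-subclass misclassification fractions on a labeled test set."""
    if test.subclass is None:
        raise ValueError("test set carries no subclass tags")
    pred = model.predict(test.X)
    out = {}
    for tag in np.unique(test.subclass):
        mask = test.subclass == tag
        out[str(tag)] = float(np.mean(pred[mask] != test.y[mask]))
    return out


def _draw_weights(
    cov: CovarianceModel | None, m: int, seed: int, d: int, grid
) -> ReceptiveFieldSet:
    if cov is None:
        rng = np.random.default_rng(seed)
        return ReceptiveFieldSet(
            W=rng.standard_normal((m, d)),
            grid=grid,
            provenance={"kind": "unstructured", "seed": seed},
        )
    return sample_weights(cov, m, seed)


def error_curve_experiment(
    cov: CovarianceModel | None,
    train: LabeledDataset,
    test: LabeledDataset,
    neuron_counts: list[int],
    repeats: int = 5,
    seed: int = 0,
) -> ErrorCurve:
    """Test-error curve against hidden-layer width.

    For each width m and each of ``repeats`` independent draws, sample a
    fresh weight bank (from ``cov``, or spherical Gaussian if ``cov`` is
    None), fit the SVM readout on the training set, and record the test
    error. Weight-draw seeds are spawned deterministically from ``seed``.
    """
    if not neuron_counts:
        raise ValueError("neuron_counts must be nonempty")
    d = train.X.shape[1]
    grid = cov.grid if cov is not None else _grid_for(train)
    errors = np.zeros((len(neuron_counts), repeats))
    seeds = np.zeros((len(neuron_counts), repeats), dtype=np.int64)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(neuron_counts) * repeats) % (2**31)
    k = 0
    for i, m in enumerate(neuron_counts):
        for r in range(repeats):
            s = int(child_seeds[k])
            k += 1
            rfs = _draw_weights(cov, m, s, d, grid)
            model = RFNModel(weights=rfs).fit(train.X, train.y, seed=s)
            errors[i, r] = evaluate_error(model, test.X, test.y)
            seeds[i, r] = s
    return ErrorCurve(
        neuron_counts=np.asarray(neuron_counts),
        errors=errors,
        seeds=seeds,
        repeats=repeats,
    )


def _grid_for(dataset: LabeledDataset):
    from .grids import Grid1D

    n, dt = dataset.meta.get("grid", (dataset.X.shape[1], 1.0))
    return Grid1D(n_samples=n, dt_ms=dt)


def v1_weight_bank(
    grid: Grid2D,
    size_px: float,
    freq_px: float,
    m: int,
    seed: int,
) -> ReceptiveFieldSet:
    """Sample m V1-model fields, each with its own uniformly random center.

    Exploits the factorization C_c = G_c K G_c of the V1 covariance, where K
    is the center-independent squared-exponential kernel and G_c the diagonal
    Gaussian envelope at center c: w = G_c K^{1/2} z has covariance C_c, so K
    is eigendecomposed once and reused for all centers. Each field's
    covariance is trace-normalized to d before sampling; centers (drawn
    uniformly over pixels) are recorded in the provenance.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = np.random.default_rng(seed)
    pts = grid.coords
    sq_dist = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=-1)
    K = np.exp(-sq_dist / (2.0 * freq_px**2))
    vals, vecs = eigendecompose(K)
    half = vecs * np.sqrt(vals)  # K^{1/2} up to rotation
    centers = np.column_stack(
        [rng.integers(0, grid.height, m), rng.integers(0, grid.width, m)]
    )
    Z = rng.standard_normal((m, grid.size))
    base = Z @ half.T  # rows ~ N(0, K)
    d = grid.size
    W = np.empty((m, d))
    for i in range(m):
        g = np.exp(
            -((pts - centers[i]) ** 2).sum(axis=1) / (2.0 * size_px**2)
        )
        trace_c = float((g**2).sum())  # Tr(C_c) since K(t,t) = 1
        W[i] = g * base[i] * np.sqrt(d / trace_c)
    return ReceptiveFieldSet(
        W=W,
        grid=grid,
        provenance={
            "kind": "v1_random_centers",
            "size_px": size_px,
            "freq_px": freq_px,
            "centers": centers,
            "seed": seed,
        },
    )
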