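"""Synthetic benchmark tasks for structured random-feature networks.

Two timeseries classification tasks probe the inductive bias of
frequency-selective receptive fields:

* frequency detection — separate a noisy 50 Hz sinusoid from power-matched
  white noise; not linearly separable because the sinusoid phase is random.
* frequency XOR — label pure 50 Hz or pure 80 Hz tones true, and 50+80 Hz
  mixtures or white noise false.

SNR is a power ratio: signal power divided by noise power, so SNR = 1.76
corresponds to 10*log10(1.76) = 2.46 dB. The signal amplitude is fixed at
A = 1 and per-sample noise variance is set from the SNR (sigma^2 = P_sig/snr,
with P_sig = A^2/2 for a pure tone). Negative/noise examples are white
Gaussian noise whose expected power matches the expected total power of a
noisy pure tone.

A fixture generator produces synthetic receptive-field populations from a
known covariance model for parameter-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .covariance import CovarianceModel
from .grids import Grid1D
from .sampling import ReceptiveFieldSet, sample_weights

__all__ = [
    "LabeledDataset",
    "default_task_grid",
    "gen_frequency_detection",
    "gen_frequency_xor",
    "gen_synthetic_rf_population",
]


@dataclass
class LabeledDataset:
    """n x d stimuli with labels and task metadata.

    ``subclass`` tags each row with its generating condition (e.g. "f1",
    "mix"); ``clean`` holds the noiseless signal component (zeros for pure
    noise rows) so the realized SNR can be audited.
    """

    X: np.ndarray
    y: np.ndarray
    meta: dict = field(default_factory=dict)
    subclass: np.ndarray | None = None
    clean: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.y) != self.X.shape[0]:
            raise ValueError("label count does not match stimulus count")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite entries in stimulus matrix")

    @property
    def n(self) -> int:
        return self.X.shape[0]


def default_task_grid() -> Grid1D:
    """100 ms at 2 kHz: the d = 200 grid both timeseries tasks use."""
    return Grid1D(n_samples=200, dt_ms=0.5)


def _tone(grid: Grid1D, freq_hz: float, phase: np.ndarray, amp: float) -> np.ndarray:
    """Rows amp*sin(2 pi f t + phase_i) on the grid."""
    t = grid.times_s
    return amp * np.sin(2.0 * np.pi * freq_hz * t[None, :] + phase[:, None])


def gen_frequency_detection(
    n_per_class: int,
    f1_hz: float = 50.0,
    snr: float = 1.76,
    grid: Grid1D | None = None,
    seed: int = 0,
    amp: float = 1.0,
) -> LabeledDataset:
    """Frequency-detection dataset: noisy f1 sinusoids vs matched white noise.

    Positives are A*sin(2 pi f1 t + phi), phi ~ Uniform[0, 2 pi), plus white
    Gaussian noise with signal-power/noise-power = ``snr``. Negatives are
    white Gaussian noise whose expected power equals the expected total
    power of the positives. Classes are balanced; labels are 1/0.
    """
    grid = grid or default_task_grid()
    if snr <= 0:
        raise ValueError(f"snr must be a positive power ratio, got {snr}")
    if f1_hz >= grid.nyquist_hz:
        raise ValueError(f"f1={f1_hz} Hz at or above Nyquist {grid.nyquist_hz} Hz")
    rng = np.random.default_rng(seed)
    d = grid.size
    sig_power = amp**2 / 2.0
    noise_var = sig_power / snr
    total_power = sig_power + noise_var

    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_per_class)
    signal = _tone(grid, f1_hz, phases, amp)
    X_pos = signal + rng.normal(0.0, np.sqrt(noise_var), size=(n_per_class, d))
    X_neg = rng.normal(0.0, np.sqrt(total_power), size=(n_per_class, d))

    X = np.vstack([X_pos, X_neg])
    y = np.concatenate([np.ones(n_per_class, int), np.zeros(n_per_class, int)])
    clean = np.vstack([signal, np.zeros_like(X_neg)])
    subclass = np.array(["f1"] * n_per_class + ["noise"] * n_per_class)
    perm = rng.permutation(2 * n_per_class)
    return LabeledDataset(
        X=X[perm],
        y=y[perm],
        subclass=subclass[perm],
        clean=clean[perm],
        meta={
            "task": "frequency_detection",
            "f1_hz": f1_hz,
            "snr": snr,
            "snr_db": 10.0 * np.log10(snr),
            "amp": amp,
            "seed": seed,
            "grid": (grid.n_samples, grid.dt_ms),
        },
    )


def gen_frequency_xor(
    n_per_subclass: int,
    f1_hz: float = 50.0,
    f2_hz: float = 80.0,
    snr: float = 1.76,
    grid: Grid1D | None = None,
    seed: int = 0,
    amp: float = 1.0,
) -> LabeledDataset:
    """Frequency-XOR dataset with four equal subclasses.

    Pure f1 and pure f2 tones are labeled 1; f1+f2 mixtures (independent
    random phases per component) and white noise are labeled 0. Tonal rows
    are corrupted at power-ratio ``snr`` relative to their own signal power
    (A^2/2 for a pure tone, A^2 for the two-component mixture); the noise
    subclass is white Gaussian with power matched to the expected total
    power of a noisy pure tone.
    """
    grid = grid or default_task_grid()
    if snr <= 0:
        raise ValueError(f"snr must be a positive power ratio, got {snr}")
    if f1_hz == f2_hz:
        raise ValueError("f1 and f2 must differ")
    for f in (f1_hz, f2_hz):
        if f >= grid.nyquist_hz:
            raise ValueError(f"frequency {f} Hz at or above Nyquist")
    rng = np.random.default_rng(seed)
    n, d = n_per_subclass, grid.size
    pure_power = amp**2 / 2.0
    pure_noise_var = pure_power / snr
    mix_noise_var = (2.0 * pure_power) / snr
    noise_class_var = pure_power + pure_noise_var

    sig_f1 = _tone(grid, f1_hz, rng.uniform(0, 2 * np.pi, n), amp)
    sig_f2 = _tone(grid, f2_hz, rng.uniform(0, 2 * np.pi, n), amp)
    sig_mix = _tone(grid, f1_hz, rng.uniform(0, 2 * np.pi, n), amp) + _tone(
        grid, f2_hz, rng.uniform(0, 2 * np.pi, n), amp
    )
    X_f1 = sig_f1 + rng.normal(0.0, np.sqrt(pure_noise_var), (n, d))
    X_f2 = sig_f2 + rng.normal(0.0, np.sqrt(pure_noise_var), (n, d))
    X_mix = sig_mix + rng.normal(0.0, np.sqrt(mix_noise_var), (n, d))
    X_noise = rng.normal(0.0, np.sqrt(noise_class_var), (n, d))

    X = np.vstack([X_f1, X_f2, X_mix, X_noise])
    y = np.concatenate([np.ones(2 * n, int), np.zeros(2 * n, int)])
    clean = np.vstack([sig_f1, sig_f2, sig_mix, np.zeros_like(X_noise)])
    subclass = np.array(["f1"] * n + ["f2"] * n + ["mix"] * n + ["noise"] * n)
    perm = rng.permutation(4 * n)
    return LabeledDataset(
        X=X[perm],
        y=y[perm],
        subclass=subclass[perm],
        clean=clean[perm],
        meta={
            "task": "frequency_xor",
            "f1_hz": f1_hz,
            "f2_hz": f2_hz,
            "snr": snr,
            "snr_db": 10.0 * np.log10(snr),
            "amp": amp,
            "seed": seed,
            "grid": (grid.n_samples, grid.dt_ms),
        },
    )


def gen_synthetic_rf_population(
    cov: CovarianceModel,
    m: int,
    noise_level: float = 0.0,
    seed: int = 0,
) -> ReceptiveFieldSet:
    """Synthetic receptive-field population from a known covariance model.

    Samples m fields from ``cov`` and optionally adds white measurement
    noise whose per-sample variance is ``noise_level`` times the mean field
    variance Tr(C)/d. Ground-truth parameters are recorded in the
    provenance for parameter-recovery tests.
    """
    if noise_level < 0:
        raise ValueError("noise_level must be nonnegative")
    rfs = sample_weights(cov, m, seed)
    if noise_level > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
        sigma2 = noise_level * cov.trace / cov.d
        rfs.W = rfs.W + rng.normal(0.0, np.sqrt(sigma2), rfs.W.shape)
    rfs.provenance.update(
        {
            "synthetic": True,
            "truth_kind": cov.kind,
            "truth_params": dict(cov.params),
            "noise_level": noise_level,
        }
    )
    return rfs
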