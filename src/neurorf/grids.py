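"""Discretization grids for receptive-field domains.

Temporal receptive fields live on a 1-D grid of equally spaced time points;
spatial (visual) receptive fields live on a 2-D pixel grid flattened in
row-major order. Public units are milliseconds and Hertz for time, pixels
for space; internal computations convert time to seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Grid1D", "Grid2D"]


@dataclass(frozen=True)
class Grid1D:
    """Equally spaced time grid on [0, L).

    Parameters
    ----------
    n_samples : int
        Number of grid points d. Must be at least 2.
    dt_ms : float
        Sampling interval in milliseconds. Must be positive.
    """

    n_samples: int
    dt_ms: float

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError(f"n_samples must be >= 2, got {self.n_samples}")
        if self.dt_ms <= 0:
            raise ValueError(f"dt_ms must be positive, got {self.dt_ms}")

    @property
    def size(self) -> int:
        return self.n_samples

    @property
    def duration_ms(self) -> float:
        """Total window length L = d * dt in ms."""
        return self.n_samples * self.dt_ms

    @property
    def duration_s(self) -> float:
        return self.duration_ms / 1000.0

    @property
    def sample_rate_hz(self) -> float:
        return 1000.0 / self.dt_ms

    @property
    def nyquist_hz(self) -> float:
        return self.sample_rate_hz / 2.0

    @property
    def times_ms(self) -> np.ndarray:
        """Grid points t_i = i * dt, i = 0..d-1, in ms."""
        return np.arange(self.n_samples) * self.dt_ms

    @property
    def times_s(self) -> np.ndarray:
        return self.times_ms / 1000.0

    def harmonic_hz(self, k: np.ndarray | int) -> np.ndarray | float:
        """Frequency of the k-th natural harmonic, omega_k = 2*pi*k/L, in Hz."""
        return np.asarray(k) / self.duration_s

    @classmethod
    def from_rate(cls, duration_ms: float, rate_khz: float) -> "Grid1D":
        """Build from window length (ms) and sampling rate (kHz)."""
        dt_ms = 1.0 / rate_khz
        n = int(round(duration_ms / dt_ms))
        return cls(n_samples=n, dt_ms=dt_ms)


@dataclass(frozen=True)
class Grid2D:
    """Pixel grid with unit spacing, flattened row-major.

    Pixel centers sit at integer coordinates (row, col) with the origin at
    the top-left pixel. Flattening order is row-major: pixel (r, c) maps to
    flat index ``r * width + c``.
    """

    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError(
                f"grid dimensions must be >= 1, got {self.height}x{self.width}"
            )

    @property
    def size(self) -> int:
        return self.height * self.width

    @property
    def n_pixels(self) -> int:
        return self.size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    @property
    def center(self) -> tuple[int, int]:
        """Integer center pixel (row, col)."""
        return (self.height // 2, self.width // 2)

    @property
    def coords(self) -> np.ndarray:
        """(n_pixels, 2) array of (row, col) coordinates in flat order."""
        rr, cc = np.meshgrid(
            np.arange(self.height), np.arange(self.width), indexing="ij"
        )
        return np.column_stack([rr.ravel(), cc.ravel()]).astype(float)

    def contains(self, point: tuple[float, float]) -> bool:
        r, c = point
        return 0 <= r <= self.height - 1 and 0 <= c <= self.width - 1
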