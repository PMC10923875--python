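"""Sliding-window dynamic functional connectivity.

Builds the window-by-window sequence of Pearson correlation matrices
A^win from a multivariate BOLD time series: window ``win`` covers samples
``[win*step, win*step + l)`` (0-based half-open), so with the default
l = 15 volumes and step = 1 (14-volume overlap) a 128-volume series gives
exactly 114 windows of 30 s duration and 28 s overlap at TR = 2 s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .hemodynamics import BOLDTimeSeries

__all__ = ["WindowSpec", "FunctionalMatrixSequence", "sliding_window_corr", "n_windows"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: length and step in samples, TR in seconds."""

    length_l: int = 15
    step: int = 1
    delta_t: float = 2.0

    def __post_init__(self) -> None:
        if self.length_l < 2:
            raise ValueError("window length must be >= 2 samples")
        if not 1 <= self.step <= self.length_l:
            raise ValueError("need 1 <= step <= length_l")
        if self.delta_t <= 0:
            raise ValueError("delta_t must be positive")

    @property
    def duration_s(self) -> float:
        """Temporal span covered by one window (l * delta_t)."""
        return self.length_l * self.delta_t

    @property
    def overlap_s(self) -> float:
        """Temporal overlap of consecutive windows ((l - step) * delta_t)."""
        return (self.length_l - self.step) * self.delta_t


def n_windows(n_vol: int, spec: WindowSpec) -> int:
    """Number of full windows: floor((n_vol - l)/step) + 1."""
    if n_vol < spec.length_l:
        raise ValueError(f"need at least {spec.length_l} volumes, got {n_vol}")
    return (n_vol - spec.length_l) // spec.step + 1


@dataclass(frozen=True)
class FunctionalMatrixSequence:
    """Ordered per-window correlation matrices, ``(n_windows, N, N)``."""

    matrices: np.ndarray
    window_start_times: np.ndarray
    spec: WindowSpec = field(default_factory=WindowSpec)

    @property
    def n_windows(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.matrices.shape[1]


def _window_corr(block: np.ndarray, win: int) -> np.ndarray:
    """Pearson matrix of one (N, l) block; constant nodes get 0 correlations."""
    N = block.shape[0]
    good = block.max(axis=1) > block.min(axis=1)  # exactly-constant detection
    C = np.zeros((N, N))
    if good.sum() >= 2:
        sub = np.corrcoef(block[good])
        C[np.ix_(good, good)] = sub
    if not good.all():
        bad = np.flatnonzero(~good) + 1
        logger.warning("window %d: zero-variance node(s) %s; correlations set to 0",
                       win + 1, list(bad))
    C = (C + C.T) / 2.0
    np.fill_diagonal(C, 1.0)
    return C


def sliding_window_corr(Y: BOLDTimeSeries | np.ndarray, spec: WindowSpec = WindowSpec()) -> FunctionalMatrixSequence:
    """Per-window Pearson correlation of every node pair.

    Accepts a BOLD time series (or a bare ``(N, n_vol)`` array, assumed at
    spacing ``spec.delta_t``). A node that is constant within a window gets
    correlation 0 with every other node in that window (logged), keeping
    long ensemble runs alive on degenerate windows.
    """
    if isinstance(Y, BOLDTimeSeries):
        data = Y.y
        t0 = float(Y.times[0]) if Y.n_vol else 0.0
    else:
        data = np.asarray(Y, dtype=float)
        t0 = 0.0
    if data.ndim != 2:
        raise ValueError("expected an (N, n_vol) array")
    W = n_windows(data.shape[1], spec)
    mats = np.empty((W, data.shape[0], data.shape[0]))
    starts = np.empty(W)
    for w in range(W):
        lo = w * spec.step
        mats[w] = _window_corr(data[:, lo : lo + spec.length_l], w)
        starts[w] = t0 + lo * spec.delta_t
    return FunctionalMatrixSequence(mats, starts, spec)
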