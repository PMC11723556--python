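"""Windowed trigonometric decomposition of concentration timeseries.

The Pearson correlation of two signals over a window of length ``T`` can be
written as a sum of per-harmonic contributions

    r = sum_n r_n,      r_n = (a_n c_n + b_n d_n) / 2,

where ``(a_n, b_n)`` and ``(c_n, d_n)`` are the cosine/sine coefficients of
the two windowed, z-scored segments.  This module computes those
coefficients with a short-time Fourier scheme: each half-overlapping segment
is multiplied by the window weights, z-scored (population normalisation, so
the decomposition identity above is exact for boxcar windows), and converted
from DFT to trigonometric form.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

logger = logging.getLogger(__name__)

__all__ = [
    "TimeSeriesSet",
    "WindowSpec",
    "TrigCoefficients",
    "HarmonicCorrelations",
    "decompose",
    "harmonic_correlations",
    "recompose",
]


@dataclass
class TimeSeriesSet:
    """A samples x sources concentration matrix with spatial metadata.

    Parameters
    ----------
    values : ndarray, shape (T, S)
        Concentration per sample per source (arbitrary units).
    sample_rate : float
        Samples per second (Hz).
    positions : ndarray, shape (S, 2)
        Per-source (x, y) coordinates in metres.
    pitch : float
        Length normaliser (metres); distances are often quoted in pitch
        units, the spacing of the obstacles generating the flow, which
        approximates the size of the largest eddies.
    label : str
        Free-text description.
    """

    values: np.ndarray
    sample_rate: float
    positions: np.ndarray
    pitch: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x sources array")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 sources")
        if self.positions.shape != (self.values.shape[1], 2):
            raise ValueError("positions must have one (x, y) entry per source")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_sources(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class WindowSpec:
    """STFT window: length in seconds, shape, and overlap fraction.

    ``shape`` is one of ``{"boxcar", "hann", "kaiser"}``; Kaiser windows are
    parameterised by ``beta`` (default 16).  Windows overlap by half their
    length by default.
    """

    length_s: float = 1.0
    shape: str = "boxcar"
    overlap: float = 0.5
    beta: float = 16.0

    def __post_init__(self) -> None:
        if self.shape not in ("boxcar", "hann", "kaiser"):
            raise ValueError(f"unknown window shape {self.shape!r}")
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must be in [0, 1)")
        if self.length_s <= 0:
            raise ValueError("window length must be positive")

    def n_samples(self, sample_rate: float) -> int:
        L = int(round(self.length_s * sample_rate))
        if L < 4:
            raise ValueError("window length must be at least 4 samples")
        return L

    def weights(self, L: int) -> np.ndarray:
        if self.shape == "kaiser":
            return _signal.get_window(("kaiser", self.beta), L)
        return _signal.get_window(self.shape, L)

    def hop(self, L: int) -> int:
        return max(1, int(round(L * (1.0 - self.overlap))))


@dataclass
class TrigCoefficients:
    """Trigonometric (cosine/sine) coefficients of z-scored segments.

    ``coeffs[w, s, n, 0]`` is the cosine coefficient a_n and
    ``coeffs[w, s, n, 1]`` the sine coefficient b_n of window ``w`` of
    source ``s`` at harmonic ``n`` (n = 0 is DC, identically zero after
    z-scoring).  ``valid[w, s]`` is False for degenerate (zero-variance)
    segments, which are excluded from all downstream pooling.
    """

    coeffs: np.ndarray  # (windows, sources, harmonics + 1, 2)
    segment_length: int
    sample_rate: float
    window: WindowSpec
    valid: np.ndarray = field(default=None)  # (windows, sources) bool

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(self.coeffs.shape[:2], dtype=bool)

    @property
    def n_windows(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_sources(self) -> int:
        return self.coeffs.shape[1]

    @property
    def n_harmonics(self) -> int:
        """Number of positive harmonics, floor(L / 2)."""
        return self.coeffs.shape[2] - 1

    @property
    def fundamental_hz(self) -> float:
        return self.sample_rate / self.segment_length

    @property
    def frequencies_hz(self) -> np.ndarray:
        """Frequency of each harmonic index (0 .. floor(L/2)) in Hz."""
        return np.arange(self.n_harmonics + 1) * self.fundamental_hz

    def harmonic_weights(self) -> np.ndarray:
        """Weights combining coefficient products into correlation components.

        Interior harmonics carry weight 1/2; the Nyquist harmonic of an
        even-length segment carries weight 1 (its cosine coefficient is not
        doubled in the DFT-to-trig conversion), keeping the sum-over-
        harmonics identity with the plain Pearson correlation exact.  DC is
        excluded (weight 0).
        """
        w = np.full(self.n_harmonics + 1, 0.5)
        w[0] = 0.0
        if self.segment_length % 2 == 0:
            w[-1] = 1.0
        return w

    def reconstruct(self, window_idx: int, source_idx: int) -> np.ndarray:
        """Inverse transform: rebuild the z-scored windowed segment."""
        L = self.segment_length
        n = np.arange(L)
        k = np.arange(self.n_harmonics + 1)
        phase = 2.0 * np.pi * np.outer(k, n) / L
        a = self.coeffs[window_idx, source_idx, :, 0]
        b = self.coeffs[window_idx, source_idx, :, 1]
        return a @ np.cos(phase) + b @ np.sin(phase)


@dataclass
class HarmonicCorrelations:
    """Per-window, per-pair correlation components r_n."""

    r: np.ndarray  # (windows, pairs, harmonics + 1)
    pair_index: list
    valid: np.ndarray = field(default=None)  # (windows, pairs) bool

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(self.r.shape[:2], dtype=bool)


def segment_starts(n_samples: int, L: int, hop: int) -> np.ndarray:
    """Start indices of full segments; trailing partial windows are dropped."""
    if n_samples < L:
        raise ValueError("series shorter than one window")
    return np.arange(0, n_samples - L + 1, hop)


def decompose(series: TimeSeriesSet, window: WindowSpec) -> TrigCoefficients:
    """Windowed trigonometric decomposition of every source's timeseries.

    Each segment is multiplied by the window weights, z-scored with the
    population (1/L) standard deviation, and transformed: with DFT
    ``X[k] = u_k + j v_k`` of the z-scored segment (normalised by L),
    ``a_k = 2 u_k`` except at DC and Nyquist where ``a_k = u_k``, and
    ``b_k = -2 v_k``.

    Zero-variance segments (constant after windowing) are flagged invalid
    with a logged warning and excluded from downstream pooling.
    """
    L = window.n_samples(series.sample_rate)
    hop = window.hop(L)
    starts = segment_starts(series.n_samples, L, hop)
    if len(starts) < 1:
        raise ValueError("at least one full window must fit in the series")
    w = window.weights(L)
    H = L // 2

    n_win, n_src = len(starts), series.n_sources
    coeffs = np.zeros((n_win, n_src, H + 1, 2))
    valid = np.ones((n_win, n_src), dtype=bool)

    # (windows, sources, L) stack of windowed segments
    seg = np.stack([series.values[t0 : t0 + L, :].T for t0 in starts])  # (W, S, L)
    seg = seg * w[None, None, :]
    mean = seg.mean(axis=2, keepdims=True)
    sd = seg.std(axis=2, keepdims=True)  # population (1/L) normalisation
    degenerate = sd[..., 0] <= 0.0
    if degenerate.any():
        valid[degenerate] = False
        logger.warning(
            "%d zero-variance segment(s) flagged degenerate and excluded",
            int(degenerate.sum()),
        )
        sd = np.where(sd <= 0.0, 1.0, sd)
    z = (seg - mean) / sd

    F = np.fft.rfft(z, axis=2) / L  # u + j v
    a = 2.0 * F.real
    a[..., 0] /= 2.0
    if L % 2 == 0:
        a[..., -1] /= 2.0
    b = -2.0 * F.imag
    coeffs[..., 0] = a
    coeffs[..., 1] = b
    return TrigCoefficients(
        coeffs=coeffs,
        segment_length=L,
        sample_rate=series.sample_rate,
        window=window,
        valid=valid,
    )


def harmonic_correlations(
    coefA: np.ndarray,
    coefB: np.ndarray,
    segment_length: int | None = None,
    pair_index: list | None = None,
    valid: np.ndarray | None = None,
) -> np.ndarray:
    """Correlation components r_n = w_n * (a_n c_n + b_n d_n).

    ``coefA`` and ``coefB`` are coefficient arrays of matching shape
    ``(..., harmonics + 1, 2)``.  The harmonic weight ``w_n`` is 1/2 except
    at the Nyquist harmonic of even-length segments where it is 1 (see
    :meth:`TrigCoefficients.harmonic_weights`).  If ``segment_length`` is
    omitted the weights default to 1/2 everywhere beyond DC (odd-length
    convention).
    """
    coefA = np.asarray(coefA, dtype=float)
    coefB = np.asarray(coefB, dtype=float)
    if coefA.shape != coefB.shape:
        raise ValueError("coefficient arrays must have matching shapes")
    nh = coefA.shape[-2] - 1
    wts = np.full(nh + 1, 0.5)
    wts[0] = 0.0
    if segment_length is not None and segment_length % 2 == 0:
        wts[-1] = 1.0
    prod = coefA[..., 0] * coefB[..., 0] + coefA[..., 1] * coefB[..., 1]
    return prod * wts


def pairwise_correlations(
    coeffs: TrigCoefficients, pairs: list[tuple[int, int]] | None = None
) -> HarmonicCorrelations:
    """Correlation components for the given ordered source pairs.

    With ``pairs=None``, every ordered pair (i, j) with i < j is used.
    """
    if pairs is None:
        S = coeffs.n_sources
        pairs = [(i, j) for i in range(S) for j in range(i + 1, S)]
    r = np.stack(
        [
            harmonic_correlations(
                coeffs.coeffs[:, i], coeffs.coeffs[:, j], coeffs.segment_length
            )
            for i, j in pairs
        ],
        axis=1,
    )
    valid = np.stack(
        [coeffs.valid[:, i] & coeffs.valid[:, j] for i, j in pairs], axis=1
    )
    return HarmonicCorrelations(r=r, pair_index=list(pairs), valid=valid)


def recompose(r: HarmonicCorrelations | np.ndarray) -> np.ndarray:
    """Sum the harmonic components back into per-window Pearson correlations."""
    arr = r.r if isinstance(r, HarmonicCorrelations) else np.asarray(r)
    return arr.sum(axis=-1)
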