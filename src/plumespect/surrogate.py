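"""Surrogate multisource signals with prescribed coefficient correlations.

Signals for M sources are built from trigonometric coefficients sampled
from a zero-mean Gaussian whose covariance kernel factorises per harmonic n
as k(i, j, n) = G(|i - j|, n) S(n): S sets the per-harmonic power (a 1/f
power law with a 1 Hz cutoff, exponent alpha; alpha = 0 is white, alpha = 4
plume-like) and G the distance decay of the coefficient correlation between
sources i and j.  Coefficients at different harmonics are uncorrelated, so
the M*floor(L/2) square kernel is block-diagonal by harmonic.  Cosine and
sine coefficient vectors are independent draws c = L u, s = L v with
K = L L^T (Cholesky) and u, v standard normal — so the out-of-phase
correlation is zero by construction.

Two presets reproduce the validation datasets whose ground truth is known:

* ``equal_informative``: G(d) = 2 exp(-d / 12) - 1 at every harmonic — the
  decay length (hence the Fisher information) is the same at all
  frequencies;
* ``high_gt_low``: G(d, n) = exp(-d / R(n)) with R(n) = 12 for harmonics in
  the lower half of the range and R(n) = 2 in the upper half — high
  frequencies decay 6x faster, so they are more informative at small
  separations.

Distances are in source-index units; mapping to pitch is a user scale.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .spectral import TimeSeriesSet, TrigCoefficients, WindowSpec

logger = logging.getLogger(__name__)

__all__ = [
    "SurrogateSpec",
    "KernelMatrix",
    "SurrogateSample",
    "power_spectrum",
    "kernel_correlation",
    "build_kernel",
    "sample_signals",
    "estimate_kernel_correlations",
]

PRESETS = ("equal_informative", "high_gt_low", "custom")


@dataclass(frozen=True)
class SurrogateSpec:
    """Configuration of a surrogate dataset.

    Signals have 2 * floor(L/2) + 1 samples; ``n_realizations`` independent
    draws stand in for time windows.  ``kernel`` names a preset, or
    "custom" with user-supplied correlation/power callables.
    """

    M: int = 16
    L: int = 40
    fs: float = 41.0
    alpha: float = 4.0
    kernel: str = "equal_informative"
    n_realizations: int = 2000
    G: object = None  # custom correlation G(d, n)
    S: object = None  # custom power S(n)

    def __post_init__(self) -> None:
        if self.M < 2:
            raise ValueError("need M >= 2 sources")
        if self.L // 2 < 2:
            raise ValueError("need floor(L/2) >= 2 harmonics")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.kernel not in PRESETS:
            raise ValueError(f"unknown kernel preset {self.kernel!r}")
        if self.kernel == "custom" and (self.G is None or self.S is None):
            raise ValueError("custom kernel requires G and S callables")

    @property
    def n_harmonics(self) -> int:
        return self.L // 2

    @property
    def n_samples(self) -> int:
        return 2 * self.n_harmonics + 1

    def frequencies_hz(self) -> np.ndarray:
        n = np.arange(1, self.n_harmonics + 1)
        return n * self.fs / self.n_samples


@dataclass
class KernelMatrix:
    """Block-diagonal (by harmonic) coefficient covariance kernel."""

    K: np.ndarray  # (M * H, M * H)
    spec: SurrogateSpec
    jitter: float = 0.0

    def block(self, n: int) -> np.ndarray:
        """Covariance block of harmonic n (1-based)."""
        M = self.spec.M
        i0 = (n - 1) * M
        return self.K[i0 : i0 + M, i0 : i0 + M]


@dataclass
class SurrogateSample:
    """Sampled surrogate signals plus their generating coefficients."""

    signals: np.ndarray  # (n_realizations, n_samples, M)
    coeffs: np.ndarray  # (n_realizations, M, H, 2) ground-truth (cos, sin)
    spec: SurrogateSpec
    kernel: KernelMatrix
    seed: int = 0

    def as_trig_coefficients(self) -> TrigCoefficients:
        """Ground-truth coefficients in the measurement-pipeline container.

        Realizations play the role of time windows; a DC slot of zeros is
        prepended so harmonic indices match array indices.
        """
        W, M, H, _ = self.coeffs.shape
        arr = np.zeros((W, M, H + 1, 2))
        arr[:, :, 1:, :] = self.coeffs
        return TrigCoefficients(
            coeffs=arr,
            segment_length=self.spec.n_samples,
            sample_rate=self.spec.fs,
            window=WindowSpec(
                length_s=self.spec.n_samples / self.spec.fs,
                shape="boxcar",
                overlap=0.0,
            ),
        )

    def as_timeseries(self, source_spacing: float = 1.0, pitch: float = 1.0) -> TimeSeriesSet:
        """Concatenated realizations as a samples x sources series.

        Sources sit on a line with ``source_spacing`` metres between
        neighbours, so index separations map onto metric separations.
        """
        W, T, M = self.signals.shape
        values = self.signals.reshape(W * T, M)
        y = np.arange(M) * source_spacing
        positions = np.column_stack([np.zeros(M), y])
        return TimeSeriesSet(
            values=values,
            sample_rate=self.spec.fs,
            positions=positions,
            pitch=pitch,
            label=f"surrogate:{self.spec.kernel}",
        )


def power_spectrum(n: np.ndarray, alpha: float, L: int, fs: float) -> np.ndarray:
    """Per-harmonic power S(n) = max(n fs / (2 floor(L/2) + 1), 1)^(-alpha).

    A 1/f power law in the harmonic's frequency with the power held at 1
    below the 1 Hz cutoff; alpha = 0 gives a flat (white) spectrum.
    """
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise ValueError("harmonic index must be >= 1")
    freq = n * fs / (2 * (L // 2) + 1)
    return np.maximum(freq, 1.0) ** (-alpha)


def kernel_correlation(spec: SurrogateSpec, d: np.ndarray, n: int) -> np.ndarray:
    """Preset correlation G(d, n) between sources |i - j| = d apart."""
    d = np.asarray(d, dtype=float)
    if spec.kernel == "equal_informative":
        return 2.0 * np.exp(-d / 12.0) - 1.0
    if spec.kernel == "high_gt_low":
        R = 12.0 if n < spec.n_harmonics / 2 else 2.0
        return np.exp(-d / R)
    return spec.G(d, n)


def build_kernel(spec: SurrogateSpec, psd_tol: float = 1e-10) -> KernelMatrix:
    """Assemble the M*H x M*H block-diagonal kernel and check PSD.

    Cross-harmonic blocks are exactly zero (coefficients at different
    harmonics are uncorrelated).  If the smallest eigenvalue of a block is
    below ``-psd_tol`` the kernel is rejected with a diagnostic.
    """
    M, H = spec.M, spec.n_harmonics
    if spec.kernel == "custom" and spec.S is not None:
        S = np.asarray([spec.S(n) for n in range(1, H + 1)], dtype=float)
    else:
        S = power_spectrum(np.arange(1, H + 1), spec.alpha, spec.L, spec.fs)
    d = np.abs(np.subtract.outer(np.arange(M), np.arange(M)))
    K = np.zeros((M * H, M * H))
    min_eig = np.inf
    for n in range(1, H + 1):
        block = S[n - 1] * kernel_correlation(spec, d, n)
        i0 = (n - 1) * M
        K[i0 : i0 + M, i0 : i0 + M] = block
        if S[n - 1] > 0:
            ev = np.linalg.eigvalsh(block / S[n - 1]).min()
            min_eig = min(min_eig, ev)
    if min_eig < -psd_tol:
        raise ValueError(
            f"kernel is not positive semidefinite: smallest normalised "
            f"eigenvalue {min_eig:.3e}"
        )
    return KernelMatrix(K=K, spec=spec)


def _cholesky_with_jitter(K: np.ndarray, max_tries: int = 3) -> tuple[np.ndarray, float]:
    if not K.any():  # zero kernel: signals are identically zero
        return np.zeros_like(K), 0.0
    jitter = 0.0
    base = 1e-10 * np.trace(K) / K.shape[0]
    for attempt in range(max_tries + 1):
        try:
            return np.linalg.cholesky(K + jitter * np.eye(K.shape[0])), jitter
        except np.linalg.LinAlgError:
            jitter = base * 10**attempt if attempt > 0 else base
            logger.warning(
                "Cholesky failed; retrying with diagonal jitter %.3e", jitter
            )
    raise np.linalg.LinAlgError(
        f"Cholesky failed after {max_tries} jitter escalations (last {jitter:.3e})"
    )


def sample_signals(
    kernel: KernelMatrix, spec: SurrogateSpec | None = None, seed: int = 0
) -> SurrogateSample:
    """Draw surrogate signals from the kernel.

    Per realization, cosine coefficients c = L u and sine coefficients
    s = L v with K = L L^T and u, v i.i.d. standard normal; source m's
    signal is x_m[t] = sum_n c_mn cos(pi n t / H) + s_mn sin(pi n t / H)
    for t = 0 .. 2H.  Identical spec and seed give identical signals.
    """
    if spec is None:
        spec = kernel.spec
    M, H, W = spec.M, spec.n_harmonics, spec.n_realizations
    rng = np.random.default_rng(seed)
    Lc, jitter = _cholesky_with_jitter(kernel.K)
    kernel.jitter = jitter

    U = rng.standard_normal((M * H, W))
    V = rng.standard_normal((M * H, W))
    # rows of K are ordered harmonic-major: index M*(n-1) + i
    C = (Lc @ U).reshape(H, M, W).transpose(2, 1, 0)  # (W, M, H)
    S_ = (Lc @ V).reshape(H, M, W).transpose(2, 1, 0)

    t = np.arange(2 * H + 1)
    n = np.arange(1, H + 1)
    phase = np.pi * np.outer(n, t) / H  # (H, T)
    cos_t, sin_t = np.cos(phase), np.sin(phase)
    signals = np.einsum("wmh,ht->wtm", C, cos_t) + np.einsum(
        "wmh,ht->wtm", S_, sin_t
    )
    coeffs = np.stack([C, S_], axis=-1)  # (W, M, H, 2)
    return SurrogateSample(
        signals=signals, coeffs=coeffs, spec=spec, kernel=kernel, seed=seed
    )


def estimate_kernel_correlations(
    coeffs: np.ndarray, separations: np.ndarray | None = None
) -> np.ndarray:
    """Empirical per-harmonic coefficient correlations vs index separation.

    ``coeffs`` has shape (realizations, M, H, 2).  For each harmonic and
    separation d, the correlation pools cosine and sine coefficients over
    all ordered source pairs with |i - j| = d, normalised by the pooled
    per-harmonic coefficient variance.  Returns an (H, n_separations)
    array.
    """
    W, M, H, _ = coeffs.shape
    if separations is None:
        separations = np.arange(M)
    separations = np.asarray(separations, dtype=int)
    out = np.zeros((H, len(separations)))
    a = coeffs[..., 0]  # (W, M, H)
    b = coeffs[..., 1]
    sig2 = np.mean(a**2 + b**2, axis=(0, 1)) / 2.0  # (H,)
    for si, d in enumerate(separations):
        prods = []
        for i in range(M):
            j = i + d
            if j >= M:
                continue
            prods.append(np.mean(a[:, i] * a[:, j] + b[:, i] * b[:, j], axis=0))
        cross = np.mean(prods, axis=0) / 2.0  # (H,)
        out[:, si] = cross / sig2
    return out
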