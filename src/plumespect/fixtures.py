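"""Small deterministic datasets for unit testing and examples.

All fixtures are 2-4 sources and at most a few thousand samples, generated
programmatically:

* ``tone``       — both sources carry the same pure cosine at harmonic 3 of
                   a 1-second window (one scaled), so the decomposition has
                   a single known coefficient pair per window;
* ``quadrature`` — the second source is the 90-degree-shifted tone, giving
                   in-phase correlation ~0 and out-of-phase ~1 at the tone
                   harmonic;
* ``ar1-pair``   — two AR(1) processes driven by correlated innovations;
                   with equal AR coefficients the coefficient correlation
                   at every frequency equals the innovation correlation
                   (flat coherence), a closed-form target.
"""
from __future__ import annotations

import numpy as np

from .spectral import TimeSeriesSet

__all__ = ["make_fixture", "FIXTURE_KINDS", "AR1_PHI", "AR1_INNOVATION_CORR"]

FIXTURE_KINDS = ("tone", "quadrature", "ar1-pair")

TONE_HARMONIC = 3
AR1_PHI = 0.8
AR1_INNOVATION_CORR = 0.6
_FS = 32.0
_WINDOWS = 64  # at 0.5 s hop: ~33 s of data


def make_fixture(kind: str, seed: int = 0) -> TimeSeriesSet:
    rng = np.random.default_rng(seed)
    L = int(_FS)  # 1-second window
    T = (_WINDOWS + 1) * L // 2 + L
    t = np.arange(T) / _FS
    if kind == "tone":
        x = np.cos(2 * np.pi * TONE_HARMONIC * t)
        values = np.column_stack([x, 0.5 * x])
    elif kind == "quadrature":
        x = np.cos(2 * np.pi * TONE_HARMONIC * t)
        y = np.sin(2 * np.pi * TONE_HARMONIC * t)
        values = np.column_stack([x, y])
    elif kind == "ar1-pair":
        cov = np.array([[1.0, AR1_INNOVATION_CORR], [AR1_INNOVATION_CORR, 1.0]])
        e = rng.multivariate_normal(np.zeros(2), cov, size=T)
        values = np.zeros((T, 2))
        for i in range(1, T):
            values[i] = AR1_PHI * values[i - 1] + e[i]
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    positions = np.array([[0.0, 0.0], [0.0, 0.0075]])
    return TimeSeriesSet(
        values=values,
        sample_rate=_FS,
        positions=positions,
        pitch=0.025,
        label=f"fixture:{kind}",
    )
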