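"""Integral length scales from velocity autocorrelation functions.

The integral length scale L_U characterises the size of the dominant,
energy-containing eddies and contextualises source separations.  Along a
chosen axis the two-point velocity autocorrelation at displacement r is

    Q(r) = [ <u(t; p) u(t; p + r)>_t + <u(t; p) u(t; p - r)>_t ] / 2,

falling back to the available side at domain edges; the normalised
function f(r) = Q(r) / Q(0) is integrated over displacement by a
rectangle rule, L_U = sum_n f(n dr) dr.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VelocityTransect", "autocorrelation", "integral_length_scale"]


@dataclass
class VelocityTransect:
    """Velocity timeseries at a reference point and regular displacements.

    ``u_pos[t, n]`` is the velocity component at displacement +n*dr from
    the reference (n = 0 is the reference itself); ``u_neg`` the same in
    the negative direction, or None at a domain edge.  ``dr`` is the
    displacement step in metres (0.02 pitch by convention).
    """

    u_pos: np.ndarray
    dr: float
    u_neg: np.ndarray | None = None
    axis: str = "y"

    def __post_init__(self) -> None:
        self.u_pos = np.asarray(self.u_pos, dtype=float)
        if self.u_neg is not None:
            self.u_neg = np.asarray(self.u_neg, dtype=float)
            if self.u_neg.shape != self.u_pos.shape:
                raise ValueError("u_neg must match u_pos in shape")
        if self.dr <= 0:
            raise ValueError("dr must be positive")
        if self.u_pos.ndim != 2:
            raise ValueError("u_pos must be time x displacement")
        if np.var(self.u_pos[:, 0]) <= 0:
            raise ValueError("reference series has zero variance")


def autocorrelation(transect: VelocityTransect) -> np.ndarray:
    """Normalised two-point autocorrelation f(r) over displacements.

    Time means are removed from each series before correlating (standard
    turbulence convention); positive- and negative-displacement averages
    are combined where both exist.
    """
    u = transect.u_pos - transect.u_pos.mean(axis=0, keepdims=True)
    ref = u[:, 0]
    q_pos = np.mean(ref[:, None] * u, axis=0)
    if transect.u_neg is not None:
        un = transect.u_neg - transect.u_neg.mean(axis=0, keepdims=True)
        q_neg = np.mean(un[:, 0][:, None] * un, axis=0)
        q = 0.5 * (q_pos + q_neg)
    else:
        q = q_pos
    if q[0] <= 0:
        raise ValueError("zero variance at reference point")
    return q / q[0]


def integral_length_scale(
    f: np.ndarray, dr: float, truncate_first_zero: bool = False
) -> float:
    """Rectangle-rule integral L_U = sum_n f(n dr) dr.

    Negative lobes of f are included by default; ``truncate_first_zero``
    optionally stops the sum at the first zero crossing.
    """
    f = np.asarray(f, dtype=float)
    if truncate_first_zero:
        neg = np.nonzero(f < 0)[0]
        if len(neg):
            f = f[: neg[0]]
    return float(np.sum(f) * dr)
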