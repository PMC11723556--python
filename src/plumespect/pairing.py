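"""Pooling Fourier coefficients across source pairs at each separation.

For each signed separation s, coefficients from all ordered source pairs a
distance s apart are pooled over time windows into a 2 x N(s) matrix
(first-source coefficients on top, second-source below; cosine and sine
coefficients concatenated).  Bivariate-Gaussian statistics are then
estimated with uncentred second moments (the coefficients are zero-mean
under temporal stationarity):

* principal variances lambda(s), mu(s) along the [1, 1] and [1, -1] axes,
* pooled marginal variance sigma_n^2 = lambda(0) / 2,
* in-phase correlation   rho_n(s)      = <ac + bd> / (2 sigma_n^2),
* out-of-phase correlation rho_perp(s) = <bc - ad> / (2 sigma_n^2),
* coupling gain beta = sqrt(rho^2 + rho_perp^2), phase theta =
  atan2(rho_perp, rho), residual variance eta^2 = sigma^2 (1 - beta^2).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectral import TrigCoefficients

logger = logging.getLogger(__name__)

__all__ = [
    "PairSet",
    "CoefficientStats",
    "build_pairs",
    "stack",
    "principal_variances",
    "sigma2",
    "coupling_stats",
    "pair_statistics",
]


@dataclass
class PairSet:
    """Ordered source pairs grouped by signed separation.

    ``pairs_at[s]`` lists every ordered pair (i, j) whose signed separation
    (coordinate of i minus coordinate of j along the chosen axis) equals s.
    Separation 0 holds the self-pairs (i, i).  ``units`` is "m", "pitch" or
    "index".
    """

    separations: np.ndarray
    pairs_at: dict
    units: str = "m"

    def n_of(self, s: float, n_windows: int) -> int:
        """N(s) = 2 x windows x ordered pairs (sine + cosine concatenated)."""
        return 2 * n_windows * len(self.pairs_at[self._key(s)])

    def _key(self, s: float) -> float:
        idx = np.argmin(np.abs(self.separations - s))
        if not np.isclose(self.separations[idx], s, rtol=0, atol=1e-9):
            raise KeyError(f"no pairs at separation {s}")
        return float(self.separations[idx])

    def pairs(self, s: float) -> list:
        return self.pairs_at[self._key(s)]

    def folded(self) -> "PairSet":
        """Merge +s and -s groups (symmetric configurations)."""
        pairs_at: dict = {}
        for s, p in self.pairs_at.items():
            key = abs(s)
            pairs_at.setdefault(key, [])
            pairs_at[key].extend(p)
        seps = np.array(sorted(pairs_at))
        return PairSet(separations=seps, pairs_at=pairs_at, units=self.units)


@dataclass
class CoefficientStats:
    """Bivariate-Gaussian coefficient statistics at one (harmonic, separation)."""

    harmonic: int
    separation: float
    sigma2: float
    lam: float
    mu: float
    rho: float
    rho_perp: float
    beta: float
    theta: float
    eta2: float
    n_samples: int


def build_pairs(
    positions: np.ndarray,
    distances: np.ndarray | None = None,
    units: str = "m",
    pitch: float = 1.0,
    axis: int = 1,
    tol: float = 1e-9,
    include_self: bool = True,
) -> PairSet:
    """Group ordered source pairs by signed separation along ``axis``.

    The separation of the ordered pair (i, j) is the signed coordinate
    difference pos[i, axis] - pos[j, axis]; with ``units="pitch"`` it is
    divided by ``pitch``.  Separations are binned with tolerance ``tol``
    (exact on simulation grids).  If ``distances`` is given, only those
    separations are retained; requesting a separation with no pairs yields
    an empty, flagged group.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim == 1:
        coord = positions
    else:
        coord = positions[:, axis]
    if units == "pitch":
        coord = coord / pitch
    S = len(coord)
    if S < 2:
        raise ValueError("need at least 2 sources")

    groups: dict = {}
    for i in range(S):
        for j in range(S):
            if i == j and not include_self:
                continue
            d = coord[i] - coord[j]
            key = round(d / tol) * tol if tol > 0 else d
            key = 0.0 if key == 0 else float(key)
            groups.setdefault(key, []).append((i, j))

    if distances is not None:
        wanted = {}
        for s in np.atleast_1d(distances):
            keys = [k for k in groups if abs(k - s) <= max(tol, 1e-12)]
            if keys:
                wanted[float(s)] = groups[keys[0]]
            else:
                logger.warning("no source pair at separation %s; empty group", s)
                wanted[float(s)] = []
        groups = wanted

    seps = np.array(sorted(groups))
    return PairSet(separations=seps, pairs_at=groups, units=units)


def stack(
    coeffs: TrigCoefficients, pairset: PairSet, n: int, s: float
) -> np.ndarray:
    """Assemble the 2 x N(s) matrix of paired harmonic-n coefficients.

    Row 1 concatenates the cosine then sine coefficients, over all windows,
    of the first source of each ordered pair at separation ``s``; row 2
    holds the corresponding coefficients of the second sources.  Windows in
    which either source's segment is degenerate are dropped.
    """
    if not 0 <= n <= coeffs.n_harmonics:
        raise ValueError(f"harmonic {n} out of range 0..{coeffs.n_harmonics}")
    pairs = pairset.pairs(s)
    top, bot = [], []
    for i, j in pairs:
        ok = coeffs.valid[:, i] & coeffs.valid[:, j]
        for comp in (0, 1):  # cosine block then sine block
            top.append(coeffs.coeffs[ok, i, n, comp])
            bot.append(coeffs.coeffs[ok, j, n, comp])
    if not top:
        return np.zeros((2, 0))
    return np.vstack([np.concatenate(top), np.concatenate(bot)])


def principal_variances(data: np.ndarray) -> tuple[float, float]:
    """Uncentred variances of the projections onto [1, 1]/sqrt2, [1, -1]/sqrt2.

    Coefficients are zero-mean by stationarity, so second moments are
    uncentred.
    """
    data = np.asarray(data, dtype=float)
    if data.shape[0] != 2 or data.shape[1] < 2:
        raise ValueError("need a 2 x N matrix with N >= 2")
    lam = np.mean(((data[0] + data[1]) / np.sqrt(2.0)) ** 2)
    mu = np.mean(((data[0] - data[1]) / np.sqrt(2.0)) ** 2)
    return float(lam), float(mu)


def sigma2(coeffs: TrigCoefficients, pairset: PairSet | None, n: int) -> float:
    """Pooled (uncentred) variance of all harmonic-n coefficients.

    Equals lambda_n(0) / 2, the marginal coefficient variance, pooled over
    sources, windows, and sine/cosine components.
    """
    if not 0 <= n <= coeffs.n_harmonics:
        raise ValueError(f"harmonic {n} out of range")
    vals = coeffs.coeffs[:, :, n, :][coeffs.valid]
    return float(np.mean(vals**2))


def coupling_stats(
    coeffs: TrigCoefficients,
    pairset: PairSet,
    n: int,
    s: float,
    sigma2_n: float | None = None,
) -> CoefficientStats:
    """Estimate (sigma^2, lambda, mu, rho, rho_perp, beta, theta, eta^2).

    rho_hat    = <ac + bd> / (2 sigma_n^2)  (equal to (lambda - mu) /
                 (2 sigma_n^2) under uncentred moments),
    rho_perp   = <bc - ad> / (2 sigma_n^2).
    """
    if sigma2_n is None:
        sigma2_n = sigma2(coeffs, pairset, n)
    if sigma2_n <= 0:
        raise ValueError(f"degenerate harmonic {n}: sigma^2 = 0")
    pairs = pairset.pairs(s)
    data = stack(coeffs, pairset, n, s)
    lam, mu = principal_variances(data)

    in_sum, out_sum, count = 0.0, 0.0, 0
    for i, j in pairs:
        ok = coeffs.valid[:, i] & coeffs.valid[:, j]
        a = coeffs.coeffs[ok, i, n, 0]
        b = coeffs.coeffs[ok, i, n, 1]
        c = coeffs.coeffs[ok, j, n, 0]
        d = coeffs.coeffs[ok, j, n, 1]
        in_sum += np.sum(a * c + b * d)
        out_sum += np.sum(b * c - a * d)
        count += a.size
    rho = in_sum / count / (2.0 * sigma2_n)
    rho_perp = out_sum / count / (2.0 * sigma2_n)
    beta = float(np.hypot(rho, rho_perp))
    theta = float(np.arctan2(rho_perp, rho))
    eta2 = float(sigma2_n * (1.0 - beta**2))
    return CoefficientStats(
        harmonic=n,
        separation=float(s),
        sigma2=float(sigma2_n),
        lam=lam,
        mu=mu,
        rho=float(rho),
        rho_perp=float(rho_perp),
        beta=beta,
        theta=theta,
        eta2=eta2,
        n_samples=data.shape[1],
    )


def pair_statistics(
    coeffs: TrigCoefficients,
    pairset: PairSet,
    harmonics: np.ndarray | None = None,
) -> pd.DataFrame:
    """Tidy table of coefficient statistics per (harmonic, separation)."""
    if harmonics is None:
        harmonics = np.arange(1, coeffs.n_harmonics + 1)
    rows = []
    for n in harmonics:
        s2 = sigma2(coeffs, pairset, int(n))
        if s2 <= 0:
            logger.warning("skipping degenerate harmonic %d", n)
            continue
        for s in pairset.separations:
            if not pairset.pairs(s):
                continue
            st = coupling_stats(coeffs, pairset, int(n), s, sigma2_n=s2)
            rows.append(
                {
                    "harmonic": int(n),
                    "harmonic_hz": n * coeffs.fundamental_hz,
                    "separation": st.separation,
                    "sigma2": st.sigma2,
                    "lambda": st.lam,
                    "mu": st.mu,
                    "rho": st.rho,
                    "rho_perp": st.rho_perp,
                    "beta": st.beta,
                    "theta": st.theta,
                    "eta2": st.eta2,
                    "n_samples": st.n_samples,
                }
            )
    return pd.DataFrame(rows)
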