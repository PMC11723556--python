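"""Model/Results objects tying the analysis stages together.

:class:`PlumeCorrelationModel` is built from a multisource concentration
:class:`~plumespect.spectral.TimeSeriesSet` (or directly from precomputed
trigonometric coefficients) and its :meth:`~PlumeCorrelationModel.fit`
estimates, per harmonic:

1. the pooled coefficient variance sigma_n^2 and the in-/out-of-phase
   coefficient correlations rho_n(s), rho_n_perp(s) at every source
   separation s (pooled over ordered source pairs and time windows);
2. an exponential decay fit rho_n(s) = (1 - b_n) e^{-s/gamma_n} + b_n over
   separations up to one pitch;
3. the closed-form Fisher information I(n, s) about source separation;
4. the spectral trend of the information — a Huber regression slope of
   log10 I on frequency per separation (the "elbow" profile);
5. optional bootstrap percentile bands (resampling time windows with
   replacement) for rho, I and the elbow slopes.

:class:`CorrelationMixtureModel` fits the distribution of observed
correlation components with the sandwiched exponential / Gamma / GIG
families, optionally with an intermittency mixture, by EM.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import corrmodels, pairing
from .fisher import (
    DecayFit,
    ElbowResult,
    RHO_CLIP,
    elbow_regression,
    fisher_info,
    fit_decay,
)
from .pairing import PairSet, build_pairs, pair_statistics
from .spectral import TimeSeriesSet, TrigCoefficients, WindowSpec, decompose

__all__ = [
    "PlumeCorrelationModel",
    "PlumeCorrelationResults",
    "CorrelationMixtureModel",
    "CorrelationMixtureResults",
    "rho_grid",
]


def rho_grid(
    coeffs: TrigCoefficients,
    pairset: PairSet,
    window_idx: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """In-phase correlation rho_n(s) for all harmonics and separations.

    Returns ``(rho, sigma2)`` with ``rho`` of shape (n_harmonics,
    n_separations) (harmonic index 1-based, DC excluded) and ``sigma2`` the
    pooled per-harmonic coefficient variance.  ``window_idx`` selects (and
    may repeat, for bootstrap resampling) time windows.
    """
    A = coeffs.coeffs
    valid = coeffs.valid
    if window_idx is not None:
        A = A[window_idx]
        valid = valid[window_idx]
    H = coeffs.n_harmonics
    sq = (A**2).sum(axis=-1)  # (W, S, H+1), a^2 + b^2
    mask = valid[..., None]
    sigma2 = (sq * mask).sum(axis=(0, 1)) / (2.0 * valid.sum())
    seps = pairset.separations
    rho = np.zeros((H, len(seps)))
    for si, s in enumerate(seps):
        tot = np.zeros(H + 1)
        count = 0
        for i, j in pairset.pairs(s):
            ok = valid[:, i] & valid[:, j]
            ai, aj = A[ok, i], A[ok, j]  # (Wok, H+1, 2)
            tot += (ai * aj).sum(axis=(0, 2))
            count += int(ok.sum())
        if count:
            rho[:, si] = tot[1:] / count / (2.0 * sigma2[1:])
        else:
            rho[:, si] = np.nan
    return rho, sigma2[1:]


@dataclass
class PlumeCorrelationResults:
    """Estimates, fits, information grid and uncertainty bands."""

    model: "PlumeCorrelationModel"
    stats: pd.DataFrame
    rho: np.ndarray  # (H, n_separations)
    sigma2: np.ndarray  # (H,)
    separations: np.ndarray
    frequencies_hz: np.ndarray  # (H,)
    decay: pd.DataFrame
    decay_fits: list
    fisher_grid: np.ndarray  # (H, n_positive_separations)
    fisher_separations: np.ndarray
    elbow: ElbowResult
    n_boot: int = 0
    seed: int = 0
    rho_percentiles: np.ndarray | None = None
    fisher_percentiles: np.ndarray | None = None
    slope_percentiles: np.ndarray | None = None

    def summary(self) -> str:
        lines = [
            "Plume spectral correlation analysis",
            "===================================",
            f"label:        {self.model.label}",
            f"windows:      {self.model.coeffs.n_windows}"
            f" x {self.model.coeffs.segment_length} samples"
            f" ({self.model.window.shape}, overlap {self.model.window.overlap})",
            f"sources:      {self.model.coeffs.n_sources}",
            f"harmonics:    {len(self.frequencies_hz)}"
            f" (fundamental {self.model.coeffs.fundamental_hz:.3g} Hz)",
            f"separations:  {len(self.separations)}"
            f" ({self.separations.min():.3g} .. {self.separations.max():.3g}"
            f" {self.model.units})",
            f"decay fit:    rho(s) = (1-b) exp(-s/gamma) + b,"
            f" s <= {self.model.fit_range_max:g}",
            "",
            "harmonic  freq_Hz     gamma         b   near_flat",
        ]
        for _, row in self.decay.iterrows():
            lines.append(
                f"{int(row['harmonic']):8d}  {row['harmonic_hz']:7.3g}"
                f"  {row['gamma']:8.4g}  {row['b']:8.4g}"
                f"   {bool(row['near_flat'])!s:>9}"
            )
        lines.append("")
        lines.append(
            "elbow slopes (log10 I per Hz) over "
            f"{self.elbow.freq_range[0]:g}-{self.elbow.freq_range[1]:g} Hz:"
        )
        for s, b in zip(self.elbow.separations, self.elbow.slopes):
            band = ""
            if self.slope_percentiles is not None:
                j = int(np.argmin(np.abs(self.elbow.separations - s)))
                band = (
                    f"   [{self.slope_percentiles[0, j]:+.4f},"
                    f" {self.slope_percentiles[2, j]:+.4f}]"
                )
            lines.append(f"  s = {s:7.3g}: beta = {b:+.4f}{band}")
        return "\n".join(lines)

    def fisher_table(self) -> pd.DataFrame:
        rows = []
        for hi, f in enumerate(self.frequencies_hz):
            for si, s in enumerate(self.fisher_separations):
                row = {
                    "harmonic": hi + 1,
                    "harmonic_hz": f,
                    "separation": s,
                    "fisher_info": self.fisher_grid[hi, si],
                }
                if self.fisher_percentiles is not None:
                    row["fisher_p5"] = self.fisher_percentiles[0, hi, si]
                    row["fisher_p50"] = self.fisher_percentiles[1, hi, si]
                    row["fisher_p95"] = self.fisher_percentiles[2, hi, si]
                rows.append(row)
        return pd.DataFrame(rows)

    def elbow_table(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"separation": self.elbow.separations, "slope": self.elbow.slopes}
        )
        if self.slope_percentiles is not None:
            out["slope_p5"] = self.slope_percentiles[0]
            out["slope_p50"] = self.slope_percentiles[1]
            out["slope_p95"] = self.slope_percentiles[2]
        return out

    def plot_heatmap(self, ax=None, log10: bool = True):
        """Fisher information heatmap (frequency x separation)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        Z = self.fisher_grid
        if log10:
            with np.errstate(divide="ignore", invalid="ignore"):
                Z = np.log10(Z)
        m = ax.pcolormesh(self.fisher_separations, self.frequencies_hz, Z)
        ax.set_xlabel(f"separation ({self.model.units})")
        ax.set_ylabel("frequency (Hz)")
        ax.figure.colorbar(m, ax=ax, label="log10 I" if log10 else "I")
        return ax

    def plot_elbow(self, ax=None):
        """Elbow profile: information-vs-frequency slope per separation."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.axhline(0.0, color="k", lw=0.5)
        ax.plot(self.elbow.separations, self.elbow.slopes, "o-")
        if self.slope_percentiles is not None:
            ax.fill_between(
                self.elbow.separations,
                self.slope_percentiles[0],
                self.slope_percentiles[2],
                alpha=0.3,
            )
        ax.set_xlabel(f"separation ({self.model.units})")
        ax.set_ylabel("slope of log10 I vs frequency (1/Hz)")
        return ax


class PlumeCorrelationModel:
    """Spectral Fisher-information analysis of multisource plume data.

    Parameters
    ----------
    series : TimeSeriesSet, optional
        Concentration timeseries; decomposed with ``window`` at fit time.
    window : WindowSpec
        STFT configuration (default: 1-second boxcar, half overlap).
    coeffs : TrigCoefficients, optional
        Precomputed coefficients (alternative to ``series``).
    positions : ndarray, optional
        Source coordinates when building from coefficients.
    units : {"pitch", "m", "index"}
        Separation units for pooling and fits.
    fold : bool
        Merge +s and -s separations (symmetric configurations).
    fit_range_max : float
        Largest separation used in the decay fits (default 1 pitch).
    freq_range : tuple
        Frequency band (Hz) for the elbow regression.
    """

    def __init__(
        self,
        series: TimeSeriesSet | None = None,
        window: WindowSpec | None = None,
        *,
        coeffs: TrigCoefficients | None = None,
        positions: np.ndarray | None = None,
        pitch: float | None = None,
        units: str = "pitch",
        fold: bool = True,
        fit_range_max: float = 1.0,
        freq_range: tuple = (1.0, 15.0),
        separation_axis: int = 1,
    ) -> None:
        if series is None and coeffs is None:
            raise ValueError("provide a TimeSeriesSet or TrigCoefficients")
        self.series = series
        self.window = window or WindowSpec()
        self._coeffs = coeffs
        if positions is None and series is not None:
            positions = series.positions
        if positions is None:
            raise ValueError("source positions are required")
        self.positions = np.asarray(positions, dtype=float)
        self.pitch = pitch if pitch is not None else (
            series.pitch if series is not None else 1.0
        )
        self.units = units
        self.fold = fold
        self.fit_range_max = fit_range_max
        self.freq_range = freq_range
        self.separation_axis = separation_axis
        self.label = series.label if series is not None else "coefficients"

    @classmethod
    def from_coefficients(
        cls, coeffs: TrigCoefficients, positions: np.ndarray, **kwargs
    ) -> "PlumeCorrelationModel":
        return cls(coeffs=coeffs, positions=positions, **kwargs)

    @property
    def coeffs(self) -> TrigCoefficients:
        if self._coeffs is None:
            self._coeffs = decompose(self.series, self.window)
        return self._coeffs

    def _pairset(self) -> PairSet:
        ps = build_pairs(
            self.positions,
            units=self.units if self.units != "index" else "m",
            pitch=self.pitch,
            axis=self.separation_axis,
        )
        return ps.folded() if self.fold else ps

    def _grids(
        self, pairset: PairSet, window_idx: np.ndarray | None
    ) -> tuple[np.ndarray, np.ndarray, list, np.ndarray]:
        """(rho, sigma2, decay fits, fisher grid) for the given windows."""
        rho, sigma2 = rho_grid(self.coeffs, pairset, window_idx)
        seps = pairset.separations
        pos = seps > 0
        H = rho.shape[0]
        fits: list = []
        I = np.full((H, int(pos.sum())), np.nan)
        for h in range(H):
            try:
                fit = fit_decay(seps, rho[h], fit_range_max=self.fit_range_max)
            except (ValueError, RuntimeError):
                fits.append(None)
                continue
            fits.append(fit)
            if fit.converged:
                I[h] = fisher_info(fit, seps[pos])
        return rho, sigma2, fits, I

    def fit(
        self,
        n_boot: int = 0,
        seed: int = 0,
        harmonics: np.ndarray | None = None,
    ) -> PlumeCorrelationResults:
        coeffs = self.coeffs
        pairset = self._pairset()
        stats = pair_statistics(coeffs, pairset, harmonics=harmonics)
        rho, sigma2, fits, I = self._grids(pairset, None)
        seps = pairset.separations
        pos_seps = seps[seps > 0]
        freqs = np.arange(1, coeffs.n_harmonics + 1) * coeffs.fundamental_hz
        elbow = elbow_regression(I, freqs, pos_seps, freq_range=self.freq_range)

        decay_rows = []
        for h, fit in enumerate(fits):
            decay_rows.append(
                {
                    "harmonic": h + 1,
                    "harmonic_hz": freqs[h],
                    "gamma": fit.gamma if fit else np.nan,
                    "b": fit.b if fit else np.nan,
                    "residual_norm": fit.residual_norm if fit else np.nan,
                    "near_flat": fit.near_flat if fit else True,
                }
            )

        res = PlumeCorrelationResults(
            model=self,
            stats=stats,
            rho=rho,
            sigma2=sigma2,
            separations=seps,
            frequencies_hz=freqs,
            decay=pd.DataFrame(decay_rows),
            decay_fits=fits,
            fisher_grid=I,
            fisher_separations=pos_seps,
            elbow=elbow,
            n_boot=n_boot,
            seed=seed,
        )
        if n_boot > 0:
            self._bootstrap(res, pairset, n_boot, seed)
        return res

    def _bootstrap(
        self,
        res: PlumeCorrelationResults,
        pairset: PairSet,
        n_boot: int,
        seed: int,
    ) -> None:
        """Window-resampling percentile bands for rho, I and elbow slopes.

        Windows are resampled with replacement jointly across sources, so
        within-window cross-source pairing is preserved.
        """
        rng = np.random.default_rng(seed)
        W = self.coeffs.n_windows
        rho_draws, I_draws, slope_draws = [], [], []
        for _ in range(n_boot):
            idx = rng.integers(0, W, size=W)
            rho_b, _, _, I_b = self._grids(pairset, idx)
            el = elbow_regression(
                I_b,
                res.frequencies_hz,
                res.fisher_separations,
                freq_range=self.freq_range,
            )
            rho_draws.append(rho_b)
            I_draws.append(I_b)
            slope_draws.append(el.slopes)
        pct = (5.0, 50.0, 95.0)
        res.rho_percentiles = np.nanpercentile(np.stack(rho_draws), pct, axis=0)
        res.fisher_percentiles = np.nanpercentile(np.stack(I_draws), pct, axis=0)
        res.slope_percentiles = np.nanpercentile(np.stack(slope_draws), pct, axis=0)
        res.elbow.percentiles = res.slope_percentiles


@dataclass
class CorrelationMixtureResults:
    """EM-fitted correlation distribution with intermittency."""

    fit: corrmodels.CorrelationModelFit
    observations: np.ndarray
    family: str
    intermittent: bool

    @property
    def params(self) -> corrmodels.SandwichParams:
        return self.fit.params

    @property
    def iota(self) -> float:
        return self.fit.iota

    @property
    def nu2(self) -> float:
        return self.fit.nu2

    @property
    def converged(self) -> bool:
        return self.fit.converged

    def fit_quality(self, y: np.ndarray | None = None) -> corrmodels.FitQuality:
        obs = self.observations if y is None else y
        return corrmodels.fit_quality(self.fit, obs)

    def summary(self) -> str:
        p = self.fit.params
        lines = [
            "Correlation distribution fit (EM)",
            "---------------------------------",
            f"family:       {self.family}"
            + (" + intermittency" if self.intermittent else ""),
            f"observations: {len(self.observations)}",
            f"positive branch params: {tuple(round(v, 6) for v in p.pos)}",
            f"negative branch params: {tuple(round(v, 6) for v in p.neg)}",
        ]
        if self.intermittent:
            lines.append(f"iota (true-correlation fraction): {self.iota:.4f}")
            lines.append(f"noise variance nu^2:              {self.nu2:.3e}")
        q = self.fit_quality()
        lines.append(f"fit quality (1 - max CDF gap):    {q.value:.4f}")
        lines.append(
            f"converged: {self.converged} in {self.fit.n_iter} iterations"
        )
        return "\n".join(lines)


class CorrelationMixtureModel:
    """EM fit of a sandwiched correlation distribution to observed r_n.

    ``family`` is "exponential", "gamma" or "gig"; with
    ``intermittent=True`` a Bernoulli mixture with a zero-mean Gaussian
    noise branch is fitted, shrinking the intermittency toward the prior
    mean ``iota0`` with strength ``prior_strength``.
    """

    def __init__(
        self,
        observations: np.ndarray,
        family: str = "exponential",
        intermittent: bool = False,
        iota0: float = 0.5,
        prior_strength: float = 1.0,
    ) -> None:
        self.observations = np.asarray(observations, dtype=float).ravel()
        self.family = family
        self.intermittent = intermittent
        self.iota0 = iota0
        self.prior_strength = prior_strength

    def fit(self, tol: float = 1e-8, max_iter: int = 500) -> CorrelationMixtureResults:
        fit = corrmodels.em_fit(
            self.observations,
            family=self.family,
            intermittent=self.intermittent,
            iota0=self.iota0,
            prior_strength=self.prior_strength,
            tol=tol,
            max_iter=max_iter,
        )
        return CorrelationMixtureResults(
            fit=fit,
            observations=self.observations,
            family=self.family,
            intermittent=self.intermittent,
        )
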