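"""Trend-plus-annual-sinusoid model for growth-axis records.

Fits ``y = b + m*x + A*sin(omega*x + phi)`` by least squares over the
physical coordinate ``x = t_index * delta_t``.  For a fixed angular
frequency the model is linear in ``(b, m, A*cos(phi), A*sin(phi))``, so
the fit profiles omega: solve the linear subproblem on a frequency grid,
then polish the best candidates with Levenberg-Marquardt.  The parameter
sign ambiguity ``(A, omega, phi) <-> (-A, omega, phi+pi)`` and the
reflection ``(A, -omega, pi - phi)`` are canonicalized to ``A >= 0``,
``omega > 0``, ``phi in [0, 2*pi)``.

A fitted sinusoid with a known period gives the growth rate directly:
an annual cycle at ``omega`` rad/cm corresponds to ``omega/2pi`` cycles/cm
and hence ``2pi/omega`` cm/yr of growth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .frequency import GrowthRate, growth_rate_from_frequency, radians_to_cycles
from .series import ForensicSeries

__all__ = ["SinusoidFit", "HarmonicTrendModel", "fit_annual_sinusoid"]


class SinusoidFitError(RuntimeError):
    """Raised when no start converges; carries the best partial fit."""

    def __init__(self, message: str, partial: "SinusoidFit | None" = None):
        super().__init__(message)
        self.partial = partial


@dataclass(frozen=True)
class SinusoidFit:
    """Least-squares parameters of ``b + m*x + A*sin(omega*x + phi)``.

    Units: ``intercept`` and ``amplitude`` in measurement units, ``slope``
    in units per physical unit, ``angular_freq`` in radians per physical
    unit, ``phase`` in radians, ``rss`` in squared units.
    """

    intercept: float
    slope: float
    amplitude: float
    angular_freq: float
    phase: float
    rss: float
    n: int = 0
    delta_t: float = 1.0

    @property
    def freq_cycles(self) -> float:
        """Cyclic frequency, cycles per physical unit."""
        return radians_to_cycles(self.angular_freq)

    def growth_rate(self, period_years: float = 1.0) -> GrowthRate:
        """Growth rate implied by reading the fitted cycle as one of the
        given period (annual by default)."""
        return growth_rate_from_frequency(self.freq_cycles, period_years)

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (
            self.intercept
            + self.slope * x
            + self.amplitude * np.sin(self.angular_freq * x + self.phase)
        )

    def summary(self) -> str:
        lines = [
            "Trend + sinusoid fit (least squares)",
            f"  N = {self.n}, delta_t = {self.delta_t:g}",
            f"  intercept  b     = {self.intercept:.6g}",
            f"  slope      m     = {self.slope:.6g}",
            f"  amplitude  A     = {self.amplitude:.6g}",
            f"  ang. freq  omega = {self.angular_freq:.6g} rad/unit"
            f"  ({self.freq_cycles:.6g} cycles/unit)",
            f"  phase      phi   = {self.phase:.6g} rad",
            f"  RSS              = {self.rss:.6g}",
        ]
        return "\n".join(lines)


def _linear_fit_at_omega(x: np.ndarray, y: np.ndarray, omega: float):
    """Profiled linear subproblem: b, m, and the two quadrature amplitudes."""
    X = np.column_stack(
        [np.ones_like(x), x, np.sin(omega * x), np.cos(omega * x)]
    )
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ coef) ** 2))
    return coef, rss


def _canonicalize(b, m, A, omega, phi):
    if omega < 0:
        # A sin(-wx + phi) = A sin(wx + (pi - phi)) reflected; keep magnitude
        omega, phi = -omega, math.pi - phi
    if A < 0:
        A, phi = -A, phi + math.pi
    phi = phi % (2.0 * math.pi)
    return b, m, A, omega, phi


class HarmonicTrendModel:
    """Trend + single-sinusoid model of a growth-axis record.

    Parameters
    ----------
    series : ForensicSeries
        The raw (not standardized) record; the model is fitted on the
        physical coordinate ``t_index * delta_t``.

    ``fit()`` returns a :class:`SinusoidFit`.
    """

    def __init__(self, series: ForensicSeries):
        if series.n < 8:
            raise ValueError("need N >= 8 observations to fit a sinusoid")
        self.series = series
        self.x = series.positions.astype(float)
        self.y = series.values.astype(float)

    def fit(
        self,
        init_freq: float | None = None,
        n_grid: int = 200,
        n_polish: int = 5,
    ) -> SinusoidFit:
        """Multistart profiled least squares.

        ``init_freq`` (radians per physical unit) seeds the grid when
        given; otherwise the grid spans from one cycle over four record
        lengths up to the angular Nyquist ``pi/delta_t``.
        """
        x, y = self.x, self.y
        span = x[-1] - x[0]
        lo = 2.0 * math.pi / (4.0 * (span + self.series.delta_t))
        hi = math.pi / self.series.delta_t
        omegas = np.geomspace(lo, hi, n_grid)
        if init_freq is not None:
            if init_freq <= 0:
                raise ValueError("init_freq must be positive (radians per unit)")
            omegas = np.unique(np.concatenate([omegas, [init_freq]]))

        profile = []
        for w in omegas:
            coef, rss = _linear_fit_at_omega(x, y, w)
            profile.append((rss, w, coef))
        profile.sort(key=lambda t: t[0])

        # trend-only reference: the sinusoid fit must not do worse
        T = np.column_stack([np.ones_like(x), x])
        tc, *_ = np.linalg.lstsq(T, y, rcond=None)
        rss_trend = float(np.sum((y - T @ tc) ** 2))

        best = None
        for rss0, w0, coef in profile[:n_polish]:
            b0, m0 = coef[0], coef[1]
            A0 = math.hypot(coef[2], coef[3])
            phi0 = math.atan2(coef[3], coef[2])

            def resid(p):
                b, m, A, w, phi = p
                return y - (b + m * x + A * np.sin(w * x + phi))

            try:
                sol = least_squares(
                    resid, [b0, m0, A0, w0, phi0], method="lm", max_nfev=2000
                )
            except Exception:
                continue
            rss = float(np.sum(sol.fun**2))
            if best is None or rss < best[0]:
                best = (rss, sol.x)

        if best is None:
            raise SinusoidFitError("no start converged in sinusoid fit")
        rss, (b, m, A, w, phi) = best
        b, m, A, w, phi = _canonicalize(b, m, A, w, phi)
        fit = SinusoidFit(
            intercept=float(b),
            slope=float(m),
            amplitude=float(A),
            angular_freq=float(w),
            phase=float(phi),
            rss=rss,
            n=self.series.n,
            delta_t=self.series.delta_t,
        )
        if fit.rss > rss_trend * (1 + 1e-9) or fit.angular_freq <= 0:
            raise SinusoidFitError(
                "sinusoid fit failed to improve on the trend-only fit",
                partial=fit,
            )
        return fit

    def residuals(self, fit: SinusoidFit) -> np.ndarray:
        """Residuals of the fitted model; feed these to standardization
        when the annual cycle itself should not dominate the spectrum."""
        return self.y - fit.predict(self.x)


def fit_annual_sinusoid(
    series: ForensicSeries, init_freq: float | None = None
) -> SinusoidFit:
    """Convenience wrapper: ``HarmonicTrendModel(series).fit(init_freq)``."""
    return HarmonicTrendModel(series).fit(init_freq=init_freq)
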