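"""Periodogram and smoothed spectral-density estimation.

The periodogram of a zero-mean series ``Y(1..N)`` on the Fourier grid
``lambda_j = 2*pi*j/N``, ``j = 1..[N/2]`` is

    I(lambda_j) = |sum_t Y(t) exp(-i*lambda_j*t)|^2 / (2*pi*N)

an (inconsistent) estimate of the spectral density ``f(lambda)``.  The
consistent estimate is a locally weighted moving average of periodogram
ordinates under a symmetric spectral window with unit-sum weights; its
sampling distribution is chi-square with effective degrees of freedom
``r = 2 / sum(w_j^2)`` per ordinate, which drives all band-power
inference downstream.

Frequencies are reported in cycles per observation (the radian grid
divided by 2*pi*); the zero frequency — the mean, removed in
preprocessing — is excluded from the grid.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .series import ForensicSeries, StandardizedSeries, preprocess

__all__ = [
    "Spectrum",
    "periodogram",
    "smooth_density",
    "effective_df",
    "find_peaks",
    "total_power",
    "daniell_weights",
    "modified_daniell_weights",
    "SpectralModel",
    "SpectrumResults",
]

_WINDOWS = {}


def _register(name):
    def deco(fn):
        _WINDOWS[name] = fn
        return fn

    return deco


@_register("daniell")
def daniell_weights(half_width: int) -> np.ndarray:
    """Boxcar-in-frequency window: 2h+1 equal weights summing to 1."""
    if half_width < 1:
        raise ValueError("half_width must be >= 1")
    m = 2 * half_width + 1
    return np.full(m, 1.0 / m)


@_register("modified_daniell")
def modified_daniell_weights(half_width: int) -> np.ndarray:
    """Daniell window with half-weighted endpoints (weights sum to 1)."""
    if half_width < 1:
        raise ValueError("half_width must be >= 1")
    w = np.full(2 * half_width + 1, 1.0)
    w[0] = w[-1] = 0.5
    return w / w.sum()


@dataclass(frozen=True)
class Spectrum:
    """Periodogram and (optionally) smoothed density on the Fourier grid.

    ``freqs`` are cycles per observation in (0, 0.5]; ``periodogram`` and
    ``density`` are power per radian frequency.  ``window_weights`` are the
    symmetric unit-sum smoothing weights and ``edf`` the chi-square
    effective degrees of freedom of one smoothed ordinate.
    """

    freqs: np.ndarray
    periodogram: np.ndarray
    n: int
    delta_t: float = 1.0
    density: np.ndarray | None = None
    window_name: str | None = None
    half_width: int | None = None
    window_weights: np.ndarray | None = None
    edf: float | None = None

    @property
    def delta_lambda(self) -> float:
        """Radian frequency spacing of the grid, 2*pi/N."""
        return 2.0 * math.pi / self.n

    @property
    def freqs_radians(self) -> np.ndarray:
        return self.freqs * 2.0 * math.pi

    def to_frame(self) -> pd.DataFrame:
        data = {"freq_cycles_per_obs": self.freqs, "periodogram": self.periodogram}
        if self.density is not None:
            data["density"] = self.density
        return pd.DataFrame(data)


def periodogram(series) -> Spectrum:
    """Periodogram on the Fourier grid ``j/N``, ``j = 1..[N/2]`` cycles/obs.

    Accepts a :class:`StandardizedSeries` (the intended input), a
    :class:`ForensicSeries`, or a plain array; inputs that are not
    mean-zero/unit-variance are analyzed as-is with a warning, since all
    the dimensionless band-power interpretation assumes standardization.
    """
    delta_t = 1.0
    if isinstance(series, StandardizedSeries):
        y = series.values
        delta_t = series.delta_t
    elif isinstance(series, ForensicSeries):
        y = series.values
        delta_t = series.delta_t
    else:
        y = np.asarray(series, dtype=float)
    n = y.size
    if n < 8:
        raise ValueError(f"periodogram needs N >= 8, got {n}")
    if abs(y.mean()) > 1e-6 or abs(y.std(ddof=1) - 1.0) > 1e-6:
        warnings.warn(
            "input is not standardized (mean 0, SD 1); dimensionless "
            "band-power conventions will not apply",
            stacklevel=2,
        )
    # rfft computes sum over t=0..N-1; the unit shift to t=1..N only
    # rotates the phase and leaves |.|^2 unchanged
    F = np.fft.rfft(y)
    m = n // 2
    I = (np.abs(F[1 : m + 1]) ** 2) / (2.0 * math.pi * n)
    freqs = np.arange(1, m + 1) / n
    return Spectrum(freqs=freqs, periodogram=I, n=n, delta_t=delta_t)


def effective_df(weights: np.ndarray) -> float:
    """Chi-square effective degrees of freedom of a smoothed ordinate,
    ``r = 2 / sum(w^2)`` for unit-sum weights.

    The raw periodogram (a single weight of 1) has r = 2; a Daniell
    window of half-width h has r = 2(2h+1).
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.size == 0:
        raise ValueError("weights must be a nonempty 1-D array")
    s = w.sum()
    if not math.isclose(s, 1.0, rel_tol=0, abs_tol=1e-8):
        raise ValueError(f"weights must sum to 1, got {s}")
    return 2.0 / float(np.sum(w**2))


def smooth_density(
    spectrum: Spectrum,
    window: str = "daniell",
    half_width: int | None = None,
) -> Spectrum:
    """Smoothed spectral-density estimate: symmetric weighted moving
    average of the periodogram along the grid.

    Edges are handled by symmetric reflection of the periodogram about
    the grid ends (the grid excludes the zero ordinate, so reflection is
    half-sample), which preserves constants and conserves total area.
    The default half-width, ``ceil(sqrt(N)/4)``, widens slowly with N so
    the estimate is consistent while adjacent smoothed ordinates stay
    nearly independent.
    """
    if half_width is None:
        half_width = max(1, math.ceil(math.sqrt(spectrum.n) / 4.0))
    try:
        weights = _WINDOWS[window](half_width)
    except KeyError:
        raise ValueError(
            f"unknown window {window!r}; available: {sorted(_WINDOWS)}"
        ) from None
    m = spectrum.periodogram.size
    if 2 * half_width + 1 >= m:
        raise ValueError(
            f"window span {2 * half_width + 1} too large for {m} grid ordinates"
        )
    padded = np.pad(spectrum.periodogram, half_width, mode="symmetric")
    dens = np.convolve(padded, weights, mode="valid")
    return replace(
        spectrum,
        density=dens,
        window_name=window,
        half_width=half_width,
        window_weights=weights,
        edf=effective_df(weights),
    )


def total_power(
    spectrum: Spectrum, which: str = "periodogram", fold_nyquist: bool = True
) -> float:
    """Integral ``sum_j 2*I(lambda_j)*dlambda`` over the whole grid.

    The factor 2 accounts for the negative frequencies.  With
    ``fold_nyquist`` (the default) the Nyquist ordinate of an even-length
    series — which has no negative-frequency partner — gets weight 1,
    making the sum equal the (population) variance of the zero-mean input
    exactly: the discrete Parseval identity.  With ``fold_nyquist=False``
    the plain factor-2 sum is returned, which window smoothing with
    reflecting edges conserves exactly.
    """
    vals = spectrum.periodogram if which == "periodogram" else spectrum.density
    if vals is None:
        raise ValueError("density not computed")
    g = np.full(vals.size, 2.0)
    if fold_nyquist and spectrum.n % 2 == 0:
        g[-1] = 1.0
    return float(np.sum(g * vals) * spectrum.delta_lambda)


def find_peaks(
    spectrum: Spectrum, min_prominence_fraction: float = 0.1
) -> list[tuple[float, float]]:
    """Local maxima of the smoothed density, ordered by height descending.

    Prominence is thresholded at ``min_prominence_fraction`` times the
    maximum density.  The first grid ordinate is excluded unless it
    dominates the whole spectrum (a boundary ordinate cannot be a proper
    local maximum but may still carry the main low-frequency power).
    """
    if spectrum.density is None:
        raise ValueError("density not computed; call smooth_density first")
    d = spectrum.density
    prom = min_prominence_fraction * float(d.max())
    idx, _ = _signal.find_peaks(d, prominence=prom)
    peaks = [(float(spectrum.freqs[i]), float(d[i])) for i in idx]
    if d[0] >= d.max():
        peaks.append((float(spectrum.freqs[0]), float(d[0])))
    peaks.sort(key=lambda p: -p[1])
    return peaks


class SpectralModel:
    """Spectral-density model of a growth-increment record.

    Wraps preprocessing + periodogram + window smoothing behind a
    model/results pair: ``SpectralModel(series).fit()`` returns a
    :class:`SpectrumResults` carrying the estimated spectrum, its
    effective degrees of freedom, and band-power methods.

    ``series`` may be raw (it is detrended and standardized first) or an
    already standardized series.
    """

    def __init__(self, series: ForensicSeries | StandardizedSeries):
        if isinstance(series, ForensicSeries):
            series = preprocess(series)
        self.series = series

    def fit(
        self, window: str = "daniell", half_width: int | None = None
    ) -> "SpectrumResults":
        spec = periodogram(self.series)
        spec = smooth_density(spec, window=window, half_width=half_width)
        return SpectrumResults(self, spec)


class SpectrumResults:
    """Fitted spectrum plus band-power inference entry points."""

    def __init__(self, model: SpectralModel, spectrum: Spectrum):
        self.model = model
        self.spectrum = spectrum

    @property
    def edf(self) -> float:
        return self.spectrum.edf

    def peaks(self, min_prominence_fraction: float = 0.1):
        return find_peaks(self.spectrum, min_prominence_fraction)

    def band_power(self, low: float, high: float, standardized: bool = True):
        from .bandpower import FrequencyBand, band_power

        return band_power(
            self.spectrum, FrequencyBand(low, high), standardized=standardized
        )

    def to_frame(self) -> pd.DataFrame:
        return self.spectrum.to_frame()

    def summary(self) -> str:
        s = self.spectrum
        top = self.peaks()[:3]
        lines = [
            "Smoothed spectral density estimate",
            f"  N = {s.n}, delta_t = {s.delta_t:g}, grid = {s.freqs.size} ordinates",
            f"  window = {s.window_name} (half-width {s.half_width}), "
            f"EDF per ordinate = {s.edf:.3g}",
            f"  total power (periodogram) = {total_power(s):.6g}",
        ]
        if top:
            lines.append("  leading peaks (cycles/obs, density):")
            for f, d in top:
                lines.append(f"    {f:.4f}  {d:.6g}")
        return "\n".join(lines)
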