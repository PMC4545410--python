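"""Band power (area under the spectral density) and its inference.

For a standardized series the area under the whole estimated density is
1, so the power in a frequency band is a dimensionless measure of
spectral shape.  On the Fourier grid with spacing ``dl = 2*pi/N``:

    AUC      = sum_{j in band} 2 * f(lambda_j) * dl
    Variance = sum_{j in band} 4 * f(lambda_j)^2 * dl^2

(the factor 2 counts the negative frequencies).  Each smoothed ordinate
is approximately ``f * chi2_r / r`` with r the window's effective degrees
of freedom, so the AUC is a weighted sum of chi-squares; it is modelled
as a single scaled chi-square ``c * chi2_R`` by moment matching:

    c = Var/(2*E),    R = 2*E^2/Var.

Confidence intervals come from the chi-square quantiles, the LF/HF ratio
of two disjoint bands is referred to an F distribution with the two
(non-integer) R values as degrees of freedom, and two independent
samples' AUCs are compared by a normal-reference t statistic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .spectrum import Spectrum

__all__ = [
    "FrequencyBand",
    "BandPower",
    "BandPowerCI",
    "RatioTestResult",
    "TwoSampleResult",
    "band_power",
    "moment_match",
    "band_power_ci",
    "bandwidth_adjust",
    "lf_hf_ratio_test",
    "two_sample_auc_test",
]


@dataclass(frozen=True)
class FrequencyBand:
    """Half-open band ``[low, high)`` in cycles per observation."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.low < self.high <= 0.5):
            raise ValueError(
                f"need 0 <= low < high <= 0.5, got [{self.low}, {self.high})"
            )

    @property
    def width(self) -> float:
        return self.high - self.low


@dataclass(frozen=True)
class BandPower:
    """Band power with its asymptotic variance and matched chi-square.

    ``auc`` is dimensionless for a standardized series; ``c`` and ``r_df``
    are the scale and degrees of freedom of the moment-matched
    ``c * chi2_R`` law, satisfying ``c = Var/(2*AUC)`` and
    ``R = AUC/c = 2*AUC^2/Var``.
    """

    auc: float
    variance: float
    c: float
    r_df: float
    band: FrequencyBand | None = None
    standardized: bool = True

    @property
    def se(self) -> float:
        return math.sqrt(self.variance)

    def ci(self, level: float = 0.95) -> "BandPowerCI":
        return band_power_ci(self, level=level)

    def summary(self) -> str:
        b = f"[{self.band.low:g}, {self.band.high:g})" if self.band else "?"
        return (
            f"Band {b}: AUC = {self.auc:.4g} (SE {self.se:.4g}), "
            f"chi-square match c = {self.c:.4g}, R = {self.r_df:.4g}"
        )


@dataclass(frozen=True)
class BandPowerCI:
    level: float
    sided: str  # "one" | "two"
    lower: float
    upper: float


@dataclass(frozen=True)
class RatioTestResult:
    """F-test of the ratio of two band powers (e.g. LF/HF)."""

    ratio: float
    scale: float
    df1: float
    df2: float
    p_one: float
    p_two: float


@dataclass(frozen=True)
class TwoSampleResult:
    """Normal-reference comparison of band powers from two records."""

    t_stat: float
    p_two: float


def moment_match(auc: float, variance: float) -> tuple[float, float]:
    """Scale and degrees of freedom of the chi-square matching the first
    two moments of the band power: ``c = Var/(2*E)``, ``R = 2*E^2/Var``.

    The match is exact by construction: ``c*R`` reproduces the mean and
    ``2*c^2*R`` the variance.
    """
    if auc <= 0 or variance <= 0:
        raise ValueError("auc and variance must be positive")
    c = 0.5 * variance / auc
    r = 2.0 * auc * auc / variance
    return c, r


def band_power(
    spectrum: Spectrum, band: FrequencyBand, standardized: bool = True
) -> BandPower:
    """Area under the smoothed density over ``[low, high)`` and its
    asymptotic variance, with the moment-matched chi-square attached.

    Grid ordinates are included when their cyclic frequency lies in the
    half-open band.  AUC is additive over disjoint bands.
    """
    if spectrum.density is None:
        raise ValueError("density not computed; smooth the spectrum first")
    mask = (spectrum.freqs >= band.low) & (spectrum.freqs < band.high)
    if not mask.any():
        raise ValueError(
            f"band [{band.low}, {band.high}) contains no grid ordinates "
            f"at N = {spectrum.n}"
        )
    dl = spectrum.delta_lambda
    f = spectrum.density[mask]
    auc = float(np.sum(2.0 * f * dl))
    var = float(np.sum(4.0 * f**2 * dl**2))
    c, r = moment_match(auc, var)
    return BandPower(
        auc=auc, variance=var, c=c, r_df=r, band=band, standardized=standardized
    )


def band_power_ci(bp: BandPower, level: float = 0.95) -> BandPowerCI:
    """Confidence interval for the band power from its chi-square law.

    Two-sided equal-tail by default: ``[c*q_{a/2}, c*q_{1-a/2}]`` with q
    the chi-square(R) quantiles.  When the series is standardized the
    total area is exactly 1, so an upper limit beyond 1 is vacuous; in
    that case the interval switches to one-sided, ``[c*q_a, 1]``.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level
    q_lo = stats.chi2.ppf(alpha / 2.0, bp.r_df)
    q_hi = stats.chi2.ppf(1.0 - alpha / 2.0, bp.r_df)
    lower, upper = bp.c * q_lo, bp.c * q_hi
    if bp.standardized and upper > 1.0:
        lower = bp.c * stats.chi2.ppf(alpha, bp.r_df)
        return BandPowerCI(level=level, sided="one", lower=float(lower), upper=1.0)
    return BandPowerCI(level=level, sided="two", lower=float(lower), upper=float(upper))


def bandwidth_adjust(
    bp: BandPower | float, target_width: float, actual_width: float | None = None
) -> BandPower | float:
    """Rescale a band power to a reference bandwidth.

    Comparing bands of unequal width biases the wider band upward; the
    AUC is multiplied by ``target/actual`` (and the variance by its
    square), as when a 0.23-wide high-frequency band is referred to a
    0.20-wide low-frequency band.  Accepts either a :class:`BandPower`
    (returns an adjusted one) or a bare AUC value (returns the adjusted
    value; ``actual_width`` is then required).
    """
    if isinstance(bp, (int, float)):
        if actual_width is None:
            raise ValueError("actual_width required for a bare AUC value")
        if target_width <= 0 or actual_width <= 0:
            raise ValueError("widths must be positive")
        return float(bp) * target_width / actual_width
    if actual_width is None:
        if bp.band is None:
            raise ValueError("actual_width required when the band is unknown")
        actual_width = bp.band.width
    if target_width <= 0 or actual_width <= 0:
        raise ValueError("widths must be positive")
    k = target_width / actual_width
    auc = bp.auc * k
    var = bp.variance * k * k
    c, r = moment_match(auc, var)
    return BandPower(
        auc=auc, variance=var, c=c, r_df=r, band=bp.band, standardized=bp.standardized
    )


def lf_hf_ratio_test(bp_lf: BandPower, bp_hf: BandPower) -> RatioTestResult:
    """F-test of whether two band powers differ.

    Each AUC is approximately ``c_i * chi2_{R_i}``; their ratio is
    distributed as ``(c2*R2)/(c3*R3) * F_{R2,R3}``.  Under the null of
    equal band power that scale is 1, so the observed ratio is referred
    directly to ``F_{R2,R3}`` (with the non-integer degrees of freedom
    evaluated continuously).  The one-sided p is the upper tail at the
    observed ratio; the two-sided p doubles the smaller tail.  Bands are
    assumed disjoint, hence the AUCs nearly independent; overlapping
    bands trigger a warning.
    """
    if (
        bp_lf.band is not None
        and bp_hf.band is not None
        and bp_lf.band.high > bp_hf.band.low
        and bp_hf.band.high > bp_lf.band.low
    ):
        warnings.warn(
            "bands overlap: the independence assumption of the F "
            "approximation is violated",
            stacklevel=2,
        )
    ratio = bp_lf.auc / bp_hf.auc
    scale = (bp_lf.c * bp_lf.r_df) / (bp_hf.c * bp_hf.r_df)
    p_one = float(stats.f.sf(ratio, bp_lf.r_df, bp_hf.r_df))
    p_two = min(1.0, 2.0 * min(p_one, 1.0 - p_one))
    return RatioTestResult(
        ratio=float(ratio),
        scale=float(scale),
        df1=float(bp_lf.r_df),
        df2=float(bp_hf.r_df),
        p_one=p_one,
        p_two=p_two,
    )


def two_sample_auc_test(
    auc1: float, se1: float, auc2: float, se2: float
) -> TwoSampleResult:
    """Compare band powers from two independent records:
    ``t = (AUC1 - AUC2)/sqrt(SE1^2 + SE2^2)``, two-sided p from the
    standard normal (the asymptotic reference for these SEs)."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    t = (auc1 - auc2) / math.hypot(se1, se2)
    p = float(2.0 * stats.norm.sf(abs(t)))
    return TwoSampleResult(t_stat=float(t), p_two=p)
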