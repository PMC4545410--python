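"""Approximate entropy (ApEn) — a regularity statistic for short series.

ApEn(m, r, N) measures how often patterns of length m that match within
tolerance r continue to match at length m+1.  With embedded vectors
``u_i = (Y_i, ..., Y_{i+m-1})`` and the Chebyshev (max-component)
distance,

    C_i^m(r)  = #{j : d(u_i, u_j) <= r} / (N - m + 1)   (self-match included)
    Phi^m(r)  = mean_i log C_i^m(r)
    ApEn      = Phi^m(r) - Phi^{m+1}(r)

in nats.  Small values mean a regular, predictable series (a constant
series gives exactly 0); large values mean irregularity.  Including the
self-match keeps every count positive, so the logarithms are always
finite — the classic estimator for short records.

The tolerance is conventionally a fraction of the series' sample SD,
which makes the statistic exactly invariant under affine rescaling of
the data.  Typical choices: m = 2, r between 60% and 80% of SD; ApEn is
well reproducible for N > 50 but usable below.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .series import ForensicSeries

__all__ = ["ApEnConfig", "ApEnResult", "apen", "apen_sweep"]


@dataclass(frozen=True)
class ApEnConfig:
    """Pattern length ``m`` and tolerance ``r`` (fraction of series SD
    unless ``r_absolute`` is given directly)."""

    m: int = 2
    r_fraction: float | None = 0.7
    r_absolute: float | None = None

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r_absolute is None:
            if self.r_fraction is None or self.r_fraction <= 0:
                raise ValueError("r_fraction must be positive")
        elif self.r_absolute < 0:
            raise ValueError("r_absolute must be nonnegative")


@dataclass(frozen=True)
class ApEnResult:
    value: float
    n: int
    m: int
    r_fraction: float | None
    r_absolute: float

    def __float__(self) -> float:
        return self.value


def _phi(y: np.ndarray, m: int, r: float) -> float:
    """Mean log of the within-tolerance match frequency of length-m
    windows, self-matches included."""
    n = y.size
    k = n - m + 1
    emb = np.lib.stride_tricks.sliding_window_view(y, m)  # (k, m)
    # pairwise Chebyshev distances; k <= a few hundred here, O(k^2 m) is fine
    d = np.abs(emb[:, None, :] - emb[None, :, :]).max(axis=2)
    counts = (d <= r).sum(axis=1)
    return float(np.mean(np.log(counts / k)))


def apen(
    series: ForensicSeries | Sequence[float] | np.ndarray,
    config: ApEnConfig | None = None,
    *,
    m: int | None = None,
    r_fraction: float | None = None,
) -> ApEnResult:
    """Approximate entropy of a series.

    ``config`` (or the ``m``/``r_fraction`` shortcuts) sets the pattern
    length and tolerance.  A constant series is perfectly regular: its
    relative tolerance is undefined (SD = 0), and ApEn is returned as 0
    with a warning.
    """
    if config is None:
        config = ApEnConfig(
            m=m if m is not None else 2,
            r_fraction=r_fraction if r_fraction is not None else 0.7,
        )
    y = np.asarray(
        series.values if isinstance(series, ForensicSeries) else series, dtype=float
    )
    if y.ndim != 1:
        raise ValueError("series must be one-dimensional")
    n = y.size
    if n < config.m + 2:
        raise ValueError(f"need N >= m + 2 = {config.m + 2}, got {n}")
    if config.r_absolute is not None:
        r = config.r_absolute
        r_frac = config.r_fraction
    else:
        sd = float(y.std(ddof=1))
        if np.ptp(y) == 0.0:
            import warnings

            warnings.warn(
                "constant series: all patterns match at any tolerance; "
                "ApEn defined as 0",
                stacklevel=2,
            )
            return ApEnResult(
                value=0.0, n=n, m=config.m, r_fraction=config.r_fraction, r_absolute=0.0
            )
        r = config.r_fraction * sd
        r_frac = config.r_fraction
    value = _phi(y, config.m, r) - _phi(y, config.m + 1, r)
    return ApEnResult(value=value, n=n, m=config.m, r_fraction=r_frac, r_absolute=r)


def apen_sweep(
    series: ForensicSeries | Sequence[float] | np.ndarray,
    m: int = 2,
    r_fractions: Sequence[float] = (0.6, 0.65, 0.7, 0.75, 0.8),
) -> list[ApEnResult]:
    """ApEn at several SD-relative tolerances, e.g. to find the r that
    best discriminates two groups."""
    return [apen(series, ApEnConfig(m=m, r_fraction=rf)) for rf in r_fractions]
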