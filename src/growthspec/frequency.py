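"""Growth-rate, periodicity, Nyquist and alias arithmetic.

The unit conventions used throughout:

* *cycles per observation* — the spectral frequency axis (radians per
  observation divided by 2*pi*).
* *cycles per physical unit* — cycles/observation divided by ``delta_t``.
* growth rates are physical length per unit time (cm/yr or cm/week);
  a year is exactly 52 weeks in all conversions, matching the convention
  of hair-growth arithmetic in this literature.

An annual cycle in a record sampled every ``delta_t`` cm at frequency
``f`` cycles/cm pins down the growth rate: ``f`` cycles/cm times
``g`` cm/yr must equal 1 cycle/yr, hence ``g = 1/(f * period)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "WEEKS_PER_YEAR",
    "GrowthRate",
    "AliasSet",
    "radians_to_cycles",
    "cycles_to_radians",
    "growth_rate_from_frequency",
    "periodicity_from_peak",
    "nyquist_frequency",
    "alias_frequencies",
]

WEEKS_PER_YEAR = 52.0


@dataclass(frozen=True)
class GrowthRate:
    """Annual growth rate inferred from the frequency of a known cycle.

    ``value`` is in physical units per year (e.g. cm/yr); ``source_freq``
    is the cycle frequency it came from, in cycles per physical unit.
    """

    value: float
    source_freq: float

    @property
    def per_week(self) -> float:
        return self.value / WEEKS_PER_YEAR


@dataclass(frozen=True)
class AliasSet:
    """Aliases ``base + 2*k*nyquist`` of a frequency under folding.

    ``aliases`` maps each ``k`` in ``-k_max..k_max`` (k != 0) to the alias
    frequency; ``in_band`` lists the (k, |frequency|) pairs whose alias
    magnitude lands inside the principal band [0, nyquist], i.e. the
    frequencies a peak observed there could actually be.
    """

    base_freq: float
    nyquist: float
    aliases: tuple[tuple[int, float], ...]
    in_band: tuple[tuple[int, float], ...]


def radians_to_cycles(angular_freq: float) -> float:
    """Convert an angular frequency (radians per unit) to cycles per unit."""
    return angular_freq / (2.0 * math.pi)


def cycles_to_radians(freq: float) -> float:
    """Convert cycles per unit to radians per unit."""
    return freq * 2.0 * math.pi


def growth_rate_from_frequency(
    freq_cycles_per_unit: float, period_years: float = 1.0
) -> GrowthRate:
    """Annual growth rate from the spatial frequency of a cycle of known
    period: ``1 / (freq * period)``.

    For an annual sinusoid fitted along a hair at 0.0312 cycles/cm the
    growth rate is 1/(0.0312 * 1) ~ 32 cm/yr.
    """
    if freq_cycles_per_unit <= 0:
        raise ValueError("frequency must be positive")
    if period_years <= 0:
        raise ValueError("period must be positive")
    return GrowthRate(
        value=1.0 / (freq_cycles_per_unit * period_years),
        source_freq=freq_cycles_per_unit,
    )


def periodicity_from_peak(
    peak_freq: float, delta_t: float, growth_rate_per_week: float
) -> float:
    """Period in weeks of a spectral peak.

    ``peak_freq`` is in cycles per observation, ``delta_t`` in physical
    units per observation, ``growth_rate_per_week`` in physical units per
    week; then ``period = delta_t / (peak_freq * growth_rate)`` weeks.
    Doubling ``delta_t`` doubles the period; doubling the growth rate
    halves it.
    """
    if peak_freq <= 0 or delta_t <= 0 or growth_rate_per_week <= 0:
        raise ValueError("peak_freq, delta_t and growth_rate must be positive")
    return delta_t / (peak_freq * growth_rate_per_week)


def nyquist_frequency(
    delta_t: float, growth_rate_per_week: float | None = None
) -> float | tuple[float, float]:
    """Nyquist folding frequency ``0.5/delta_t`` in cycles per physical unit.

    Spectral content above this frequency folds back (aliases) into the
    band below it.  When a growth rate (physical units per week) is given,
    also returns the folding frequency on the time axis, in cycles/week.
    """
    if delta_t <= 0:
        raise ValueError("delta_t must be positive")
    per_unit = 0.5 / delta_t
    if growth_rate_per_week is None:
        return per_unit
    return per_unit, per_unit * growth_rate_per_week


def alias_frequencies(base_freq: float, nyquist: float, k_max: int = 3) -> AliasSet:
    """All aliases ``base + 2*k*nyquist`` for ``|k| <= k_max``.

    Sampling at rate ``2*nyquist`` cannot distinguish ``base`` from any
    member of this set (nor from their negatives), so a peak observed in
    the principal band [0, nyquist] may be contamination from any alias.
    ``in_band`` reports which aliases fold into that band.
    """
    if nyquist <= 0:
        raise ValueError("nyquist must be positive")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    ks = [k for k in range(-k_max, k_max + 1) if k != 0]
    aliases = tuple((k, base_freq + 2.0 * k * nyquist) for k in ks)
    in_band = tuple(
        (k, abs(f)) for k, f in aliases if 0.0 <= abs(f) <= nyquist
    )
    return AliasSet(
        base_freq=base_freq,
        nyquist=nyquist,
        aliases=aliases,
        in_band=in_band,
    )
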