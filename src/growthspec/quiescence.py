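"""Hair-quiescence (telogen) model linking growth rate to dormancy.

Hair alternates growth with a quiescent (telogen) phase; in healthy
human scalp hair the quiescence totals Q = 13 weeks of a 52-week year
and annual growth is about G = 16 cm/yr.  Stress and disrupted
metabolism lengthen the telogen.  If growth while growing is unchanged
but quiescence is augmented to AQ weeks, the observed annual growth
falls in proportion to the remaining growing weeks:

    G' = (52 - AQ)/(52 - Q) * G        and conversely
    AQ = 52 - (G'/G) * (52 - Q)

so a measured reduction in annual growth rate converts directly into an
inferred augmented quiescence — the only way to estimate quiescence from
remains, where it cannot be observed.

``simulate_quiescent_growth`` produces the corresponding weekly growth
record: a mean + annual sinusoid of weekly increments, with a contiguous
block of quiescent weeks masked out, together with the observed
(gap-free) record an examiner of the hair would actually see.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frequency import WEEKS_PER_YEAR

__all__ = [
    "QuiescenceModel",
    "GrowthSimulation",
    "reduced_growth",
    "augmented_quiescence",
    "simulate_quiescent_growth",
    "calibrate_amplitude",
]

_W = int(WEEKS_PER_YEAR)  # 52


@dataclass(frozen=True)
class QuiescenceModel:
    """Reference vs reduced growth tied by the quiescence relation.

    ``q_weeks``/``g`` are the reference quiescence and annual growth;
    ``aq_weeks``/``g_prime`` the augmented quiescence and the reduced
    growth it implies.  ``augmentation`` is the multiplier AQ/Q.
    """

    q_weeks: float
    g: float
    aq_weeks: float
    g_prime: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.q_weeks < WEEKS_PER_YEAR):
            raise ValueError("Q must lie in [0, 52)")
        if not (0.0 <= self.aq_weeks <= WEEKS_PER_YEAR):
            raise ValueError("AQ must lie in [0, 52]")
        expect = reduced_growth(self.g, self.q_weeks, self.aq_weeks)
        if abs(self.g_prime - expect) > 1e-9 * max(1.0, abs(self.g)):
            raise ValueError("G' inconsistent with (G, Q, AQ)")

    @property
    def augmentation(self) -> float:
        return self.aq_weeks / self.q_weeks if self.q_weeks else float("inf")

    @classmethod
    def from_growth_rates(
        cls, g: float, g_prime: float, q_weeks: float = 13.0
    ) -> "QuiescenceModel":
        aq = augmented_quiescence(g, g_prime, q_weeks)
        return cls(q_weeks=q_weeks, g=g, aq_weeks=aq, g_prime=g_prime)

    def summary(self) -> str:
        return (
            f"Quiescence model: G = {self.g:g}/yr, Q = {self.q_weeks:g} wk  ->  "
            f"G' = {self.g_prime:g}/yr, AQ = {self.aq_weeks:g} wk "
            f"(augmentation x{self.augmentation:.2f})"
        )


@dataclass(frozen=True)
class GrowthSimulation:
    """Weekly growth record with quiescent weeks masked.

    ``weekly_increments`` holds all 52 nominal increments (length/week);
    ``quiescent_mask`` marks the weeks in which the hair did not grow.
    ``observed_increments`` is the gap-free record over the growing
    weeks — what measurement along the recovered hair yields.
    """

    weekly_increments: np.ndarray
    quiescent_mask: np.ndarray

    @property
    def observed_increments(self) -> np.ndarray:
        return self.weekly_increments[~self.quiescent_mask]

    @property
    def observed_weeks(self) -> int:
        return int((~self.quiescent_mask).sum())

    @property
    def observed_length(self) -> float:
        return float(self.observed_increments.sum())

    @property
    def nominal_length(self) -> float:
        return float(self.weekly_increments.sum())

    @property
    def observed_cumulative(self) -> np.ndarray:
        """Cumulative observed length; the observed increments are its
        first differences (derivative/integral consistency)."""
        return np.cumsum(self.observed_increments)


def reduced_growth(g: float, q_weeks: float, aq_weeks: float) -> float:
    """Annual growth under augmented quiescence:
    ``G' = (52 - AQ)/(52 - Q) * G``."""
    if g <= 0:
        raise ValueError("G must be positive")
    if not (0.0 <= q_weeks < WEEKS_PER_YEAR):
        raise ValueError("Q must lie in [0, 52) (Q = 52 leaves no growing weeks)")
    if not (0.0 <= aq_weeks <= WEEKS_PER_YEAR):
        raise ValueError("AQ must lie in [0, 52]")
    return (WEEKS_PER_YEAR - aq_weeks) / (WEEKS_PER_YEAR - q_weeks) * g


def augmented_quiescence(g: float, g_prime: float, q_weeks: float) -> float:
    """Quiescence implied by a reduced growth rate:
    ``AQ = 52 - (G'/G)*(52 - Q)`` — the algebraic inverse of
    :func:`reduced_growth`."""
    if g <= 0 or g_prime <= 0:
        raise ValueError("growth rates must be positive")
    if not (0.0 <= q_weeks < WEEKS_PER_YEAR):
        raise ValueError("Q must lie in [0, 52)")
    aq = WEEKS_PER_YEAR - (g_prime / g) * (WEEKS_PER_YEAR - q_weeks)
    if aq < -1e-12:
        raise ValueError(
            f"G' = {g_prime} exceeds the quiescence-free maximum "
            f"{g * WEEKS_PER_YEAR / (WEEKS_PER_YEAR - q_weeks):g}"
        )
    return max(aq, 0.0)


def simulate_quiescent_growth(
    nominal_rate: float,
    q_weeks: int,
    amplitude_fraction: float = 0.0,
    trough_centered: bool = True,
) -> GrowthSimulation:
    """Weekly increments ``mean * (1 + a*cos)`` over 52 weeks with
    ``q_weeks`` consecutive weeks masked quiescent.

    ``nominal_rate`` is the annual growth were there no quiescence
    (mean weekly increment ``nominal_rate/52``); ``amplitude_fraction``
    is the annual sinusoid's amplitude as a fraction of that mean
    (must be <= 1: increments cannot go negative).  With
    ``trough_centered`` the quiescent block sits at the sinusoid trough
    (dormancy in the slow-growth season), which is what lets a 20 cm/yr
    hair with 13 quiescent weeks still show ~16 cm observed; the
    alternative places the block at the start of the year.
    """
    if nominal_rate <= 0:
        raise ValueError("nominal_rate must be positive")
    if not (0 <= q_weeks < _W):
        raise ValueError("q_weeks must lie in [0, 52)")
    if not (0.0 <= amplitude_fraction <= 1.0):
        raise ValueError(
            "amplitude_fraction must lie in [0, 1]: larger values imply "
            "negative weekly increments"
        )
    mean = nominal_rate / WEEKS_PER_YEAR
    weeks = np.arange(_W)
    # peak at week 0, trough at week 26
    inc = mean * (1.0 + amplitude_fraction * np.cos(2.0 * np.pi * weeks / _W))
    mask = np.zeros(_W, dtype=bool)
    if q_weeks:
        start = (_W // 2 - q_weeks // 2) if trough_centered else 0
        mask[start : start + q_weeks] = True
    return GrowthSimulation(weekly_increments=inc, quiescent_mask=mask)


def calibrate_amplitude(
    nominal_rate: float,
    q_weeks: int,
    target_observed_length: float,
    trough_centered: bool = True,
    tol: float = 1e-10,
) -> float:
    """Amplitude fraction whose trough-masked simulation shows a target
    observed annual length, found by bisection on [0, 1].

    With a flat profile the observed length is
    ``nominal * (52 - Q)/52``; masking the trough removes
    below-average weeks, so the observed length increases with the
    amplitude.  Raises if the target is outside the attainable range.
    """
    lo, hi = 0.0, 1.0

    def observed(a: float) -> float:
        return simulate_quiescent_growth(
            nominal_rate, q_weeks, a, trough_centered
        ).observed_length

    f_lo, f_hi = observed(lo), observed(hi)
    if not (min(f_lo, f_hi) - tol <= target_observed_length <= max(f_lo, f_hi) + tol):
        raise ValueError(
            f"target {target_observed_length:g} outside attainable range "
            f"[{min(f_lo, f_hi):g}, {max(f_lo, f_hi):g}]"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if (observed(mid) - target_observed_length) * (f_lo - target_observed_length) > 0:
            lo, f_lo = mid, observed(mid)
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)
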