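"""Synthetic growth-increment series with known ground truth.

No deposited accessions exist for the kinds of records this package
analyzes (mammoth-hair isotope profiles, hair-scale repeat intervals),
so every stage is exercised on generated data whose true structure is
recorded alongside:

* ``mammoth_like`` — linear trend + annual sinusoid + Gaussian noise,
  defaulting to the published hydrogen-isotope fit along a mammoth hair
  (dD = -158 - 0.727*cm + 8.69*sin(-0.196*cm + 3.98), sampled every
  0.3 cm);
* ``ar1`` — stationary AR(1) noise with closed-form spectral density
  ``sigma^2 / (2*pi*(1 - 2*phi*cos(lambda) + phi^2))``;
* ``two_tone`` — two sinusoids at set cyclic frequencies plus noise
  (band-power ground truth: a sinusoid of amplitude A carries power
  A^2/2);
* ``regularity_pair`` — a sampled sine and white noise of matched
  length/variance for regularity (ApEn) ordering tests;
* ``masked_growth`` — the quiescent-hair weekly record.

Each generator returns ``(series, truth)`` where ``truth`` is a JSON-able
dict of the generating parameters (slope, omega, band powers, quiescence
mask, ...).  The seed fully determines the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .quiescence import simulate_quiescent_growth
from .series import ForensicSeries

__all__ = ["FixtureSpec", "generate", "KINDS"]

KINDS = ("mammoth_like", "ar1", "two_tone", "regularity_pair", "masked_growth")

# published trend+sinusoid fit to the mammoth-hair isotope record
MAMMOTH_PARAMS = {
    "intercept": -158.0,
    "slope": -0.727,
    "amplitude": 8.69,
    "angular_freq": -0.196,  # printed with a negative sign; magnitude is the frequency
    "phase": 3.98,
    "noise_sd": 2.0,
}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic series: kind, length, step, parameters,
    seed.  The same spec always yields bit-identical output."""

    kind: str
    n: int = 100
    delta_t: float = 1.0
    params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}; choose from {KINDS}")
        if self.n < 8:
            raise ValueError("n must be >= 8")
        if self.delta_t <= 0:
            raise ValueError("delta_t must be positive")


def _mammoth_like(spec: FixtureSpec, rng: np.random.Generator):
    p = {**MAMMOTH_PARAMS, **spec.params}
    x = np.arange(1, spec.n + 1) * spec.delta_t
    clean = (
        p["intercept"]
        + p["slope"] * x
        + p["amplitude"] * np.sin(p["angular_freq"] * x + p["phase"])
    )
    y = clean + rng.normal(0.0, p["noise_sd"], spec.n)
    truth = dict(p)
    truth["freq_cycles_per_unit"] = abs(p["angular_freq"]) / (2.0 * math.pi)
    return y, "per-mil dD", truth


def _ar1(spec: FixtureSpec, rng: np.random.Generator):
    phi = float(spec.params.get("phi", 0.6))
    sigma = float(spec.params.get("sigma", 1.0))
    if not (-1.0 < phi < 1.0):
        raise ValueError("AR(1) needs |phi| < 1 for stationarity")
    burn = 200
    e = rng.normal(0.0, sigma, spec.n + burn)
    y = np.empty(spec.n + burn)
    # start from the stationary marginal so no transient remains
    y[0] = rng.normal(0.0, sigma / math.sqrt(1.0 - phi * phi))
    for t in range(1, y.size):
        y[t] = phi * y[t - 1] + e[t]
    truth = {
        "phi": phi,
        "sigma": sigma,
        "spectral_density": "sigma^2/(2*pi*(1 - 2*phi*cos(lambda) + phi^2))",
    }
    return y[burn:], "", truth


def _two_tone(spec: FixtureSpec, rng: np.random.Generator):
    f1 = float(spec.params.get("freq1", 0.15))  # cycles/observation
    f2 = float(spec.params.get("freq2", 0.42))
    a1 = float(spec.params.get("amp1", 2.0))
    a2 = float(spec.params.get("amp2", 1.0))
    noise_sd = float(spec.params.get("noise_sd", 0.1))
    t = np.arange(1, spec.n + 1)
    y = (
        a1 * np.sin(2.0 * np.pi * f1 * t + 0.3)
        + a2 * np.sin(2.0 * np.pi * f2 * t + 1.1)
        + rng.normal(0.0, noise_sd, spec.n)
    )
    truth = {
        "freq1": f1,
        "freq2": f2,
        "amp1": a1,
        "amp2": a2,
        "noise_sd": noise_sd,
        # a sinusoid of amplitude A contributes power A^2/2
        "power1": a1 * a1 / 2.0,
        "power2": a2 * a2 / 2.0,
        "power_ratio": (a1 * a1) / (a2 * a2),
    }
    return y, "", truth


def _regularity_pair(spec: FixtureSpec, rng: np.random.Generator):
    freq = float(spec.params.get("freq", 0.05))
    t = np.arange(1, spec.n + 1)
    sine = np.sqrt(2.0) * np.sin(2.0 * np.pi * freq * t)  # unit variance
    noise = rng.normal(0.0, 1.0, spec.n)
    truth = {"freq": freq, "regular": "sine", "irregular": "noise"}
    return np.concatenate([sine, noise]), "", truth  # split by caller via truth


def _masked_growth(spec: FixtureSpec, rng: np.random.Generator):
    rate = float(spec.params.get("nominal_rate", 20.0))
    q = int(spec.params.get("q_weeks", 13))
    amp = float(spec.params.get("amplitude_fraction", 0.25))
    sim = simulate_quiescent_growth(rate, q, amp, trough_centered=True)
    truth = {
        "nominal_rate": rate,
        "q_weeks": q,
        "amplitude_fraction": amp,
        "observed_length": sim.observed_length,
        "quiescent_mask": sim.quiescent_mask.tolist(),
    }
    return sim.observed_increments, "cm/week", truth


_GENERATORS = {
    "mammoth_like": _mammoth_like,
    "ar1": _ar1,
    "two_tone": _two_tone,
    "regularity_pair": _regularity_pair,
    "masked_growth": _masked_growth,
}


def generate(spec: FixtureSpec) -> tuple[ForensicSeries, dict[str, Any]]:
    """Build the series for a :class:`FixtureSpec` plus its ground-truth
    sidecar (all generating parameters, JSON-serializable)."""
    rng = np.random.default_rng(spec.seed)
    values, units, truth = _GENERATORS[spec.kind](spec, rng)
    truth.update({"kind": spec.kind, "n": spec.n, "delta_t": spec.delta_t,
                  "seed": spec.seed})
    series = ForensicSeries(
        np.asarray(values, dtype=float),
        delta_t=spec.delta_t,
        label=f"{spec.kind}-seed{spec.seed}",
        units=units,
    )
    return series, truth


def regularity_pair(
    n: int = 200, freq: float = 0.05, seed: int = 0
) -> tuple[ForensicSeries, ForensicSeries]:
    """Convenience: the (regular sine, irregular noise) pair as two
    separate series of length ``n`` with matched variance."""
    spec = FixtureSpec(kind="regularity_pair", n=n, params={"freq": freq}, seed=seed)
    series, _ = generate(spec)
    vals = series.values
    sine = ForensicSeries(vals[:n], delta_t=1.0, label=f"sine-{seed}")
    noise = ForensicSeries(vals[n:], delta_t=1.0, label=f"noise-{seed}")
    return sine, noise
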