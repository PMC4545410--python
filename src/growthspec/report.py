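"""End-to-end pipeline: preprocess -> spectrum -> band power -> periodicity
-> regularity, emitting a single machine-readable report.

``run_pipeline`` strings the library stages together exactly as one
would call them by hand; the report is a plain nested dict (JSON-ready)
in which every number is traceable to one library operation.  Floats are
rounded to 6 significant digits on serialization unless full precision
is requested.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any

from . import __version__
from .bandpower import FrequencyBand, band_power, band_power_ci, lf_hf_ratio_test
from .entropy import ApEnConfig, apen
from .frequency import alias_frequencies, nyquist_frequency, periodicity_from_peak
from .harmonic import HarmonicTrendModel
from .series import ForensicSeries, load_series, preprocess, standardize
from .spectrum import find_peaks, periodogram, smooth_density, total_power

__all__ = ["PipelineConfig", "run_pipeline", "report_to_json"]

REPORT_SCHEMA = 1


class StageError(RuntimeError):
    """Wraps a failure with the name of the pipeline stage it arose in."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything the pipeline needs besides the series itself.

    ``growth_rate_per_week`` (physical units/week) converts spectral
    peaks to periodicities; when absent and ``fit_sinusoid`` is set, the
    annual-sinusoid fit supplies it.  ``lf_band``/``hf_band`` are in
    cycles per observation.
    """

    delta_t: float = 1.0
    units: str = ""
    window: str = "daniell"
    half_width: int | None = None
    lf_band: tuple[float, float] = (0.07, 0.27)
    hf_band: tuple[float, float] = (0.27, 0.5)
    ci_level: float = 0.95
    fit_sinusoid: bool = True
    growth_rate_per_week: float | None = None
    annual_period_years: float = 1.0
    apen_m: int = 2
    apen_r_fraction: float = 0.7
    alias_k_max: int = 3


def _round_floats(obj: Any, sig: int) -> Any:
    if isinstance(obj, float):
        if obj == 0 or not math.isfinite(obj):
            return obj
        return round(obj, sig - 1 - int(math.floor(math.log10(abs(obj)))))
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    return obj


def run_pipeline(
    series: ForensicSeries | str | Path, config: PipelineConfig | None = None
) -> dict[str, Any]:
    """Run every stage on one record and collect the results.

    Deterministic: the same series and config always produce the same
    report.  Any stage failure is re-raised as :class:`StageError`
    naming the stage.
    """
    cfg = config or PipelineConfig()
    report: dict[str, Any] = {
        "schema": REPORT_SCHEMA,
        "tool": {"name": "growthspec", "version": __version__},
        "config": asdict(cfg),
    }

    if not isinstance(series, ForensicSeries):
        try:
            series = load_series(series, delta_t=cfg.delta_t, units=cfg.units)
        except Exception as e:  # noqa: BLE001 — stage attribution
            raise StageError("series_preprocess", e) from e
    report["input"] = {
        "label": series.label,
        "n": series.n,
        "delta_t": series.delta_t,
        "units": series.units,
    }

    # --- trend + annual sinusoid, growth rate -----------------------------
    growth_per_week = cfg.growth_rate_per_week
    try:
        if cfg.fit_sinusoid and series.n >= 8:
            model = HarmonicTrendModel(series)
            fit = model.fit()
            growth = fit.growth_rate(cfg.annual_period_years)
            report["sinusoid_fit"] = {
                "intercept": fit.intercept,
                "slope": fit.slope,
                "amplitude": fit.amplitude,
                "angular_freq": fit.angular_freq,
                "freq_cycles_per_unit": fit.freq_cycles,
                "phase": fit.phase,
                "rss": fit.rss,
            }
            report["growth_rate"] = {
                "per_year": growth.value,
                "per_week": growth.per_week,
            }
            if growth_per_week is None:
                growth_per_week = growth.per_week
            resid = model.residuals(fit)
            std = standardize(
                resid, delta_t=series.delta_t, label=series.label, units=series.units
            )
        else:
            std = preprocess(series)
            report["sinusoid_fit"] = None
    except StageError:
        raise
    except Exception as e:
        raise StageError("growth_frequency", e) from e
    report["preprocessing"] = std.provenance()

    # --- spectrum ---------------------------------------------------------
    try:
        spec = periodogram(std)
        spec = smooth_density(spec, window=cfg.window, half_width=cfg.half_width)
    except Exception as e:
        raise StageError("spectral_estimation", e) from e
    report["spectrum"] = {
        "n": spec.n,
        "grid_size": int(spec.freqs.size),
        "window": spec.window_name,
        "half_width": spec.half_width,
        "edf": spec.edf,
        "total_power": total_power(spec),
    }
    peaks = find_peaks(spec)
    report["peaks"] = [{"freq_cycles_per_obs": f, "density": d} for f, d in peaks]

    # --- band power & LF/HF ----------------------------------------------
    try:
        bp_lf = band_power(spec, FrequencyBand(*cfg.lf_band))
        bp_hf = band_power(spec, FrequencyBand(*cfg.hf_band))
        ratio = lf_hf_ratio_test(bp_lf, bp_hf)
        bands = {}
        for name, bp in (("lf", bp_lf), ("hf", bp_hf)):
            ci = band_power_ci(bp, level=cfg.ci_level)
            bands[name] = {
                "band": [bp.band.low, bp.band.high],
                "auc": bp.auc,
                "se": bp.se,
                "c": bp.c,
                "R": bp.r_df,
                "ci": {
                    "level": ci.level,
                    "sided": ci.sided,
                    "lower": ci.lower,
                    "upper": ci.upper,
                },
            }
        report["band_power"] = bands
        report["lf_hf"] = {
            "ratio": ratio.ratio,
            "df1": ratio.df1,
            "df2": ratio.df2,
            "p_one": ratio.p_one,
            "p_two": ratio.p_two,
        }
    except Exception as e:
        raise StageError("band_power_inference", e) from e

    # --- periodicities & aliases -----------------------------------------
    if growth_per_week is not None and growth_per_week > 0:
        try:
            nyq_unit, nyq_week = nyquist_frequency(series.delta_t, growth_per_week)
            periodicities = [
                {
                    "peak_freq_cycles_per_obs": f,
                    "period_weeks": periodicity_from_peak(
                        f, series.delta_t, growth_per_week
                    ),
                }
                for f, _ in peaks
            ]
            daily = alias_frequencies(7.0, nyq_week, k_max=cfg.alias_k_max)
            report["periodicity"] = {
                "growth_rate_per_week": growth_per_week,
                "nyquist_cycles_per_unit": nyq_unit,
                "nyquist_cycles_per_week": nyq_week,
                "peaks": periodicities,
                "daily_cycle_aliases_in_band": [
                    {"k": k, "freq_cycles_per_week": f} for k, f in daily.in_band
                ],
            }
        except Exception as e:
            raise StageError("growth_frequency", e) from e
    else:
        report["periodicity"] = None

    # --- regularity -------------------------------------------------------
    try:
        res = apen(series, ApEnConfig(m=cfg.apen_m, r_fraction=cfg.apen_r_fraction))
        report["apen"] = {
            "value": res.value,
            "n": res.n,
            "m": res.m,
            "r_fraction": res.r_fraction,
            "r_absolute": res.r_absolute,
        }
    except Exception as e:
        raise StageError("approximate_entropy", e) from e

    return report


def report_to_json(report: dict[str, Any], full_precision: bool = False) -> str:
    out = report if full_precision else _round_floats(report, 6)
    return json.dumps(out, indent=2, sort_keys=False)
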