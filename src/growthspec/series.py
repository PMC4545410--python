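"""Containers and preprocessing for growth-increment time series.

A *forensic series* is a single column of measurements taken at equal
physical steps along a growth axis — hydrogen-isotope ratios per 0.3 cm of
hair, hair-scale repeat intervals, enamel growth-line spacings.  Spectral
analysis downstream assumes a zero-mean, unit-variance, approximately
stationary series, so the preprocessing here is: fit and remove a linear
trend, divide by the sample standard deviation, and (when gaps split the
record) concatenate segments end to end.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ForensicSeries",
    "StandardizedSeries",
    "SegmentedSeries",
    "detrend",
    "standardize",
    "concatenate",
    "preprocess",
    "load_series",
    "save_series",
]

logger = logging.getLogger(__name__)


class DegenerateSeriesError(ValueError):
    """Raised when a series cannot support the requested operation
    (too short, constant, or otherwise non-analyzable)."""


@dataclass(frozen=True)
class ForensicSeries:
    """Equally spaced measurements along a growth axis.

    Parameters
    ----------
    values : array-like
        One measurement per observation, in measurement units
        (per-mil isotope ratio, micrometres, ...).
    delta_t : float
        Physical step per observation (e.g. cm per observation).
        Strictly positive.  For intrinsically discrete records
        (growth lines counted one by one) use ``delta_t = 1``.
    label, units : str
        Free-text provenance.
    """

    values: np.ndarray
    delta_t: float = 1.0
    label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if vals.size < 2:
            raise DegenerateSeriesError("a series needs at least 2 observations")
        if not np.all(np.isfinite(vals)):
            raise ValueError("values must all be finite (encode gaps as segments)")
        if not (self.delta_t > 0):
            raise ValueError(f"delta_t must be > 0, got {self.delta_t}")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def t_index(self) -> np.ndarray:
        """1-based observation index."""
        return np.arange(1, self.values.size + 1)

    @property
    def positions(self) -> np.ndarray:
        """Physical coordinate of each observation, ``t_index * delta_t``."""
        return self.t_index * self.delta_t


@dataclass(frozen=True)
class StandardizedSeries:
    """Detrended, unit-variance series plus the coefficients that were removed.

    ``intercept + slope * t_index`` is the fitted line (on the 1-based
    observation index); ``scale`` is the sample SD (N-1 denominator) the
    residuals were divided by.  The original series is recoverable as
    ``intercept + slope * t + scale * values``.
    """

    values: np.ndarray
    delta_t: float
    intercept: float
    slope: float
    scale: float
    label: str = ""
    units: str = ""

    def __len__(self) -> int:
        return self.values.size

    @property
    def n(self) -> int:
        return self.values.size

    def provenance(self) -> dict:
        return {
            "detrend_intercept": self.intercept,
            "detrend_slope": self.slope,
            "scale_sd": self.scale,
            "n": self.n,
            "delta_t": self.delta_t,
            "units": self.units,
        }


@dataclass(frozen=True)
class SegmentedSeries:
    """Ordered gap-separated segments of one record, sharing step and units."""

    segments: tuple[ForensicSeries, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("need at least one segment")
        object.__setattr__(self, "segments", tuple(self.segments))
        dt0, u0 = self.segments[0].delta_t, self.segments[0].units
        for seg in self.segments[1:]:
            if seg.delta_t != dt0:
                raise ValueError("segments must share delta_t")
            if seg.units != u0:
                raise ValueError("segments must share units")


def detrend(series: ForensicSeries) -> tuple[np.ndarray, float, float]:
    """Remove the ordinary-least-squares line of the values on the
    observation index.

    Returns ``(residuals, intercept, slope)`` with the line fitted on the
    1-based index, so ``residuals + intercept + slope * t_index``
    reconstructs the input.  Residuals sum to zero by the OLS normal
    equations.
    """
    if series.n < 3:
        raise DegenerateSeriesError(
            f"detrending needs N >= 3 observations, got {series.n}"
        )
    t = series.t_index.astype(float)
    y = series.values
    # closed-form simple regression; t is never constant by construction
    tbar, ybar = t.mean(), y.mean()
    slope = float(np.dot(t - tbar, y - ybar) / np.dot(t - tbar, t - tbar))
    intercept = float(ybar - slope * tbar)
    residuals = y - (intercept + slope * t)
    return residuals, intercept, slope


def standardize(
    residuals: np.ndarray,
    *,
    delta_t: float = 1.0,
    intercept: float = 0.0,
    slope: float = 0.0,
    label: str = "",
    units: str = "",
) -> StandardizedSeries:
    """Divide a (residual) series by its sample standard deviation.

    The mean is removed first if not already ~0, so the output has mean 0
    and SD 1 (N-1 denominator).  An affine map preserves all frequency
    content.  A constant input has no frequency content to analyze and
    raises :class:`DegenerateSeriesError`.
    """
    res = np.asarray(residuals, dtype=float)
    mean = float(res.mean())
    centered = res - mean
    sd = float(centered.std(ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateSeriesError("constant series: SD = 0, nothing to analyze")
    return StandardizedSeries(
        values=centered / sd,
        delta_t=delta_t,
        intercept=intercept + mean,
        slope=slope,
        scale=sd,
        label=label,
        units=units,
    )


def preprocess(series: ForensicSeries) -> StandardizedSeries:
    """Detrend then standardize: the full pipeline from raw measurements to
    the zero-mean, unit-variance series spectral estimation expects."""
    residuals, intercept, slope = detrend(series)
    return standardize(
        residuals,
        delta_t=series.delta_t,
        intercept=intercept,
        slope=slope,
        label=series.label,
        units=series.units,
    )


def concatenate(segmented: SegmentedSeries) -> tuple[ForensicSeries, list[int]]:
    """Pool gap-separated segments by laying them end to end.

    Returns the concatenated series and the list of segment boundaries
    (cumulative lengths, excluding the final endpoint).  No taper or
    boundary correction is applied at the joins; a warning is logged when
    more than 20% of the total length lies in segments shorter than 10
    observations, since join artifacts then become appreciable.
    """
    segs = segmented.segments
    values = np.concatenate([s.values for s in segs])
    lengths = [s.n for s in segs]
    boundaries = list(np.cumsum(lengths)[:-1])
    short = sum(n for n in lengths if n < 10)
    if short > 0.2 * sum(lengths):
        logger.warning(
            "more than 20%% of the pooled series lies in segments shorter "
            "than 10 observations (%d of %d); joins may distort the spectrum",
            short,
            sum(lengths),
        )
    first = segs[0]
    label = first.label or "concatenated"
    return (
        ForensicSeries(values, delta_t=first.delta_t, label=label, units=first.units),
        boundaries,
    )


# ---------------------------------------------------------------------------
# delimited-text I/O


def load_series(
    path: str | Path,
    *,
    delta_t: float,
    units: str = "",
    column: int | str = 0,
    sep: str | None = None,
) -> ForensicSeries:
    """Read a one-column delimited text file (CSV/TSV) into a series.

    ``delta_t`` and ``units`` are declared by the caller, never inferred
    from the file.  A header row is detected automatically; ``column``
    selects by position or by name.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, header=None, dtype=str)
    if isinstance(column, str):
        header = df.iloc[0].tolist()
        if column not in header:
            raise KeyError(f"{path}: no column named {column!r}")
        col = df.iloc[1:, header.index(column)]
    else:
        col = df.iloc[:, column]
        # drop a header row if the first cell is not numeric
        first = pd.to_numeric(pd.Series([col.iloc[0]]), errors="coerce")
        if first.isna().iloc[0]:
            col = col.iloc[1:]
    if col.empty:
        raise DegenerateSeriesError(f"{path}: no data rows")
    vals = pd.to_numeric(col, errors="coerce").reset_index(drop=True)
    if vals.isna().any():
        raise ValueError(f"{path}: non-numeric entries in data column")
    return ForensicSeries(
        vals.to_numpy(dtype=float), delta_t=delta_t, label=path.stem, units=units
    )


def save_series(series: StandardizedSeries | ForensicSeries, path: str | Path) -> None:
    """Write the values as one-column CSV, plus a JSON sidecar with the
    preprocessing provenance when the series is standardized."""
    path = Path(path)
    pd.DataFrame({"value": np.asarray(series.values)}).to_csv(path, index=False)
    if isinstance(series, StandardizedSeries):
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(series.provenance(), indent=2))
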