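"""Peak detection and the 18-value per-(screening, compound) feature set.

Two counting rules are applied to the residual trace: *all* peaks (a single
strictly increasing step into the apex and a single strictly decreasing
step out of it) and *robust* peaks (at least three consecutive increasing
and three consecutive decreasing steps).  The default feature vector has
18 named entries:

    std, kurtosis, skewness,
    sum_positive, sum_negative,
    n_peaks_all_per_min, n_peaks_robust_per_min,
    first_peak_frac,
    height_1..height_5, width_1..width_5

Peak counts are normalized by the film length in minutes; the first-peak
occurrence is the apex time of the earliest robust peak as a fraction of
the film length (sentinel 1.0 when no robust peak exists); heights and
widths come from the five highest / five widest robust peaks, zero-padded.
Two alternative compositions are reachable through :class:`FeatureConfig`:
a 20-value variant adding the sums of the top-5 heights and widths, and an
18-value variant that keeps those sums but drops the two peak counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocess import ResidualSeries

log = logging.getLogger(__name__)

__all__ = ["Peak", "FeatureConfig", "detect_peaks", "top_k",
           "extract_features", "feature_names"]


@dataclass(frozen=True)
class Peak:
    """One detected residual peak."""

    apex_index: int
    height: float        # residual value at the apex
    width_min: float     # rise start -> fall end, minutes
    rise_steps: int      # consecutive strictly increasing steps into the apex
    fall_steps: int      # consecutive strictly decreasing steps out of it
    apex_time_min: float  # apex time from series start, minutes

    def __post_init__(self):
        if self.rise_steps < 1 or self.fall_steps < 1:
            raise ValueError("rise/fall runs must each cover at least one step")
        if self.width_min <= 0:
            raise ValueError("width must be positive")


@dataclass(frozen=True)
class FeatureConfig:
    min_steps_robust: int = 3
    n_top: int = 5
    # "drop_sums": 18 features without the top-5 sum aggregates (default);
    # "drop_counts": 18 features keeping the sums but not the peak counts;
    # "full": all 20.
    variant: str = "drop_sums"

    def __post_init__(self):
        if self.variant not in ("drop_sums", "drop_counts", "full"):
            raise ValueError(f"unknown feature variant {self.variant!r}")


def detect_peaks(residuals: ResidualSeries | np.ndarray, min_steps: int,
                 step_minutes: float | None = None) -> list[Peak]:
    """Find apices with >= min_steps strictly monotone steps on each side.

    A run is broken by any plateau or reversal.  The rise/fall runs stored
    on each peak are the *maximal* monotone runs around the apex, and the
    width spans them; ``min_steps`` only decides which apices qualify.
    Returns peaks in time order; a too-short series yields an empty list.
    """
    if min_steps < 1:
        raise ValueError("min_steps must be >= 1")
    if isinstance(residuals, ResidualSeries):
        values = residuals.residuals
        if step_minutes is None:
            step_minutes = residuals.step_minutes
    else:
        values = np.asarray(residuals, dtype=float)
        if step_minutes is None:
            step_minutes = 0.5  # nominal 30 s cadence
    n = len(values)
    if n < 2 * min_steps + 1:
        log.warning("series of length %d too short for min_steps=%d", n, min_steps)
        return []
    d = np.diff(values)
    # up_run[i]: length of the maximal strictly increasing run ending at i
    up_run = np.zeros(n, dtype=int)
    for i in range(1, n):
        if d[i - 1] > 0:
            up_run[i] = up_run[i - 1] + 1
    down_run = np.zeros(n, dtype=int)
    for i in range(n - 2, -1, -1):
        if d[i] < 0:
            down_run[i] = down_run[i + 1] + 1
    peaks = []
    for i in range(1, n - 1):
        if up_run[i] >= min_steps and down_run[i] >= min_steps:
            rise, fall = int(up_run[i]), int(down_run[i])
            peaks.append(Peak(
                apex_index=i,
                height=float(values[i]),
                width_min=(rise + fall) * step_minutes,
                rise_steps=rise,
                fall_steps=fall,
                apex_time_min=i * step_minutes,
            ))
    return peaks


def top_k(peaks: list[Peak], k: int, key: str = "height") -> list[Peak]:
    """The k largest peaks by height or width, descending; ties keep the
    earlier apex first."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if key not in ("height", "width"):
        raise ValueError(f"key must be 'height' or 'width', got {key!r}")
    attr = "height" if key == "height" else "width_min"
    ordered = sorted(peaks, key=lambda p: (-getattr(p, attr), p.apex_index))
    return ordered[:k]


def feature_names(config: FeatureConfig = FeatureConfig()) -> list[str]:
    """Ordered feature-column names for the configured variant."""
    moments = ["std", "kurtosis", "skewness"]
    sums = ["sum_positive", "sum_negative"]
    counts = ["n_peaks_all_per_min", "n_peaks_robust_per_min"]
    occurrence = ["first_peak_frac"]
    heights = [f"height_{i}" for i in range(1, config.n_top + 1)]
    widths = [f"width_{i}" for i in range(1, config.n_top + 1)]
    aggregates = ["sum_top_heights", "sum_top_widths"]
    if config.variant == "drop_sums":
        return moments + sums + counts + occurrence + heights + widths
    if config.variant == "drop_counts":
        return moments + sums + occurrence + heights + widths + aggregates
    return moments + sums + counts + occurrence + heights + widths + aggregates


def extract_features(residuals: ResidualSeries,
                     config: FeatureConfig = FeatureConfig()) -> dict[str, float]:
    """The named feature values for one residual series.

    All-constant input maps the moments to 0 (rather than NaN) and all peak
    features to 0, with the first-peak sentinel at 1.0.
    """
    x = residuals.residuals
    if len(x) == 0:
        raise ValueError("residual series is empty")
    out: dict[str, float] = {}
    std = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    if std > 0:
        out["std"] = std
        out["kurtosis"] = float(stats.kurtosis(x, fisher=True, bias=True))
        out["skewness"] = float(stats.skew(x, bias=True))
    else:
        out["std"] = out["kurtosis"] = out["skewness"] = 0.0
    out["sum_positive"] = float(x[x > 0].sum())
    out["sum_negative"] = float(x[x < 0].sum())

    length = residuals.film_length_min
    all_peaks = detect_peaks(residuals, min_steps=1)
    robust = detect_peaks(residuals, min_steps=config.min_steps_robust)
    out["n_peaks_all_per_min"] = len(all_peaks) / length
    out["n_peaks_robust_per_min"] = len(robust) / length
    if robust:
        out["first_peak_frac"] = min(robust[0].apex_time_min / length, 1.0)
    else:
        out["first_peak_frac"] = 1.0

    highest = top_k(robust, config.n_top, key="height") if robust else []
    widest = top_k(robust, config.n_top, key="width") if robust else []
    for i in range(config.n_top):
        out[f"height_{i + 1}"] = highest[i].height if i < len(highest) else 0.0
        out[f"width_{i + 1}"] = widest[i].width_min if i < len(widest) else 0.0
    out["sum_top_heights"] = float(sum(p.height for p in highest))
    out["sum_top_widths"] = float(sum(p.width_min for p in widest))
    return {name: out[name] for name in feature_names(config)}
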