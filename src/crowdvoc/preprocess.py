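"""Box-model detrending of per-screening compound traces.

A cinema screening room is treated as a single well-mixed compartment of
volume ``V`` flushed with ``Q`` of outside air per hour carrying a constant
inflow mixing ratio ``C_in``.  With a constant source ``E`` (here: the
audience's emission, expressed per person after the trace has been divided
by the viewer count) the mixing ratio obeys

    dC/dt = (Q/V) (C_in - C) + E/V,

whose solution is an exponential relaxation with time constant ``tau = V/Q``
toward the steady state ``C_ss = C_in + E/Q``:

    C(t) = C_ss + (C0 - C_ss) exp(-t/tau).

The constant-emission model captures the smooth rise of breath-borne
compounds during a film; subtracting it leaves the *residual time series*
whose short-lived excursions carry the scene-locked crowd response.  The
preprocessing chain is: window the trace to the screening, drop the last
five minutes (the stand-up isoprene burst), divide by the viewer count,
fit (E, C0) by least squares with C_in fixed, and subtract the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import lsq_linear

from .errors import FitError, FormatError
from .io import CompoundSeries, ScreeningRecord

log = logging.getLogger(__name__)

__all__ = [
    "RoomParams",
    "BoxModelFit",
    "ResidualSeries",
    "PreprocessConfig",
    "trim_tail",
    "trim_head",
    "normalize_per_person",
    "predict_box_model",
    "box_model_solution",
    "fit_box_model",
    "compute_residuals",
    "estimate_inflow",
    "preprocess_screening",
]


@dataclass(frozen=True)
class RoomParams:
    """Screening-room constants of the one-box mass balance."""

    volume: float = 6500.0            # m^3
    ventilation_rate: float = 1300.0  # m^3/h fresh outside air
    inflow: float = 0.0               # inflow mixing ratio C_in, series units

    def __post_init__(self):
        if self.volume <= 0 or self.ventilation_rate <= 0:
            raise ValueError("volume and ventilation_rate must be positive")
        if self.inflow < 0:
            raise ValueError("inflow mixing ratio must be non-negative")

    @property
    def residence_time_h(self) -> float:
        """Air residence time V/Q in hours (5 h for the measured rooms)."""
        return self.volume / self.ventilation_rate


@dataclass(frozen=True)
class BoxModelFit:
    """Least-squares parameters of the constant-emission box model."""

    emission_rate: float   # E, series-units * m^3/h (per person if normalized)
    initial_value: float   # C0, series units
    inflow: float          # C_in used for the fit, series units
    rms_misfit: float      # RMS of (measured - modelled), series units
    n_samples: int

    def steady_state(self, params: "RoomParams") -> float:
        """Asymptotic mixing ratio C_in + E/Q."""
        return self.inflow + self.emission_rate / params.ventilation_rate


@dataclass(frozen=True)
class ResidualSeries:
    """Detrended per-person trace plus the film length it came from."""

    timestamps: np.ndarray   # datetime64[s] uniform grid
    residuals: np.ndarray    # signed, series units per person
    film_length_min: float
    compound_id: str = ""

    def __post_init__(self):
        ts = np.asarray(self.timestamps, dtype="datetime64[s]")
        vals = np.asarray(self.residuals, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "residuals", vals)
        if ts.shape != vals.shape:
            raise ValueError("timestamps/residuals length mismatch")
        if self.film_length_min <= 0:
            raise ValueError("film_length_min must be positive")

    def __len__(self) -> int:
        return len(self.residuals)

    @property
    def step_minutes(self) -> float:
        return float(np.diff(self.timestamps[:2]).astype("timedelta64[s]")[0]
                     / np.timedelta64(1, "s")) / 60.0

    def minutes_from_start(self) -> np.ndarray:
        dt = (self.timestamps - self.timestamps[0]).astype("timedelta64[s]")
        return dt.astype(float) / 60.0


@dataclass(frozen=True)
class PreprocessConfig:
    trim_minutes: float = 5.0
    baseline_window_min: float = 10.0
    # drop this many minutes at the head before fitting (0 = fit the whole
    # trimmed window including the entry rise, which the model tracks)
    fit_start_min: float = 0.0
    allow_negative_emission: bool = False
    max_gap_steps: int = 3


# ---------------------------------------------------------------------------
# elementary transforms

def trim_tail(series: CompoundSeries, minutes: float = 5.0) -> CompoundSeries:
    """Drop all samples later than ``end - minutes`` (closed head window)."""
    if minutes < 0:
        raise ValueError("trim duration must be non-negative")
    if minutes == 0:
        return series
    cutoff = series.timestamps[-1] - np.timedelta64(int(round(minutes * 60)), "s")
    mask = series.timestamps <= cutoff
    if mask.sum() < 2:
        raise ValueError(
            f"series ({len(series)} samples) shorter than the {minutes}-min trim")
    return replace(series, timestamps=series.timestamps[mask],
                   values=series.values[mask])


def trim_head(series: CompoundSeries, minutes: float) -> CompoundSeries:
    """Drop all samples earlier than ``start + minutes``."""
    if minutes < 0:
        raise ValueError("head trim must be non-negative")
    if minutes == 0:
        return series
    cutoff = series.timestamps[0] + np.timedelta64(int(round(minutes * 60)), "s")
    mask = series.timestamps >= cutoff
    if mask.sum() < 2:
        raise ValueError("series shorter than the head trim")
    return replace(series, timestamps=series.timestamps[mask],
                   values=series.values[mask])


def normalize_per_person(series: CompoundSeries, viewer_count: int) -> CompoundSeries:
    """Divide the trace by the audience size (known from ticket sales)."""
    if viewer_count < 1:
        raise ValueError("viewer_count must be >= 1; exclude the screening upstream")
    return replace(series, values=series.values / viewer_count, per_person=True)


# ---------------------------------------------------------------------------
# box model

def box_model_solution(params: RoomParams, emission_rate: float, c0: float,
                       t_hours: np.ndarray) -> np.ndarray:
    """Closed-form solution C(t) on an array of elapsed hours."""
    tau = params.residence_time_h
    c_ss = params.inflow + emission_rate / params.ventilation_rate
    return c_ss + (c0 - c_ss) * np.exp(-np.asarray(t_hours, float) / tau)


def predict_box_model(params: RoomParams, emission_rate: float, c0: float,
                      timestamps: np.ndarray,
                      compound_id: str = "model") -> CompoundSeries:
    """Box-model trace on a uniform datetime grid, as a CompoundSeries."""
    ts = np.asarray(timestamps, dtype="datetime64[s]")
    steps = np.diff(ts).astype(float)
    if len(ts) < 2 or np.ptp(steps) > 1e-9 or steps[0] <= 0:
        raise FormatError("predict_box_model requires a uniform increasing grid")
    hours = (ts - ts[0]).astype("timedelta64[s]").astype(float) / 3600.0
    values = box_model_solution(params, emission_rate, c0, hours)
    return CompoundSeries(compound_id=compound_id, timestamps=ts, values=values)


def fit_box_model(series: CompoundSeries, params: RoomParams,
                  c_in: float | None = None,
                  allow_negative: bool = False) -> BoxModelFit:
    """Least-squares (E, C0) of the constant-emission box model.

    With ``c_in`` fixed the solution is linear in the steady-state excess
    ``a = E/Q`` and the initial value, via the basis

        C(t) - C_in = a (1 - e^{-t/tau}) + (C0 - C_in) e^{-t/tau},

    so the optimum is found exactly by linear least squares.  The excess is
    bounded below by zero for breath-borne compounds unless
    ``allow_negative`` (deposition) is set.

    ``c_in`` defaults to ``params.inflow``; pass the per-person pre-entry
    baseline when the raw trace was divided by the viewer count.
    """
    if len(series) < 10:
        raise FitError(f"need >= 10 samples to fit, got {len(series)}")
    if c_in is None:
        c_in = params.inflow
    t = series.hours_from_start()
    decay = np.exp(-t / params.residence_time_h)
    design = np.column_stack([1.0 - decay, decay])
    y = series.values - c_in
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    if not allow_negative and coef[0] < 0:
        res = lsq_linear(design, y, bounds=([0.0, -np.inf], [np.inf, np.inf]))
        if not res.success:
            raise FitError(f"bounded least squares failed: {res.message}")
        coef = res.x
    excess, c0_rel = float(coef[0]), float(coef[1])
    model = c_in + design @ coef
    rms = float(np.sqrt(np.mean((series.values - model) ** 2)))
    return BoxModelFit(
        emission_rate=excess * params.ventilation_rate,
        initial_value=c0_rel + c_in,
        inflow=float(c_in),
        rms_misfit=rms,
        n_samples=len(series),
    )


def compute_residuals(series: CompoundSeries, fit: BoxModelFit,
                      params: RoomParams,
                      film_length_min: float | None = None) -> ResidualSeries:
    """Residual trace: measured minus the fitted box-model prediction."""
    c_ss = fit.steady_state(params)
    model = c_ss + (fit.initial_value - c_ss) * np.exp(
        -series.hours_from_start() / params.residence_time_h)
    if model.shape != series.values.shape:
        raise ValueError("length mismatch between series and model")
    if film_length_min is None:
        film_length_min = (series.timestamps[-1] - series.timestamps[0]) \
            .astype("timedelta64[s]").astype(float) / 60.0
    return ResidualSeries(
        timestamps=series.timestamps,
        residuals=series.values - model,
        film_length_min=float(film_length_min),
        compound_id=series.compound_id,
    )


# ---------------------------------------------------------------------------
# pipeline convenience

def estimate_inflow(full_series: CompoundSeries, record: ScreeningRecord,
                    window_min: float = 10.0) -> float | None:
    """Median mixing ratio in the pre-entry window [start - w, start).

    Returns None when the full-span trace has no data there (the caller then
    falls back to the configured room inflow).
    """
    t1 = np.datetime64(record.start_time.to_datetime64(), "s")
    t0 = t1 - np.timedelta64(int(round(window_min * 60)), "s")
    mask = (full_series.timestamps >= t0) & (full_series.timestamps < t1)
    vals = full_series.values[mask]
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        return None
    return float(np.median(vals))


def preprocess_screening(window: CompoundSeries, record: ScreeningRecord,
                         params: RoomParams,
                         config: PreprocessConfig = PreprocessConfig(),
                         full_series: CompoundSeries | None = None,
                         ) -> tuple[ResidualSeries, BoxModelFit]:
    """Trim, normalize, fit, and detrend one screening's trace.

    ``window`` is the screening-window slice; ``full_series`` (optional) is
    the untrimmed campaign trace used to estimate the inflow baseline from
    the 10 minutes before the audience enters.
    """
    trimmed = trim_tail(window, config.trim_minutes)
    if config.fit_start_min:
        trimmed = trim_head(trimmed, config.fit_start_min)
    per_person = normalize_per_person(trimmed, record.viewer_count)
    c_in_raw = None
    if full_series is not None:
        c_in_raw = estimate_inflow(full_series, record, config.baseline_window_min)
    if c_in_raw is None:
        c_in = params.inflow / record.viewer_count if params.inflow else 0.0
        log.debug("screening %s/%s: no baseline data, using configured inflow",
                  record.screening_id, window.compound_id)
    else:
        c_in = c_in_raw / record.viewer_count
    fit = fit_box_model(per_person, params, c_in=c_in,
                        allow_negative=config.allow_negative_emission)
    residuals = compute_residuals(per_person, fit, params,
                                  film_length_min=record.length_minutes)
    return residuals, fit
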