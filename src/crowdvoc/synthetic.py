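"""Synthetic cinema studies with the structure the analysis assumes.

The generator is the forward model of the preprocessing stage: a
well-mixed screening room (6500 m^3, 1300 m^3/h fresh air while occupied)
whose audience emits each compound at a constant per-person baseline rate,
plus short boxcar emission bursts locked to film-specific scene times.
Film identity is a fixed event schedule shared by every screening of that
film; class identity is the schedule's rate/amplitude statistics.  An
optional end-of-film burst mimics the stand-up isoprene spike, under-12
viewers emit a configurable fraction of the adult rate, and independent
Gaussian noise is added per sample.

Screenings are laid on one continuous 30-s grid; between screenings the
room is flushed at a stronger "purge" ventilation rate (cleaning practice)
so each screening starts from a settled baseline despite the occupied
room's 5-h residence time.  Concentrations are advanced by the exact
exponential relaxation of the one-box mass balance over each sampling
step, with the emission and ventilation piecewise constant.

Everything is a deterministic function of the study seed, and
:func:`generate_study_files` writes the exact tab-separated dialect that
:mod:`crowdvoc.io` reads back.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (DEFAULT_DIALECT, CompoundSeries, ScreeningRecord, StudyTable,
                 TableDialect, build_study, write_compound_table,
                 write_screenings)
from .preprocess import RoomParams

__all__ = [
    "ClassProfile", "CompoundSpec", "StudySpec", "FilmSchedule",
    "draw_film_schedule", "simulate_screening", "generate_study",
    "generate_study_files", "default_spec", "make_separable_spec",
    "make_null_spec",
]


@dataclass(frozen=True)
class ClassProfile:
    """Population and emission statistics of one age class."""

    age_class: int
    n_films: int
    screenings_per_film: tuple[int, int]        # inclusive uniform range
    film_length_min: tuple[float, float] = (85.0, 115.0)
    viewer_count: tuple[int, int] = (40, 160)   # inclusive uniform range
    event_rate_per_h: float = 8.0               # scene-locked bursts per hour
    event_amplitude: float = 300.0              # mean burst rate, ppb m^3/h per person
    event_amplitude_sigma: float = 0.4          # lognormal shape (log-space sd)
    event_duration_min: tuple[float, float] = (1.5, 3.0)
    baseline_emission: float = 25.0             # ppb m^3/h per person
    under12_fraction: float = 0.0
    screening_counts: tuple[int, ...] | None = None  # exact per-film counts

    def __post_init__(self):
        if self.n_films < 1 or self.screenings_per_film[0] < 1:
            raise ValueError("need at least one film and one screening per film")
        if self.screening_counts is not None \
                and len(self.screening_counts) != self.n_films:
            raise ValueError("screening_counts must list one count per film")
        if min(self.event_rate_per_h, self.event_amplitude,
               self.baseline_emission) < 0:
            raise ValueError("rates and amplitudes must be non-negative")
        if not 0 <= self.under12_fraction <= 1:
            raise ValueError("under12_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class CompoundSpec:
    """Per-compound scaling of the shared emission pattern."""

    compound_id: str
    unit: str = "ppb"
    scale: float = 1.0          # multiplies baseline + event emissions
    inflow: float = 0.0         # outside-air mixing ratio, same unit
    noise_sigma: float = 0.05   # additive Gaussian noise per sample
    exit_spike: bool = False    # participates in the end-of-film burst


@dataclass(frozen=True)
class StudySpec:
    """Full description of a synthetic measurement campaign."""

    profiles: tuple[ClassProfile, ...]
    compounds: tuple[CompoundSpec, ...]
    room: RoomParams = RoomParams()
    cadence_s: float = 30.0
    exit_spike: bool = True
    seed: int = 0
    start: str = "2013-12-01 10:00:00"
    child_emission_factor: float = 0.5   # under-12 emission relative to adults
    entry_ramp_min: float = 5.0          # audience filing in after film start
    exit_min: float = 2.0                # audience leaving after film end
    baseline_lead_min: float = 15.0      # settled pre-entry window per screening
    gap_min: float = 75.0                # purge gap between screenings
    purge_air_exchanges_per_h: float = 8.0
    exit_spike_factor: float = 12.0      # spike emission as multiple of baseline
    exit_spike_window_min: tuple[float, float] = (3.0, 1.0)  # before film end

    def __post_init__(self):
        if len({p.age_class for p in self.profiles}) < 2:
            raise ValueError("need at least two classes for classification")
        if self.cadence_s <= 0:
            raise ValueError("cadence must be positive")


@dataclass(frozen=True)
class FilmSchedule:
    """A film's fixed scene-locked event schedule (shared across screenings)."""

    film_title: str
    age_class: int
    length_min: float
    event_times_min: np.ndarray
    event_amps: np.ndarray       # ppb m^3/h per person, reference compound
    event_durs_min: np.ndarray


def draw_film_schedule(profile: ClassProfile, title: str, length_min: float,
                       rng: np.random.Generator, spec: StudySpec) -> FilmSchedule:
    """Draw a film's event schedule once; events stay clear of the entry
    ramp and of the trimmed final five minutes."""
    lo = spec.entry_ramp_min + 2.0
    hi = length_min - 8.0
    n = rng.poisson(profile.event_rate_per_h * length_min / 60.0)
    if hi <= lo:
        n = 0
    times = np.sort(rng.uniform(lo, hi, size=n))
    s = profile.event_amplitude_sigma
    mean = max(profile.event_amplitude, 1e-12)
    amps = np.exp(rng.normal(np.log(mean) - s * s / 2.0, s, size=n))
    if profile.event_amplitude == 0:
        amps = np.zeros(n)
    durs = rng.uniform(*profile.event_duration_min, size=n)
    return FilmSchedule(title, profile.age_class, length_min, times, amps, durs)


@dataclass
class _Planned:
    record: ScreeningRecord
    schedule: FilmSchedule
    n_eff: float  # adult-equivalent emitters


def _render(planned: list[_Planned], spec: StudySpec,
            rng_noise: np.random.Generator) -> dict[str, CompoundSeries]:
    """Advance the one-box model over one continuous grid for all compounds."""
    step_s = spec.cadence_s
    t0 = min(p.record.start_time for p in planned) \
        - pd.Timedelta(minutes=spec.baseline_lead_min)
    t1 = max(p.record.end_time for p in planned) \
        + pd.Timedelta(minutes=spec.baseline_lead_min)
    n_samples = int((t1 - t0).total_seconds() // step_s) + 1
    grid = (np.datetime64(t0.to_datetime64(), "s")
            + (np.arange(n_samples) * int(step_s)).astype("timedelta64[s]"))
    t_min = np.arange(n_samples) * (step_s / 60.0)  # minutes from grid start

    base = np.zeros(n_samples)    # baseline + event emission, reference units
    spike = np.zeros(n_samples)   # end-of-film burst emission
    occupied = np.zeros(n_samples, dtype=bool)
    for p in planned:
        rec, sched = p.record, p.schedule
        start = (rec.start_time - t0).total_seconds() / 60.0
        end = (rec.end_time - t0).total_seconds() / 60.0
        occupied |= (t_min >= start - spec.baseline_lead_min) \
            & (t_min <= end + spec.baseline_lead_min)
        # occupancy: linear entry ramp, full house, linear exit
        occ = np.clip((t_min - start) / max(spec.entry_ramp_min, 1e-9), 0, 1) \
            - np.clip((t_min - end) / max(spec.exit_min, 1e-9), 0, 1)
        occ = np.clip(occ, 0.0, 1.0) * p.n_eff
        emission = occ * _profile(spec, rec.age_class).baseline_emission
        for t_ev, amp, dur in zip(sched.event_times_min, sched.event_amps,
                                  sched.event_durs_min):
            in_burst = (t_min >= start + t_ev) & (t_min < start + t_ev + dur)
            emission = emission + in_burst * occ * amp
        base += emission
        if spec.exit_spike:
            w0, w1 = spec.exit_spike_window_min
            in_spike = (t_min >= end - w0) & (t_min < end - w1)
            spike += in_spike * occ \
                * _profile(spec, rec.age_class).baseline_emission \
                * spec.exit_spike_factor

    V, Q = spec.room.volume, spec.room.ventilation_rate
    q = np.where(occupied, Q, spec.purge_air_exchanges_per_h * V)
    dt_h = step_s / 3600.0
    alpha = np.exp(-q * dt_h / V)

    out: dict[str, CompoundSeries] = {}
    for comp in spec.compounds:
        emission = comp.scale * (base + (spike if comp.exit_spike else 0.0))
        ss = comp.inflow + emission / q
        values = np.empty(n_samples)
        c = comp.inflow
        for i in range(n_samples):
            values[i] = c
            c = ss[i] + (c - ss[i]) * alpha[i]
        sigma = comp.noise_sigma
        if sigma > 0:
            values = values + rng_noise.normal(0.0, sigma, size=n_samples)
        out[comp.compound_id] = CompoundSeries(
            compound_id=comp.compound_id, timestamps=grid, values=values,
            unit=comp.unit)
    return out


def _profile(spec: StudySpec, age_class: int) -> ClassProfile:
    for p in spec.profiles:
        if p.age_class == age_class:
            return p
    raise KeyError(age_class)


def _effective_emitters(n: int, under12: int, child_factor: float) -> float:
    return (n - under12) + child_factor * under12


def simulate_screening(profile: ClassProfile, schedule: FilmSchedule,
                       spec: StudySpec, rng: np.random.Generator,
                       viewer_count: int | None = None,
                       start: pd.Timestamp | None = None,
                       screening_id: str = "S0000",
                       ) -> tuple[ScreeningRecord, dict[str, CompoundSeries]]:
    """Render one standalone screening (its own grid, settled baseline)."""
    if viewer_count is None:
        viewer_count = int(rng.integers(profile.viewer_count[0],
                                        profile.viewer_count[1] + 1))
    if start is None:
        start = pd.Timestamp(spec.start) + pd.Timedelta(hours=10)
    under12 = int(rng.binomial(viewer_count, profile.under12_fraction))
    record = ScreeningRecord(
        screening_id=screening_id, film_title=schedule.film_title,
        age_class=profile.age_class, room_id="room1",
        start_time=start, end_time=start + pd.Timedelta(minutes=schedule.length_min),
        viewer_count=viewer_count, under12_count=under12)
    n_eff = _effective_emitters(viewer_count, under12, spec.child_emission_factor)
    traces = _render([_Planned(record, schedule, n_eff)], spec, rng)
    return record, traces


def generate_study(spec: StudySpec
                   ) -> tuple[list[ScreeningRecord], dict[str, CompoundSeries]]:
    """Generate the whole campaign: metadata plus full-span compound traces.

    Fully determined by ``spec.seed``.  Use :func:`crowdvoc.io.build_study`
    (or :func:`generate_study_files` + the readers) to window the traces
    into a :class:`~crowdvoc.io.StudyTable`.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_films, rng_sched, rng_noise = (np.random.default_rng(c)
                                       for c in ss.spawn(3))
    schedules: list[FilmSchedule] = []
    counts: list[int] = []
    for profile in spec.profiles:
        for i in range(profile.n_films):
            title = f"fsk{profile.age_class}-film{i + 1}"
            length = float(np.round(rng_films.uniform(*profile.film_length_min)))
            schedules.append(draw_film_schedule(profile, title, length,
                                                rng_films, spec))
            if profile.screening_counts is not None:
                counts.append(int(profile.screening_counts[i]))
            else:
                counts.append(int(rng_films.integers(
                    profile.screenings_per_film[0],
                    profile.screenings_per_film[1] + 1)))
    showings = [s for s, n in zip(schedules, counts) for _ in range(n)]
    order = rng_sched.permutation(len(showings))

    planned: list[_Planned] = []
    cursor = pd.Timestamp(spec.start)
    for k, idx in enumerate(order):
        sched = showings[idx]
        profile = _profile(spec, sched.age_class)
        start = cursor + pd.Timedelta(minutes=spec.gap_min + spec.baseline_lead_min)
        n = int(rng_sched.integers(profile.viewer_count[0],
                                   profile.viewer_count[1] + 1))
        under12 = int(rng_sched.binomial(n, profile.under12_fraction))
        record = ScreeningRecord(
            screening_id=f"S{k:04d}", film_title=sched.film_title,
            age_class=sched.age_class,
            room_id="room1" if k % 2 == 0 else "room2",
            start_time=start,
            end_time=start + pd.Timedelta(minutes=sched.length_min),
            viewer_count=n, under12_count=under12)
        planned.append(_Planned(
            record, sched,
            _effective_emitters(n, under12, spec.child_emission_factor)))
        cursor = record.end_time
    tables = _render(planned, spec, rng_noise)
    return [p.record for p in planned], tables


def generate_study_files(spec: StudySpec, out_dir,
                         dialect: TableDialect = DEFAULT_DIALECT
                         ) -> tuple[Path, Path]:
    """Write the study to disk in the metadata/compound-table dialect."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, tables = generate_study(spec)
    meta_path = out / "screenings.tsv"
    comp_path = out / "compounds.tsv"
    write_screenings(meta_path, records, dialect)
    write_compound_table(comp_path, tables, dialect)
    return meta_path, comp_path


def study_table(spec: StudySpec, max_gap_steps: int = 3) -> StudyTable:
    """Generate and window a study entirely in memory."""
    records, tables = generate_study(spec)
    return build_study(records, tables, max_gap_steps)


# ---------------------------------------------------------------------------
# ready-made study conditions

def default_spec(seed: int = 0) -> StudySpec:
    """A campaign-shaped study: 11 films in 4 classes, ~30-s cadence,
    CO2 + isoprene + acetone, realistic audience sizes and noise."""
    profiles = (
        ClassProfile(0, n_films=2, screenings_per_film=(18, 33),
                     event_rate_per_h=6, event_amplitude=150,
                     under12_fraction=0.35),
        ClassProfile(6, n_films=3, screenings_per_film=(10, 13),
                     event_rate_per_h=8, event_amplitude=250,
                     under12_fraction=0.25),
        ClassProfile(12, n_films=3, screenings_per_film=(2, 34),
                     event_rate_per_h=10, event_amplitude=400,
                     under12_fraction=0.05),
        ClassProfile(16, n_films=3, screenings_per_film=(1, 3),
                     event_rate_per_h=12, event_amplitude=600,
                     under12_fraction=0.0),
    )
    compounds = (
        CompoundSpec("CO2", unit="ppm", scale=700.0, inflow=400.0,
                     noise_sigma=2.0),
        CompoundSpec("m69.0699", unit="ppb", scale=1.0, inflow=0.1,
                     noise_sigma=0.05, exit_spike=True),
        CompoundSpec("m59.0491", unit="ppb", scale=1.5, inflow=0.5,
                     noise_sigma=0.1),
    )
    return StudySpec(profiles=profiles, compounds=compounds, seed=seed)


def make_separable_spec(seed: int = 0,
                        amplitudes: tuple[float, ...] = (200.0, 1000.0,
                                                         5000.0, 25000.0),
                        n_films: tuple[int, ...] = (2, 3, 2, 2),
                        screenings_per_film: int = 10) -> StudySpec:
    """Four classes whose burst amplitudes are 5x apart — the
    identifiability condition under which the pipeline should recover the
    labels with high AUC."""
    profiles = tuple(
        ClassProfile(cls, n_films=nf,
                     screenings_per_film=(screenings_per_film,
                                          screenings_per_film),
                     viewer_count=(50, 150),
                     event_rate_per_h=10, event_amplitude=amp)
        for cls, nf, amp in zip((0, 6, 12, 16), n_films, amplitudes))
    compounds = (CompoundSpec("m69.0699", noise_sigma=0.05, inflow=0.1,
                              exit_spike=True),)
    return StudySpec(profiles=profiles, compounds=compounds, seed=seed)


def make_null_spec(seed: int = 0, n_films: tuple[int, ...] = (2, 3, 2, 2),
                   screenings_per_film: int = 10) -> StudySpec:
    """Identical emission profiles in every class: labels carry no signal,
    so AUC should hover near 0.5 and permutation p-values be uniform."""
    profiles = tuple(
        ClassProfile(cls, n_films=nf,
                     screenings_per_film=(screenings_per_film,
                                          screenings_per_film),
                     viewer_count=(50, 150),
                     event_rate_per_h=10, event_amplitude=1000.0)
        for cls, nf in zip((0, 6, 12, 16), n_films))
    compounds = (CompoundSpec("m69.0699", noise_sigma=0.05, inflow=0.1,
                              exit_spike=True),)
    return StudySpec(profiles=profiles, compounds=compounds, seed=seed)
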