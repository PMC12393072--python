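"""Seeded simulator of MOS gas-sensor array streams.

Replaces the hardware (sensor chamber, pump, fan) and the fruit with a
statistical emulator that has the structure the processing chain assumes:

* each sensor reading is ``baseline + drift + temperature and humidity
  response + odor term + Gaussian noise``;
* odor concentration during a sampling phase is a linear ramp, so the
  noise-free reading slope equals a configurable per-sensor emission rate
  (a.u./s) — the quantity the pipeline estimates;
* the start of a prototype sampling phase carries an additive exponential
  warm-up transient (time constant ``warmup_tau``), the reason the device
  discards the first 70 of 100 sampling readings;
* group-level effect sizes default to the net-slope distributions observed
  in the original 13-sensor sensitivity survey
  (:data:`durinose.catalog.SURVEY_GROUP_SLOPES`).

All randomness flows from one integer seed through
:class:`numpy.random.SeedSequence`, so identical seed + configuration gives
bit-identical streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .acquisition import PhaseSchedule
from .catalog import GM_SENSORS, SURVEY_GROUP_SLOPES, SURVEY_SENSORS
from .errors import ValidationError

GROUPS = ("air_only", "durian_uninfested", "durian_infested")

#: relaxation time constant (s) of the signal back to baseline during rest
REST_TAU_S = 30.0

STREAM_COLUMNS_FRONT = ("time_s", "phase", "fruit_id", "group", "day", "replicate")


@dataclass(frozen=True)
class SensorSpec:
    """Response model of one MOS sensor channel.

    Parameters are in arbitrary units (a.u.): ``baseline`` is the clean-air
    signal, ``drift_rate`` the slow monotone drift (a.u./s), ``temp_coef``
    and ``hum_coef`` the linear environmental responses (a.u./°C, a.u./%RH),
    ``noise_sd`` the per-second Gaussian read noise, and ``warmup_tau`` (s)
    with ``warmup_amp`` (a.u.) the post-switch heating transient.
    """

    name: str
    baseline: float = 100.0
    drift_rate: float = 0.0
    temp_coef: float = 0.0
    hum_coef: float = 0.0
    odor_gain: float = 1.0
    noise_sd: float = 0.0
    warmup_tau: float = 20.0
    warmup_amp: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError(f"{self.name}: noise_sd must be >= 0")
        if self.warmup_tau <= 0:
            raise ValidationError(f"{self.name}: warmup_tau must be > 0")


def _check_unique(specs: tuple[SensorSpec, ...]) -> tuple[SensorSpec, ...]:
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValidationError("sensor names must be unique within an array")
    return specs


def default_survey_specs(noise_sd: float = 5e-4) -> tuple[SensorSpec, ...]:
    """The 13-sensor survey array with realistic mild drift and environment
    response; baselines staggered so channels are distinguishable.

    The read-noise default is small in absolute units: net odor-emission
    slopes are of order 1e-4 a.u./s, and a device that resolves them must
    have per-second noise well below the ~1e-2 a.u. signal excursion of a
    100-s sampling phase."""
    specs = []
    for i, name in enumerate(SURVEY_SENSORS):
        specs.append(SensorSpec(
            name=name,
            baseline=90.0 + 5.0 * i,
            drift_rate=2e-5,
            temp_coef=0.4 + 0.02 * i,
            hum_coef=0.10 + 0.005 * i,
            noise_sd=noise_sd,
        ))
    return _check_unique(tuple(specs))


def default_prototype_specs(noise_sd: float = 0.3,
                            warmup_amp: float = 5.0) -> tuple[SensorSpec, ...]:
    """The 4-channel GM prototype array, with a warm-up transient sized so
    the first ~70 s of sampling are visibly contaminated (tau = 20 s)."""
    specs = []
    for i, name in enumerate(GM_SENSORS):
        specs.append(SensorSpec(
            name=name,
            baseline=100.0 + 10.0 * i,
            drift_rate=1e-5,
            temp_coef=0.5 + 0.05 * i,
            hum_coef=0.12 + 0.01 * i,
            noise_sd=noise_sd,
            warmup_tau=20.0,
            warmup_amp=warmup_amp,
        ))
    return _check_unique(tuple(specs))


@dataclass(frozen=True)
class EnvProfile:
    """Per-second temperature (°C) and relative humidity (%RH) series."""

    temperature: np.ndarray
    humidity: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        h = np.asarray(self.humidity, dtype=float)
        if t.shape != h.shape or t.ndim != 1:
            raise ValidationError("temperature and humidity series must be "
                                  "1-D and the same length")
        if np.any(h < 0) or np.any(h > 100):
            raise ValidationError("humidity must lie in [0, 100] %RH")
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "humidity", h)

    def __len__(self) -> int:
        return len(self.temperature)

    @classmethod
    def constant(cls, duration_s: int, temp_c: float = 25.0,
                 rh_pct: float = 60.0) -> "EnvProfile":
        return cls(np.full(duration_s, temp_c), np.full(duration_s, rh_pct))

    @classmethod
    def diel(cls, duration_s: int, temp_mean: float = 25.0,
             temp_amp: float = 5.0, rh_mean: float = 60.0,
             rh_amp: float = 15.0, period_s: float = 86400.0,
             rh_lag_s: float = 7200.0) -> "EnvProfile":
        """Sinusoidal diel cycle; humidity roughly in anti-phase with
        temperature but lagging by ``rh_lag_s`` (about 2 h in unconditioned
        air), so T and RH covary strongly without being collinear."""
        t = np.arange(duration_s, dtype=float)
        w = 2.0 * np.pi * t / period_s
        temp = temp_mean + temp_amp * np.sin(w)
        rh = np.clip(rh_mean - rh_amp * np.sin(w - 2.0 * np.pi * rh_lag_s
                                               / period_s), 0.0, 100.0)
        return cls(temp, rh)


@dataclass(frozen=True)
class OdorSource:
    """What the chamber smells of: a group label and per-sensor target net
    emission rates (a.u./s)."""

    group: str
    per_sensor_slope: dict[str, float]
    day: int | None = None
    fruit_id: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"unknown group {self.group!r}; expected one of {GROUPS}")

    @classmethod
    def air(cls) -> "OdorSource":
        return cls(group="air_only", per_sensor_slope={})


def _base_signal(spec: SensorSpec, t_global: np.ndarray, temp: np.ndarray,
                 rh: np.ndarray, t_ref: float, h_ref: float,
                 rng: np.random.Generator) -> np.ndarray:
    sig = (spec.baseline
           + spec.drift_rate * t_global
           + spec.temp_coef * (temp - t_ref)
           + spec.hum_coef * (rh - h_ref))
    if spec.noise_sd > 0:
        sig = sig + rng.normal(0.0, spec.noise_sd, size=len(t_global))
    return sig


def _frame(time_s: np.ndarray, phase: np.ndarray, readings: dict[str, np.ndarray],
           temp: np.ndarray, rh: np.ndarray, metadata: dict) -> pd.DataFrame:
    data = {
        "time_s": time_s,
        "phase": phase,
        "fruit_id": metadata.get("fruit_id", ""),
        "group": metadata.get("group", ""),
        "day": metadata.get("day", 0),
        "replicate": metadata.get("replicate", 0),
    }
    data.update(readings)
    data["temp_c"] = temp
    data["rh_pct"] = rh
    return pd.DataFrame(data)


def simulate_control_air(specs: tuple[SensorSpec, ...], duration_h: float,
                         env_profile: EnvProfile | None = None,
                         seed: int = 0) -> pd.DataFrame:
    """Charcoal-filtered control air: no odor term, only baseline, drift,
    environmental response and noise.  This is the stream the environmental
    calibration is fitted on (24 h by default in the deployed device)."""
    if duration_h <= 0:
        raise ValidationError("duration_h must be > 0")
    _check_unique(specs)
    n = int(round(duration_h * 3600))
    if env_profile is None:
        env_profile = EnvProfile.diel(n)
    if len(env_profile) != n:
        raise ValidationError(
            f"env_profile length {len(env_profile)} does not cover "
            f"{n} s of acquisition")
    rng = np.random.default_rng(seed)
    t = np.arange(n, dtype=float)
    t_ref = float(env_profile.temperature.mean())
    h_ref = float(env_profile.humidity.mean())
    readings = {
        s.name: _base_signal(s, t, env_profile.temperature,
                             env_profile.humidity, t_ref, h_ref, rng)
        for s in specs
    }
    return _frame(t, np.full(n, "room_air"), readings,
                  env_profile.temperature, env_profile.humidity,
                  {"group": "air_only"})


def simulate_cycle(specs: tuple[SensorSpec, ...], odor_source: OdorSource,
                   schedule: PhaseSchedule | None = None,
                   env: tuple[float, float] | EnvProfile = (25.0, 60.0),
                   seed: int = 0, t_start: float = 0.0,
                   metadata: dict | None = None) -> pd.DataFrame:
    """One acquisition cycle for one odor source.

    Survey schedules produce a paired room-air / sample-air cycle; prototype
    schedules produce reset / sampling / rest.  During the odor-bearing phase
    the noise-free reading slope equals ``odor_source.per_sensor_slope`` for
    each sensor, on top of the shared baseline trend; the prototype sampling
    phase additionally carries the warm-up transient
    ``warmup_amp * exp(-t/warmup_tau)``.
    """
    schedule = schedule or PhaseSchedule.prototype()
    _check_unique(specs)
    unknown = set(odor_source.per_sensor_slope) - {s.name for s in specs}
    if unknown:
        raise ValidationError(
            f"per_sensor_slope has sensors not in the array: {sorted(unknown)}")
    n = schedule.cycle_s
    if isinstance(env, EnvProfile):
        if len(env) != n:
            raise ValidationError(
                f"env profile length {len(env)} != cycle length {n}")
        temp, rh = env.temperature, env.humidity
        t_ref, h_ref = float(temp.mean()), float(rh.mean())
    else:
        temp = np.full(n, float(env[0]))
        rh = np.full(n, float(env[1]))
        t_ref, h_ref = float(env[0]), float(env[1])

    t_global = t_start + np.arange(n, dtype=float)
    phase_labels = np.empty(n, dtype=object)
    odor_phase = "sample_air" if schedule.mode == "survey" else "sampling"
    offset = 0
    bounds = {}
    for pname, dur in schedule.phases:
        phase_labels[offset:offset + dur] = pname
        bounds[pname] = (offset, offset + dur)
        offset += dur

    rng = np.random.default_rng(seed)
    readings: dict[str, np.ndarray] = {}
    for spec in specs:
        sig = _base_signal(spec, t_global, temp, rh, t_ref, h_ref, rng)
        slope = float(odor_source.per_sensor_slope.get(spec.name, 0.0))
        lo, hi = bounds[odor_phase]
        t_phase = np.arange(hi - lo, dtype=float)
        sig[lo:hi] += slope * t_phase
        if schedule.mode == "prototype":
            if spec.warmup_amp != 0.0:
                sig[lo:hi] += spec.warmup_amp * np.exp(-t_phase / spec.warmup_tau)
            # rest phase: odor accumulated by the end of sampling decays away
            rlo, rhi = bounds["rest"]
            t_rest = np.arange(rhi - rlo, dtype=float)
            sig[rlo:rhi] += slope * (hi - lo - 1) * np.exp(-t_rest / REST_TAU_S)
        readings[spec.name] = sig

    meta = {"group": odor_source.group, "fruit_id": odor_source.fruit_id or "",
            "day": odor_source.day or 0}
    meta.update(metadata or {})
    return _frame(t_global, phase_labels, readings, temp, rh, meta)


def _quantile_z(n: int) -> np.ndarray:
    """Deterministic stratified normal scores (i + 0.5)/n; used for
    noise-free group draws that still carry the group's mean and spread."""
    return stats.norm.ppf((np.arange(n) + 0.5) / n)


@dataclass(frozen=True)
class SurveyDesign:
    """The 13-sensor sensitivity survey: n uninfested + n infested fruits,
    one paired room-air/sample-air measurement each."""

    n_uninfested: int = 5
    n_infested: int = 5
    slope_table: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(SURVEY_GROUP_SLOPES))
    draw: str = "normal"  # "normal" or "quantile" (deterministic)
    noise_sd: float = 5e-4
    temp_c: float = 25.0
    rh_pct: float = 60.0

    def __post_init__(self) -> None:
        if self.n_uninfested < 2 or self.n_infested < 2:
            raise ValidationError("need >= 2 fruits per group")
        if self.draw not in ("normal", "quantile"):
            raise ValidationError(f"unknown draw mode {self.draw!r}")


def simulate_survey_experiment(design: SurveyDesign | None = None,
                               seed: int = 0) -> pd.DataFrame:
    """Paired room-air/sample-air cycles for the sensitivity survey.

    Each fruit's per-sensor net emission rate is drawn from the group's
    Normal(mean, SD) (``draw="normal"``) or placed at deterministic normal
    quantiles of it (``draw="quantile"``, reproducible spread with zero
    sampling randomness).  Returns one concatenated stream; cycles follow
    each other in time so :func:`durinose.acquisition.segment_cycles`
    recovers one cycle per fruit.
    """
    design = design or SurveyDesign()
    sensors = list(design.slope_table)
    specs = tuple(
        replace(s, noise_sd=design.noise_sd)
        for s in default_survey_specs() if s.name in sensors
    )
    schedule = PhaseSchedule.survey()
    ss = np.random.SeedSequence(seed)
    n_total = design.n_uninfested + design.n_infested
    child_seeds = ss.spawn(n_total + 1)
    slope_rng = np.random.default_rng(child_seeds[0])

    frames = []
    t_start = 0.0
    fruit_no = 0
    for group, n in (("durian_uninfested", design.n_uninfested),
                     ("durian_infested", design.n_infested)):
        z = _quantile_z(n)
        for i in range(n):
            slopes = {}
            for sensor in sensors:
                mu_u, sd_u, mu_i, sd_i = design.slope_table[sensor]
                mu, sd = ((mu_u, sd_u) if group == "durian_uninfested"
                          else (mu_i, sd_i))
                if design.draw == "quantile":
                    slopes[sensor] = mu + sd * z[i]
                else:
                    slopes[sensor] = float(slope_rng.normal(mu, sd))
            fid = ("U" if group == "durian_uninfested" else "I") + f"{i + 1:02d}"
            source = OdorSource(group=group, per_sensor_slope=slopes,
                                fruit_id=fid)
            frames.append(simulate_cycle(
                specs, source, schedule, env=(design.temp_c, design.rh_pct),
                seed=child_seeds[fruit_no + 1].generate_state(1)[0] % (2**31),
                t_start=t_start))
            t_start += schedule.cycle_s
            fruit_no += 1
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class OutdoorDesign:
    """Outdoor detection on "Monthong" fruit: corrected, normalized GM-channel
    readings near fruit in open air.

    The training set is 5 infested + 5 uninfested fruits, 3 measurements of
    30 retained readings each, plus 3 air-only measurements; the test set is
    10 further fruits measured once.  Class-conditional channel mean shifts
    are configurable; the defaults give a clearly separated air class and
    heavily overlapping infested/uninfested classes, the regime the device
    operates in outdoors.
    """

    n_train_fruits_per_group: int = 5
    n_test_fruits_per_group: int = 5
    measurements_per_train_fruit: int = 3
    measurements_per_test_fruit: int = 1
    readings_per_measurement: int = 30
    n_air_measurements: int = 3
    durian_shift: tuple[float, ...] = (1.2, 1.0, 0.9, 0.8)
    mealybug_delta: tuple[float, ...] = (0.15, 0.30, -0.25, 0.35)
    fruit_sd: float = 0.5
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if len(self.durian_shift) != len(GM_SENSORS) or \
                len(self.mealybug_delta) != len(GM_SENSORS):
            raise ValidationError("class shifts must have one entry per GM channel")


def _reading_block(rng: np.random.Generator, center: np.ndarray, sd: float,
                   n: int) -> np.ndarray:
    return center + rng.normal(0.0, sd, size=(n, len(center)))


def simulate_outdoor_experiment(design: OutdoorDesign | None = None,
                                seed: int = 0
                                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Training and test reading tables for outdoor infestation detection.

    Rows are single retained readings in the 4 GM channels (dimensionless,
    post correction and normalization); columns ``class`` in
    {air, durian, durian_mealybug}, ``fruit_id``, ``measurement`` and the
    channels.  Defaults give 990 training rows (900 durian + 90 air) and 300
    test rows.
    """
    design = design or OutdoorDesign()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    base = {
        "air": np.zeros(len(GM_SENSORS)),
        "durian": np.asarray(design.durian_shift, dtype=float),
        "durian_mealybug": (np.asarray(design.durian_shift, dtype=float)
                            + np.asarray(design.mealybug_delta, dtype=float)),
    }

    def make_split(n_fruits: int, n_meas: int, n_air: int,
                   tag: str) -> pd.DataFrame:
        rows = []
        for cls, grp_tag in (("durian", "U"), ("durian_mealybug", "I")):
            for f in range(n_fruits):
                fruit_effect = rng.normal(0.0, design.fruit_sd,
                                          size=len(GM_SENSORS))
                center = base[cls] + fruit_effect
                for m in range(n_meas):
                    block = _reading_block(rng, center, design.noise_sd,
                                           design.readings_per_measurement)
                    for r in block:
                        rows.append({"class": cls,
                                     "fruit_id": f"{tag}{grp_tag}{f + 1:02d}",
                                     "measurement": m,
                                     **dict(zip(GM_SENSORS, r))})
        for m in range(n_air):
            block = _reading_block(rng, base["air"], design.noise_sd,
                                   design.readings_per_measurement)
            for r in block:
                rows.append({"class": "air", "fruit_id": f"{tag}AIR",
                             "measurement": m, **dict(zip(GM_SENSORS, r))})
        return pd.DataFrame(rows)

    train = make_split(design.n_train_fruits_per_group,
                       design.measurements_per_train_fruit,
                       design.n_air_measurements, "TR")
    test = make_split(design.n_test_fruits_per_group,
                      design.measurements_per_test_fruit, 0, "TE")
    return train, test


@dataclass(frozen=True)
class IndoorDesign:
    """Indoor daily ripening of "Kradum Thong" fruit: 3 mealybug-inoculated
    and 3 control fruits, 30 readings per day for 7 days.

    Each fruit's daily 4-channel mean performs a directed walk whose
    direction changes at the fruit's cracking day; inoculated fruits take
    ``infested_multiplier`` times larger daily steps (the accelerated,
    stress-driven odor shift seen in infested fruit).
    """

    n_fruits: int = 6
    n_infested: int = 3
    n_days: int = 7
    readings_per_day: int = 30
    cracking_day: int = 4
    step_size: float = 1.0
    infested_multiplier: float = 1.5
    noise_sd: float = 0.35

    def __post_init__(self) -> None:
        if not (0 <= self.n_infested <= self.n_fruits):
            raise ValidationError("n_infested must be within n_fruits")
        if not (1 <= self.cracking_day <= self.n_days):
            raise ValidationError("cracking_day must lie within the study days")


def simulate_indoor_ripening(design: IndoorDesign | None = None,
                             seed: int = 0) -> pd.DataFrame:
    """Daily GM-channel reading table for the indoor ripening experiment.

    Returns a long frame ``fruit_id, group, day, reading, <channels>`` with
    ``n_days * readings_per_day`` rows per fruit (210 by default).  Before
    the cracking day the daily mean advances along one direction in channel
    space; from the day after cracking it departs along an orthogonal
    direction, so day clouds cluster around the cracking day and separate on
    either side of it.
    """
    design = design or IndoorDesign()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    p = len(GM_SENSORS)
    rows = []
    for f in range(design.n_fruits):
        infested = f < design.n_infested
        group = "durian_infested" if infested else "durian_uninfested"
        step = design.step_size * (design.infested_multiplier if infested else 1.0)
        u = rng.normal(size=p)
        u /= np.linalg.norm(u)
        v = rng.normal(size=p)
        v -= (v @ u) * u
        v /= np.linalg.norm(v)
        mean = np.zeros(p)
        for day in range(1, design.n_days + 1):
            if day > 1:
                direction = u if day <= design.cracking_day else v
                mean = mean + step * direction
            block = _reading_block(rng, mean, design.noise_sd,
                                   design.readings_per_day)
            fid = f"KT{f + 1:02d}"
            for r_idx, r in enumerate(block):
                rows.append({"fruit_id": fid, "group": group, "day": day,
                             "reading": r_idx, **dict(zip(GM_SENSORS, r))})
    return pd.DataFrame(rows)
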