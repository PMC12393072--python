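"""Environmental compensation and normalization of prototype readings.

MOS sensor signals respond strongly to temperature and humidity.  The
deployed device fits, once, a per-sensor linear model of the clean-air
signal on T (°C) and RH (%RH) from a long control-air recording (24 h of
charcoal-filtered air), then subtracts the fitted environmental component
from every subsequent reading.  After correction, each sampling phase is
normalized against its anchor reading so channels become dimensionless
relative fluctuations comparable across cycles and devices.

The calibration is a *joint* multiple regression on T and RH rather than two
marginal fits: T and RH covary diurnally, and marginal slopes would be
confounded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .acquisition import sensor_columns
from .errors import (
    DegenerateDesignError,
    NormalizationError,
    ValidationError,
)

CALIBRATION_COLUMNS = ("sensor", "intercept", "beta_T", "beta_H",
                       "T_ref", "H_ref", "n", "resid_sd")

#: minimum control-air samples for a trustworthy calibration
MIN_CALIBRATION_N = 100


@dataclass(frozen=True)
class SensorCalibration:
    intercept: float
    beta_T: float   # a.u. per °C
    beta_H: float   # a.u. per %RH
    n: int
    resid_sd: float


@dataclass(frozen=True)
class EnvCalibration:
    """Per-sensor environmental response coefficients, with the calibration
    reference point (T_ref, H_ref) = the control-air means."""

    sensors: dict[str, SensorCalibration]
    T_ref: float
    H_ref: float

    def __post_init__(self) -> None:
        for name, cal in self.sensors.items():
            if cal.n < MIN_CALIBRATION_N:
                raise ValidationError(
                    f"{name}: calibration needs n >= {MIN_CALIBRATION_N}, "
                    f"got {cal.n}")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"sensor": s, "intercept": c.intercept, "beta_T": c.beta_T,
                 "beta_H": c.beta_H, "T_ref": self.T_ref, "H_ref": self.H_ref,
                 "n": c.n, "resid_sd": c.resid_sd}
                for s, c in self.sensors.items()]
        return pd.DataFrame(rows, columns=list(CALIBRATION_COLUMNS))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EnvCalibration":
        missing = set(CALIBRATION_COLUMNS) - set(frame.columns)
        if missing:
            raise ValidationError(f"calibration table missing {sorted(missing)}")
        sensors = {
            row["sensor"]: SensorCalibration(
                intercept=float(row["intercept"]), beta_T=float(row["beta_T"]),
                beta_H=float(row["beta_H"]), n=int(row["n"]),
                resid_sd=float(row["resid_sd"]))
            for _, row in frame.iterrows()
        }
        return cls(sensors=sensors, T_ref=float(frame["T_ref"].iloc[0]),
                   H_ref=float(frame["H_ref"].iloc[0]))

    @classmethod
    def from_csv(cls, path) -> "EnvCalibration":
        return cls.from_frame(pd.read_csv(path))


def fit_env_calibration(control_stream: pd.DataFrame) -> EnvCalibration:
    """Fit per-sensor OLS of reading on temperature and humidity.

    The stream must be control (odor-free) air with ``temp_c`` and ``rh_pct``
    columns; every other non-metadata column is treated as a sensor channel.
    Raises :class:`DegenerateDesignError` when T and RH carry no usable
    variation (constant or collinear), in which case a richer environmental
    profile must be recorded.
    """
    for col in ("temp_c", "rh_pct"):
        if col not in control_stream.columns:
            raise ValidationError(f"control stream lacks {col!r}")
    sensors = sensor_columns(control_stream)
    if not sensors:
        raise ValidationError("control stream has no sensor columns")
    temp = control_stream["temp_c"].to_numpy(dtype=float)
    rh = control_stream["rh_pct"].to_numpy(dtype=float)
    design = sm.add_constant(np.column_stack([temp, rh]), has_constant="add")
    if np.linalg.matrix_rank(design) < 3:
        raise DegenerateDesignError(
            "temperature and humidity are constant or collinear over the "
            "calibration period; record a profile with independent T/RH "
            "variation")
    cals = {}
    for name in sensors:
        fit = sm.OLS(control_stream[name].to_numpy(dtype=float), design).fit()
        resid_sd = float(np.sqrt(fit.scale))
        cals[name] = SensorCalibration(
            intercept=float(fit.params[0]), beta_T=float(fit.params[1]),
            beta_H=float(fit.params[2]), n=int(fit.nobs), resid_sd=resid_sd)
    return EnvCalibration(sensors=cals, T_ref=float(temp.mean()),
                          H_ref=float(rh.mean()))


def apply_env_correction(readings: pd.DataFrame, cal: EnvCalibration,
                         temp=None, rh=None) -> pd.DataFrame:
    """Remove the fitted environmental component from every sensor channel.

    ``corrected = raw - beta_T * (T - T_ref) - beta_H * (RH - H_ref)``; at
    the calibration reference point the correction is the identity.  T and
    RH default to the stream's own ``temp_c``/``rh_pct`` columns.
    """
    temp = readings["temp_c"].to_numpy(dtype=float) if temp is None \
        else np.asarray(temp, dtype=float)
    rh = readings["rh_pct"].to_numpy(dtype=float) if rh is None \
        else np.asarray(rh, dtype=float)
    out = readings.copy()
    for name in sensor_columns(readings):
        if name not in cal.sensors:
            raise ValidationError(f"no calibration for sensor {name!r}")
        c = cal.sensors[name]
        out[name] = (readings[name].to_numpy(dtype=float)
                     - c.beta_T * (temp - cal.T_ref)
                     - c.beta_H * (rh - cal.H_ref))
    return out


def normalize_cycle(sampling_readings, variant: str = "relative"):
    """Two-step normalization of a sampling phase against its anchor.

    Step 1 divides every reading by the anchor (first retained) reading;
    step 2 re-expresses the ratio as a fluctuation: ``ratio - 1`` for the
    default ``"relative"`` variant (0 at the anchor, +0.10 for a 10% rise)
    or ``log(ratio)`` for the ``"log"`` variant.  Output is dimensionless
    and invariant to rescaling the raw series by any positive constant.
    """
    if variant not in ("relative", "log"):
        raise ValidationError(f"unknown normalization variant {variant!r}")
    if isinstance(sampling_readings, pd.DataFrame):
        out = sampling_readings.copy()
        for name in sensor_columns(sampling_readings):
            out[name] = normalize_cycle(
                sampling_readings[name].to_numpy(dtype=float), variant)
        return out
    values = np.asarray(sampling_readings, dtype=float)
    if values.size == 0:
        raise ValidationError("empty sampling series")
    anchor = values[0]
    if anchor == 0:
        raise NormalizationError("anchor reading is zero; cannot normalize")
    ratio = values / anchor
    if variant == "log":
        if np.any(ratio <= 0):
            raise NormalizationError("log normalization needs ratios > 0")
        return np.log(ratio)
    return ratio - 1.0
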