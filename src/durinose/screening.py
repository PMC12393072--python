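"""Per-sensor two-group screening with the Brunner-Munzel test.

The sensitivity survey asks, sensor by sensor, whether net odor-emission
slopes differ between uninfested and mealybug-infested fruit.  Group sizes
are small and spreads are wildly unequal across sensors, so the comparison
uses the Brunner-Munzel rank test of the relative effect
``p = P(X < Y) + 0.5 * P(X = Y)``: a studentized midrank statistic with
Welch-Satterthwaite-type degrees of freedom, valid under unequal variances
and arbitrary distribution shapes.

No multiple-testing correction is applied across the array's sensors; the
screen reports raw per-sensor p-values (a deliberate, documented choice for
a 13-sensor exploratory screen).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateVarianceError, InsufficientDataError, ValidationError

SCREEN_COLUMNS = ("sensor", "mean_uninf", "sd_uninf", "mean_inf", "sd_inf",
                  "bm", "df", "p", "flag", "direction")


@dataclass(frozen=True)
class BMResult:
    """Brunner-Munzel comparison of two samples x (group A) and y (group B).

    ``p_hat`` estimates P(X < Y) + 0.5 P(X = Y); the statistic is negative
    when y tends to fall below x (p_hat < 0.5) and zero iff p_hat = 0.5.
    Complete separation of the two samples yields an infinite statistic with
    p_value 0 and undefined df.
    """

    statistic: float
    df: float
    p_value: float
    p_hat: float
    n_x: int
    n_y: int
    mean_x: float
    sd_x: float
    mean_y: float
    sd_y: float


def brunner_munzel(x, y) -> BMResult:
    """Two-sided Brunner-Munzel test of ``P(X < Y) + 0.5 P(X = Y) = 0.5``.

    Uses midranks for ties, the studentized statistic of the original test
    and a t reference distribution with Welch-type df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise InsufficientDataError("each group needs >= 2 observations")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValidationError("non-finite values in input")

    rank_all = stats.rankdata(np.concatenate([x, y]))
    rank_x_all, rank_y_all = rank_all[:nx], rank_all[nx:]
    rank_x_within = stats.rankdata(x)
    rank_y_within = stats.rankdata(y)
    mean_rx, mean_ry = rank_x_all.mean(), rank_y_all.mean()

    p_hat = (mean_ry - (ny + 1) / 2.0) / nx

    sx2 = np.sum((rank_x_all - rank_x_within
                  - mean_rx + rank_x_within.mean()) ** 2) / (nx - 1)
    sy2 = np.sum((rank_y_all - rank_y_within
                  - mean_ry + rank_y_within.mean()) ** 2) / (ny - 1)

    summary = dict(n_x=nx, n_y=ny,
                   mean_x=float(x.mean()), sd_x=float(x.std(ddof=1)),
                   mean_y=float(y.mean()), sd_y=float(y.std(ddof=1)))

    pooled = nx * sx2 + ny * sy2
    if pooled == 0.0:
        if p_hat == 0.5:
            raise DegenerateVarianceError(
                "all observations tied across both samples; the relative "
                "effect is exactly 0.5 with zero variance - add data with "
                "measurable variation")
        # complete separation: direction is certain, magnitude unbounded
        sign = 1.0 if p_hat > 0.5 else -1.0
        return BMResult(statistic=sign * math.inf, df=math.nan, p_value=0.0,
                        p_hat=float(p_hat), **summary)

    statistic = (nx * ny * (mean_ry - mean_rx)
                 / ((nx + ny) * math.sqrt(pooled)))
    df = pooled ** 2 / ((nx * sx2) ** 2 / (nx - 1) + (ny * sy2) ** 2 / (ny - 1))
    p_value = 2.0 * stats.t.sf(abs(statistic), df)
    return BMResult(statistic=float(statistic), df=float(df),
                    p_value=float(p_value), p_hat=float(p_hat), **summary)


def screen_sensors(feature_table: pd.DataFrame, alpha: float = 0.05,
                   value_col: str = "slope_net", sensor_col: str = "sensor",
                   group_col: str = "group",
                   groups: tuple[str, str] = ("durian_uninfested",
                                              "durian_infested")
                   ) -> pd.DataFrame:
    """One Brunner-Munzel comparison per sensor over a long feature table.

    ``groups`` orders the comparison as (x, y) = (uninfested, infested), so a
    negative statistic means infestation lowered the sensor's net slope.
    Returns one row per sensor:
    ``sensor, mean_uninf, sd_uninf, mean_inf, sd_inf, bm, df, p, flag,
    direction`` with ``flag = p < alpha`` and ``direction`` the sign of the
    infested-minus-uninfested mean difference.
    """
    if not 0 <= alpha <= 1:
        raise ValidationError("alpha must lie in [0, 1]")
    for col in (value_col, sensor_col, group_col):
        if col not in feature_table.columns:
            raise ValidationError(f"feature table lacks column {col!r}")
    present = set(feature_table[group_col].unique())
    missing = set(groups) - present
    if missing:
        raise ValidationError(f"feature table lacks groups {sorted(missing)}")

    rows = []
    for sensor, block in feature_table.groupby(sensor_col, sort=False):
        x = block.loc[block[group_col] == groups[0], value_col].to_numpy()
        y = block.loc[block[group_col] == groups[1], value_col].to_numpy()
        res = brunner_munzel(x, y)
        rows.append({
            "sensor": sensor,
            "mean_uninf": res.mean_x, "sd_uninf": res.sd_x,
            "mean_inf": res.mean_y, "sd_inf": res.sd_y,
            "bm": res.statistic, "df": res.df, "p": res.p_value,
            "flag": bool(res.p_value < alpha),
            "direction": int(np.sign(res.mean_y - res.mean_x)),
        })
    return pd.DataFrame(rows, columns=list(SCREEN_COLUMNS))


def flagged_sensors(report: pd.DataFrame) -> list[str]:
    """Sensors the screen flagged as responsive, in report order."""
    return report.loc[report["flag"], "sensor"].tolist()
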