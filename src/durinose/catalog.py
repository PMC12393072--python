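"""Reference data for the sensor arrays used by the durian e-nose.

Two arrays are modelled:

* the 13-sensor *survey* array (MQ2..MQ135 plus the four channels of the
  Grove Multichannel Gas Sensor v2) used to screen which low-cost MOS
  sensors respond to mealybug-associated volatiles, and
* the 4-channel *prototype* array (GM102B, GM302B, GM502B, GM702B) used in
  the deployed device.

``SURVEY_GROUP_SLOPES`` holds the per-sensor net odor-emission slope
distributions (mean, SD, in a.u./s) observed for uninfested and
mealybug-infested durians in the original sensitivity survey; the
simulator uses them as the default group effect sizes.

``OUTDOOR_REFERENCE_AXES`` holds the linear discriminant functions reported
for the original outdoor deployment on "Monthong" fruit, used as reference
coefficients when exercising a model built from stored axes.
"""

from __future__ import annotations

MQ_SENSORS: tuple[str, ...] = (
    "MQ2", "MQ3", "MQ4", "MQ5", "MQ6", "MQ7", "MQ8", "MQ9", "MQ135",
)

GM_SENSORS: tuple[str, ...] = ("GM102B", "GM302B", "GM502B", "GM702B")

SURVEY_SENSORS: tuple[str, ...] = MQ_SENSORS + GM_SENSORS

#: target gases from the distributor datasheets (documentation only)
SENSOR_TARGETS: dict[str, str] = {
    "MQ2": "LPG, propane, methane, hydrogen",
    "MQ3": "alcohol vapors",
    "MQ4": "methane",
    "MQ5": "LPG, natural gas, hydrogen",
    "MQ6": "LPG, butane",
    "MQ7": "carbon monoxide",
    "MQ8": "hydrogen",
    "MQ9": "CO, methane, LPG",
    "MQ135": "ammonia, sulfide, benzene, VOCs",
    "GM102B": "ethanol",
    "GM302B": "formaldehyde",
    "GM502B": "carbon monoxide",
    "GM702B": "nitrogen dioxide",
}

#: sensor -> (mean_uninfested, sd_uninfested, mean_infested, sd_infested),
#: net slope in a.u./s, from the 2024 survey of 5 uninfested + 5 infested fruits
SURVEY_GROUP_SLOPES: dict[str, tuple[float, float, float, float]] = {
    "MQ2": (-0.000001, 0.000088, -0.000010, 0.000027),
    "MQ3": (0.000054, 0.000117, -0.000042, 0.000032),
    "MQ4": (-0.000013, 0.000095, -0.000009, 0.000036),
    "MQ5": (0.000023, 0.000112, -0.000049, 0.000046),
    "MQ6": (0.000026, 0.000030, -0.000020, 0.000019),
    "MQ7": (0.000152, 0.000243, -0.000032, 0.000031),
    "MQ8": (0.000020, 0.000025, -0.000028, 0.000026),
    "MQ9": (0.000020, 0.000027, -0.000016, 0.000009),
    "MQ135": (0.000021, 0.000054, -0.000028, 0.000021),
    "GM102B": (-0.000008, 0.000107, 0.000042, 0.000055),
    "GM302B": (-0.000053, 0.000172, 0.000070, 0.000056),
    "GM502B": (-0.000087, 0.000208, 0.000059, 0.000061),
    "GM702B": (-0.000991, 0.002331, 0.000215, 0.000219),
}

#: sensors reported as significantly responsive to mealybug infestation
#: in the original survey, with the sign of the infestation effect
SURVEY_REPORTED_FLAGS: dict[str, int] = {
    "MQ6": -1,
    "MQ7": -1,
    "MQ8": -1,
    "GM302B": +1,
    "GM502B": +1,
}

#: axis -> {channel: coefficient}; discriminant functions reported for the
#: original outdoor deployment (air / durian / durian+mealybug, GM channels)
OUTDOOR_REFERENCE_AXES: dict[str, dict[str, float]] = {
    "Axis 1": {
        "GM102B": -0.10737,
        "GM302B": 0.23079,
        "GM502B": -0.19401,
        "GM702B": -0.0029751,
    },
    "Axis 2": {
        "GM102B": 0.010277,
        "GM302B": 0.0058381,
        "GM502B": -0.0067202,
        "GM702B": 0.039215,
    },
}
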