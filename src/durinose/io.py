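"""CSV stream I/O, run configuration, and reproducible output writing.

The stream dialect is one row per second:
``time_s,phase,fruit_id,group,day,replicate,<sensor...>,temp_c,rh_pct``
(UTF-8, "." decimal separator, mandatory header).  Extra columns are carried
through as metadata.  Every output file can embed a ``# durinose=<version>
config=<hash>`` comment line so artifacts are traceable to the exact
configuration; re-running with identical config and seed reproduces files
byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import OrderingError, SchemaError, ValidationError

REQUIRED_STREAM_COLUMNS = ("time_s", "phase", "temp_c", "rh_pct")


def read_stream_csv(path) -> pd.DataFrame:
    """Read a raw stream CSV, validating schema and time ordering.

    Comment lines starting with ``#`` are ignored; columns beyond the
    dialect's are preserved as metadata.
    """
    stream = pd.read_csv(path, comment="#")
    missing = [c for c in REQUIRED_STREAM_COLUMNS if c not in stream.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    t = stream["time_s"].to_numpy(dtype=float)
    if len(t) > 1 and not (t[1:] > t[:-1]).all():
        bad = int((t[1:] <= t[:-1]).argmax()) + 1
        raise OrderingError(
            f"{path}: time_s not strictly increasing at row {bad}")
    return stream


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha1(canon.encode()).hexdigest()[:12]


def write_csv(frame: pd.DataFrame, path, meta: str | None = None) -> None:
    """Write a CSV, optionally prefixed with a ``#`` provenance comment
    line (suppressed by passing ``meta=None``)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if meta:
            fh.write(f"# {meta}\n")
        frame.to_csv(fh, index=False)


def write_json(obj: dict, path, meta: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = dict(obj)
    if meta:
        payload["_meta"] = meta
    path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                               default=str) + "\n", encoding="utf-8")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for a pipeline run.

    ``mode`` selects the experiment (``survey``: 13-sensor screening;
    ``outdoor``: 3-class detection with train/test LDA; ``indoor``: daily
    ripening trajectories with staging).  ``design`` holds keyword
    arguments for the matching simulator design; ``stream_csv`` switches
    the survey pipeline from simulation to an external stream file.
    """

    mode: str
    seed: int = 0
    out_dir: str = "results"
    alpha: float = 0.05
    n_permutations: int = 999
    metric: str = "euclidean"
    normalization: str = "relative"
    coverage: float = 0.95
    stream_csv: str | None = None
    write_meta: bool = True
    design: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("survey", "outdoor", "indoor"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if not 0 <= self.alpha <= 1:
            raise ValidationError("alpha must lie in [0, 1]")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if self.metric not in ("euclidean", "braycurtis", "cityblock"):
            raise ValidationError(f"unsupported metric {self.metric!r}")
        if self.normalization not in ("relative", "log"):
            raise ValidationError(
                f"unknown normalization {self.normalization!r}")
        if not 0 < self.coverage < 1:
            raise ValidationError("coverage must lie in (0, 1)")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(
                f"{path}: unknown configuration key(s) {sorted(unknown)}")
        return cls(**raw)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        """Hash of the scientific configuration; where artifacts are written
        (and whether the hash itself is embedded) does not change it."""
        payload = self.as_dict()
        payload.pop("out_dir")
        payload.pop("write_meta")
        return config_hash(payload)
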