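"""CSV / config readers and writers and the run manifest.

Dialects are fixed (comma separator, dot decimal, header required) and
numerics are written with 10 significant digits so that write-then-read is
an identity to well below any tolerance used in the analysis.  Unit
conventions are enforced through header suffixes: ``_min`` for times,
``_ug_ml`` for plasma concentrations, ``_mg_l`` for vessel concentrations.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ivivc import AbsorptionProfile, LevyModel, PlasmaProfile, UIRParameters
from .metrics import DissolutionProfile

__all__ = [
    "RunManifest",
    "read_profile_csv",
    "write_dissolution_csv",
    "write_plasma_csv",
    "write_absorption_csv",
    "read_absorption_csv",
    "read_params",
    "write_params",
]

_FLOAT_FMT = "%.10g"


@dataclass
class RunManifest:
    """Provenance record emitted once per pipeline run."""

    command: str
    config_hash: str
    seed: int
    inputs: list
    outputs: list
    tool_version: str
    timestamp: str

    @classmethod
    def create(cls, command: str, config: dict, seed: int, inputs=(), outputs=()):
        from . import __version__

        blob = json.dumps(config, sort_keys=True, default=str).encode()
        return cls(
            command=command,
            config_hash=hashlib.sha256(blob).hexdigest()[:16],
            seed=seed,
            inputs=[str(p) for p in inputs],
            outputs=[str(p) for p in outputs],
            tool_version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def _read_validated(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: file contains no data rows")
    return df


def read_profile_csv(path: str | Path, kind: str = "dissolution", dose: float = 400.0):
    """Read a two-or-more-column profile CSV into a typed object.

    ``kind='dissolution'`` expects ``time_min,<label>...`` (% dissolved);
    ``kind='plasma'`` expects ``time_min,conc_ug_ml``.  Times must be
    strictly increasing and values non-negative.
    """
    df = _read_validated(path)
    if "time_min" not in df.columns:
        raise ValueError(f"{path}: first column must be 'time_min'")
    t = df["time_min"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: time_min must be strictly increasing")
    value_cols = [c for c in df.columns if c != "time_min"]
    if not value_cols:
        raise ValueError(f"{path}: no value columns found")
    for c in value_cols:
        bad = np.nonzero(df[c].to_numpy(dtype=float) < 0)[0]
        if bad.size:
            raise ValueError(f"{path}: negative values in column {c!r} at rows {bad.tolist()}")

    if kind == "plasma":
        if "conc_ug_ml" not in df.columns:
            raise ValueError(f"{path}: plasma CSV needs a 'conc_ug_ml' column")
        return PlasmaProfile(
            time_points=t,
            concentrations=df["conc_ug_ml"].to_numpy(dtype=float),
            dose=dose,
            label=Path(path).stem,
        )
    if kind == "dissolution":
        profiles = [
            DissolutionProfile(
                time_points=t, values=df[c].to_numpy(dtype=float), label=c
            )
            for c in value_cols
        ]
        return profiles[0] if len(profiles) == 1 else profiles
    raise ValueError(f"unknown profile kind {kind!r}")


def write_dissolution_csv(profiles, path: str | Path) -> None:
    if isinstance(profiles, DissolutionProfile):
        profiles = [profiles]
    base = profiles[0].time_points
    data = {"time_min": base}
    for i, p in enumerate(profiles):
        if not np.array_equal(p.time_points, base):
            raise ValueError("all profiles must share one time grid")
        data[p.label or f"profile_{i}"] = p.values
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_plasma_csv(plasma: PlasmaProfile, path: str | Path) -> None:
    pd.DataFrame(
        {"time_min": plasma.time_points, "conc_ug_ml": plasma.concentrations}
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_absorption_csv(absorption: AbsorptionProfile, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_min": absorption.time_points,
            "fraction_absorbed": absorption.fraction_absorbed,
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_absorption_csv(path: str | Path) -> AbsorptionProfile:
    df = _read_validated(path)
    return AbsorptionProfile(
        time_points=df["time_min"].to_numpy(dtype=float),
        fraction_absorbed=df["fraction_absorbed"].to_numpy(dtype=float),
    )


def write_params(obj, path: str | Path) -> None:
    """Flat key/value file (YAML mapping) for UIR / Levy parameters."""
    if isinstance(obj, UIRParameters):
        data = {"type": "uir", **asdict(obj)}
    elif isinstance(obj, LevyModel):
        data = {
            "type": "levy",
            "slope": obj.slope,
            "intercept": obj.intercept,
            "r_squared": obj.r_squared,
        }
    elif isinstance(obj, dict):
        data = obj
    else:
        data = asdict(obj)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def read_params(path: str | Path):
    data = yaml.safe_load(Path(path).read_text())
    kind = data.pop("type", None)
    if kind == "uir":
        return UIRParameters(**data)
    if kind == "levy":
        data.pop("r_squared", None)
        return LevyModel(**data)
    return data
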