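"""Reading and writing depth-profile tables, fixtures and configuration.

Depth profiles travel as CSV with columns
``depth_index,contrast,percent_signal_change[,sem]`` (1-based depth
index from the white-matter border).  Configuration and fixtures are
YAML (JSON also accepted); constants dump as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .profiles import DepthProfile
from .signal import AcquisitionConstants, RelaxationConstants

__all__ = [
    "read_profiles",
    "write_profiles",
    "trim_profile",
    "load_config",
    "dump_config",
    "constants_dict",
]

REQUIRED_COLUMNS = ("depth_index", "contrast", "percent_signal_change")


class ProfileSchemaError(ValueError):
    """Raised when a profile table violates the CSV schema."""


def write_profiles(
    path: str | Path,
    profiles: Mapping[str, DepthProfile],
    sem: Mapping[str, np.ndarray] | None = None,
) -> Path:
    """Write one or more contrasts to a profile CSV."""
    rows = []
    for contrast, prof in profiles.items():
        for k, (idx, val) in enumerate(zip(prof.depth_indices, prof.values)):
            row = {
                "depth_index": int(idx),
                "contrast": contrast,
                "percent_signal_change": float(val),
            }
            if sem is not None and contrast in sem:
                row["sem"] = float(np.asarray(sem[contrast])[k])
            rows.append(row)
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_profiles(path: str | Path) -> dict[str, DepthProfile]:
    """Read a profile CSV into per-contrast :class:`DepthProfile` objects.

    Raises :class:`ProfileSchemaError` naming the offending column or row
    on malformed input.  A ``sem`` column, when present, is attached as
    ``profile.sem``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ProfileSchemaError(f"{path}: unreadable CSV ({exc})") from exc
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ProfileSchemaError(f"{path}: missing required column {col!r}")
    for col in ("depth_index", "percent_signal_change"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if df[col].isna().any() or bad.any():
            row = int(df.index[df[col].isna() | bad][0])
            raise ProfileSchemaError(f"{path}: non-numeric {col!r} at row {row}")

    out: dict[str, DepthProfile] = {}
    for contrast, sub in df.groupby("contrast", sort=False):
        idx = sub["depth_index"].to_numpy(dtype=int)
        if np.unique(idx).size != idx.size:
            raise ProfileSchemaError(
                f"{path}: duplicate depth_index for contrast {contrast!r}"
            )
        order = np.argsort(idx)
        prof = DepthProfile(
            values=sub["percent_signal_change"].to_numpy(dtype=float)[order],
            contrast=str(contrast),
            trimmed=bool(idx.min() > 1),
            depth_indices=idx[order],
        )
        if "sem" in sub.columns:
            object.__setattr__(
                prof, "sem", sub["sem"].to_numpy(dtype=float)[order]
            )
        out[str(contrast)] = prof
    return out


def trim_profile(profile: DepthProfile) -> DepthProfile:
    """Central-8-point view of a 10-depth profile (already-trimmed pass through)."""
    if profile.trimmed:
        return profile
    return DepthProfile(
        values=profile.values[1:-1],
        contrast=profile.contrast,
        smoothed=profile.smoothed,
        trimmed=True,
        depth_indices=profile.depth_indices[1:-1],
    )


# -- configuration ----------------------------------------------------------


def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON) configuration mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return data


def dump_config(config: Mapping, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(config, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(dict(config), sort_keys=True))
    return path


def constants_dict(
    acq: AcquisitionConstants | None = None,
    relax: RelaxationConstants | None = None,
) -> dict:
    """The active constant set as a JSON-serialisable mapping."""
    acq = acq or AcquisitionConstants()
    relax = relax or RelaxationConstants()
    return {"acquisition": acq.to_dict(), "relaxation": relax.to_dict()}
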