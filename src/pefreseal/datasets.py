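"""Time-series containers and the delimited-text formats used on disk.

All files are comma-separated UTF-8 text with a one-line header and '.'
decimals.  Columns:

fluorescence:  replicate, delta_t_s, intensity_au
uptake:        replicate, field_kV_cm, delta_t_s, ratio, incubation_s
trace:         replicate, time_s, tpp_uM

Numeric output keeps 15 significant digits so write/read round-trips are
lossless at double precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

FLOAT_FORMAT = "%.15g"

FLUORESCENCE_COLUMNS = ["replicate", "delta_t_s", "intensity_au"]
UPTAKE_COLUMNS = ["replicate", "field_kV_cm", "delta_t_s", "ratio", "incubation_s"]
TRACE_COLUMNS = ["replicate", "time_s", "tpp_uM"]


@dataclass(frozen=True)
class FluorescenceSeries:
    """One replicate of the membrane-resealing fluorescence design."""

    delta_t: np.ndarray
    intensity: np.ndarray
    replicate_id: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "delta_t", np.asarray(self.delta_t, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        if self.delta_t.shape != self.intensity.shape or self.delta_t.ndim != 1:
            raise ValidationError("delta_t and intensity must be equal-length 1-d arrays")
        if np.any(self.delta_t < 0):
            raise ValidationError("delays must be non-negative")
        if self.delta_t.size > 1 and not np.all(np.diff(self.delta_t) > 0):
            raise ValidationError("delays must be strictly increasing within a replicate")


@dataclass(frozen=True)
class UptakeRecoveryDataset:
    """One field strength of the cell-wall recovery design: absorbed
    fraction N/N_m versus post-pulse delay at fixed incubation time."""

    field_strength: float
    delta_t: np.ndarray
    ratio: np.ndarray
    incubation_t: float = 180.0
    replicate_id: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "delta_t", np.asarray(self.delta_t, dtype=float))
        object.__setattr__(self, "ratio", np.asarray(self.ratio, dtype=float))
        if self.delta_t.shape != self.ratio.shape or self.delta_t.ndim != 1:
            raise ValidationError("delta_t and ratio must be equal-length 1-d arrays")
        if np.any(self.delta_t < 0):
            raise ValidationError("delays must be non-negative")
        if self.delta_t.size > 1 and not np.all(np.diff(self.delta_t) > 0):
            raise ValidationError("delays must be strictly increasing within a dataset")
        if np.any((self.ratio < 0) | (self.ratio > 1)):
            raise ValidationError("ratios must lie in [0, 1]")
        if not (self.incubation_t > 0):
            raise ValidationError("incubation_t must be > 0 s")


def _read_table(path: Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # empty file, parse failure
        raise ValidationError(f"{path}: cannot parse table ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    for col in required:
        if col == "replicate":
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ValidationError(
                f"{path}: non-numeric value in column '{col}', row {int(bad[0])}"
            )
        if coerced.isna().any():
            raise ValidationError(
                f"{path}: missing value in column '{col}', "
                f"row {int(df.index[coerced.isna()][0])}"
            )
        df[col] = coerced
    if df.empty:
        raise ValidationError(f"{path}: table has no data rows")
    return df


def write_fluorescence_csv(path: Path, series: Iterable[FluorescenceSeries]) -> None:
    frames = []
    for i, s in enumerate(series):
        rep = s.replicate_id if s.replicate_id is not None else f"rep{i:03d}"
        frames.append(
            pd.DataFrame(
                {"replicate": rep, "delta_t_s": s.delta_t, "intensity_au": s.intensity}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def read_fluorescence_csv(path: Path) -> list[FluorescenceSeries]:
    df = _read_table(Path(path), FLUORESCENCE_COLUMNS)
    out = []
    for rep, grp in df.groupby("replicate", sort=True):
        grp = grp.sort_values("delta_t_s")
        out.append(
            FluorescenceSeries(
                delta_t=grp["delta_t_s"].to_numpy(),
                intensity=grp["intensity_au"].to_numpy(),
                replicate_id=str(rep),
            )
        )
    return out


def write_uptake_csv(path: Path, datasets: Iterable[UptakeRecoveryDataset]) -> None:
    frames = []
    for i, d in enumerate(datasets):
        rep = d.replicate_id if d.replicate_id is not None else f"rep{i:03d}"
        frames.append(
            pd.DataFrame(
                {
                    "replicate": rep,
                    "field_kV_cm": d.field_strength,
                    "delta_t_s": d.delta_t,
                    "ratio": d.ratio,
                    "incubation_s": d.incubation_t,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def read_uptake_csv(path: Path) -> list[UptakeRecoveryDataset]:
    df = _read_table(Path(path), UPTAKE_COLUMNS)
    out = []
    for (rep, field_strength), grp in df.groupby(
        ["replicate", "field_kV_cm"], sort=True
    ):
        grp = grp.sort_values("delta_t_s")
        incub = grp["incubation_s"].unique()
        if incub.size != 1:
            raise ValidationError(
                f"{path}: mixed incubation_s within replicate {rep!r}"
            )
        out.append(
            UptakeRecoveryDataset(
                field_strength=float(field_strength),
                delta_t=grp["delta_t_s"].to_numpy(),
                ratio=grp["ratio"].to_numpy(),
                incubation_t=float(incub[0]),
                replicate_id=str(rep),
            )
        )
    return out


def write_trace_csv(path: Path, t_grid: np.ndarray, traces: np.ndarray) -> None:
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    frames = [
        pd.DataFrame(
            {"replicate": f"rep{i:03d}", "time_s": np.asarray(t_grid), "tpp_uM": row}
        )
        for i, row in enumerate(traces)
    ]
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def write_manifest(path: Path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_manifest(path: Path) -> dict:
    return json.loads(Path(path).read_text())
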