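"""Session and results file I/O.

A trial session is a directory holding three plain-text files:

``config``
    Flat ``key: value`` text (a YAML-compatible subset) with subject,
    prosthesis and acquisition metadata.
``forces.csv``
    Columns ``time_s, f_ml_N, f_ap_N, f_v_N`` — 3-component ground reaction
    force sampled uniformly at ``force_rate`` (default 1000 Hz).  Vertical is
    positive up, anterior positive forward, lab frame fixed to the treadmill.
``markers.csv`` (optional)
    Columns ``time_s, ap_AL_m, ap_UL_m`` — fore-aft positions of the
    prosthesis-tip and fifth-metatarsal markers at ``marker_rate``
    (default 200 Hz).

Files store SI units only; body-weight normalisation happens downstream.
Analysis output is a long-format results table with one row per
(subject, configuration, variable, leg-or-aggregate) key.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError, FormatError, VocabularyError

__all__ = [
    "TrialConfig",
    "ForceTrace",
    "MarkerTrace",
    "Session",
    "read_session",
    "write_session",
    "read_results",
    "write_results",
    "results_table",
    "RESULT_VARIABLES",
    "RESULT_COLUMNS",
]

#: Spacing tolerance for "uniformly sampled" time grids, in seconds.
TIME_TOL = 1e-9

LEGS = ("AL", "UL")

#: Base variable vocabulary for results tables.  Symmetry indices are the
#: same names prefixed with ``si_``.
RESULT_VARIABLES = frozenset(
    {
        "step_frequency",
        "step_time",
        "contact_time",
        "aerial_time",
        "contact_length",
        "stance_avg_vgrf",
        "stance_avg_vgrf_bw",
        "peak_vgrf",
        "peak_resultant_grf",
        "leg_stiffness",
        "contact_angle",
        "delta_y",
        "delta_leg",
        "delta_rsp",
        "vmax",
        "belt_speed_marker",
    }
)

RESULT_COLUMNS = [
    "subject",
    "rsp_model",
    "stiffness_category",
    "height_offset",
    "velocity",
    "variable",
    "leg",
    "value",
]


@dataclass(frozen=True)
class TrialConfig:
    """Subject, prosthesis and acquisition metadata for one trial.

    ``L0_AL`` is the affected-leg length measured from the greater trochanter
    to the distal end of the unloaded prosthesis; ``L0_UL`` the unaffected-leg
    length from the greater trochanter to the floor during standing.
    ``k_RSP`` is the bench-measured prosthesis stiffness in kN/m.
    """

    subject_id: str
    body_mass: float  # kg
    belt_velocity: float  # m/s
    L0_AL: float  # m
    L0_UL: float  # m
    k_RSP: float  # kN/m
    force_rate: float = 1000.0  # Hz
    marker_rate: float = 200.0  # Hz
    rsp_model: str = "OBK"
    stiffness_category: int = 0  # offset from recommended, in {-1, 0, +1}
    height_offset: int = 0  # cm offset from recommended, in {-2, 0, +2}
    first_contact_leg: str = "AL"

    def __post_init__(self) -> None:
        for name in ("body_mass", "belt_velocity", "force_rate", "marker_rate",
                     "L0_AL", "L0_UL", "k_RSP"):
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise ConfigError(f"config key {name!r} must be a positive number, got {value!r}")
        if self.first_contact_leg not in LEGS:
            raise ConfigError(
                f"config key 'first_contact_leg' must be one of {LEGS}, got {self.first_contact_leg!r}"
            )

    def leg_length(self, leg: str) -> float:
        """Unloaded leg length for ``leg`` ('AL' or 'UL'), never swapped."""
        if leg == "AL":
            return self.L0_AL
        if leg == "UL":
            return self.L0_UL
        raise ConfigError(f"unknown leg label {leg!r}")


def _check_uniform(time: np.ndarray, rate: float, what: str) -> None:
    if time.ndim != 1 or time.size < 2:
        raise FormatError(f"{what}: need at least 2 samples")
    dt = np.diff(time)
    if np.any(dt <= 0):
        raise FormatError(f"{what}: time must be strictly increasing")
    if np.max(np.abs(dt - 1.0 / rate)) > TIME_TOL:
        raise FormatError(
            f"{what}: time grid is not uniform at {rate} Hz (max deviation "
            f"{np.max(np.abs(dt - 1.0 / rate)):.3g} s)"
        )


@dataclass(frozen=True)
class ForceTrace:
    """Uniformly sampled 3-component GRF series for one trial."""

    time: np.ndarray  # s
    f_ml: np.ndarray  # N, medio-lateral
    f_ap: np.ndarray  # N, fore-aft, positive anterior
    f_v: np.ndarray  # N, vertical, positive up
    rate: float  # Hz

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        for name in ("f_ml", "f_ap", "f_v"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != self.time.shape:
                raise FormatError(f"forces: channel {name} length differs from time")
        _check_uniform(self.time, self.rate, "forces")


@dataclass(frozen=True)
class MarkerTrace:
    """Fore-aft marker positions (lab frame) for both legs."""

    time: np.ndarray  # s
    ap_AL: np.ndarray  # m
    ap_UL: np.ndarray  # m
    rate: float  # Hz

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        for name in ("ap_AL", "ap_UL"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != self.time.shape:
                raise FormatError(f"markers: channel {name} length differs from time")
        _check_uniform(self.time, self.rate, "markers")

    def ap(self, leg: str) -> np.ndarray:
        return self.ap_AL if leg == "AL" else self.ap_UL


@dataclass(frozen=True)
class Session:
    config: TrialConfig
    forces: ForceTrace
    markers: Optional[MarkerTrace] = None


_CONFIG_FLOAT_KEYS = ("body_mass", "belt_velocity", "force_rate", "marker_rate",
                      "L0_AL", "L0_UL", "k_RSP")
_CONFIG_INT_KEYS = ("stiffness_category", "height_offset")
_CONFIG_STR_KEYS = ("subject_id", "rsp_model", "first_contact_leg")


def _parse_config(path: Path) -> TrialConfig:
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:  # pragma: no cover - malformed YAML is rare
        raise ConfigError(f"cannot parse config file {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} is not a key-value mapping")
    kwargs = {}
    for key in _CONFIG_FLOAT_KEYS:
        if key in raw:
            try:
                kwargs[key] = float(raw[key])
            except (TypeError, ValueError):
                raise ConfigError(f"config key {key!r} is not numeric: {raw[key]!r}")
    for key in _CONFIG_INT_KEYS:
        if key in raw:
            try:
                kwargs[key] = int(raw[key])
            except (TypeError, ValueError):
                raise ConfigError(f"config key {key!r} is not an integer: {raw[key]!r}")
    for key in _CONFIG_STR_KEYS:
        if key in raw:
            kwargs[key] = str(raw[key])
    required = {"subject_id", "body_mass", "belt_velocity", "L0_AL", "L0_UL", "k_RSP"}
    missing = required - kwargs.keys()
    if missing:
        raise ConfigError(f"config file {path} missing required key(s): {sorted(missing)}")
    return TrialConfig(**kwargs)


def _format_number(x) -> str:
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return repr(float(x))


def write_session(path, config: TrialConfig, forces: ForceTrace,
                  markers: Optional[MarkerTrace] = None) -> Path:
    """Write a session directory; returns the directory path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    lines = []
    for f in fields(TrialConfig):
        value = getattr(config, f.name)
        lines.append(f"{f.name}: {_format_number(value) if not isinstance(value, str) else value}")
    (path / "config").write_text("\n".join(lines) + "\n")

    pd.DataFrame(
        {"time_s": forces.time, "f_ml_N": forces.f_ml,
         "f_ap_N": forces.f_ap, "f_v_N": forces.f_v}
    ).to_csv(path / "forces.csv", index=False)
    if markers is not None:
        pd.DataFrame(
            {"time_s": markers.time, "ap_AL_m": markers.ap_AL, "ap_UL_m": markers.ap_UL}
        ).to_csv(path / "markers.csv", index=False)
    return path


def read_session(path) -> Session:
    """Read a session directory into validated objects.

    A missing ``markers.csv`` yields ``Session.markers is None``; a missing
    forces or config file is an error.
    """
    path = Path(path)
    config_path = path / "config"
    forces_path = path / "forces.csv"
    if not config_path.exists():
        raise ConfigError(f"session {path} has no config file")
    if not forces_path.exists():
        raise FormatError(f"session {path} has no forces.csv")
    config = _parse_config(config_path)

    fdf = pd.read_csv(forces_path)
    expected = ["time_s", "f_ml_N", "f_ap_N", "f_v_N"]
    if list(fdf.columns) != expected:
        raise FormatError(f"forces.csv columns {list(fdf.columns)} != {expected}")
    forces = ForceTrace(
        time=fdf["time_s"].to_numpy(),
        f_ml=fdf["f_ml_N"].to_numpy(),
        f_ap=fdf["f_ap_N"].to_numpy(),
        f_v=fdf["f_v_N"].to_numpy(),
        rate=config.force_rate,
    )
    markers = None
    markers_path = path / "markers.csv"
    if markers_path.exists():
        mdf = pd.read_csv(markers_path)
        expected_m = ["time_s", "ap_AL_m", "ap_UL_m"]
        if list(mdf.columns) != expected_m:
            raise FormatError(f"markers.csv columns {list(mdf.columns)} != {expected_m}")
        markers = MarkerTrace(
            time=mdf["time_s"].to_numpy(),
            ap_AL=mdf["ap_AL_m"].to_numpy(),
            ap_UL=mdf["ap_UL_m"].to_numpy(),
            rate=config.marker_rate,
        )
    return Session(config=config, forces=forces, markers=markers)


def _check_vocabulary(variables) -> None:
    for var in variables:
        base = var[3:] if var.startswith("si_") else var
        if base not in RESULT_VARIABLES:
            raise VocabularyError(
                f"unknown results variable {var!r}; base names must be in the "
                f"declared vocabulary"
            )


def results_table(rows) -> pd.DataFrame:
    """Build a vocabulary-checked long-format results table from row dicts."""
    df = pd.DataFrame(list(rows), columns=RESULT_COLUMNS)
    _check_vocabulary(df["variable"])
    return df


def write_results(table: pd.DataFrame, path) -> Path:
    """Write a long-format results table with deterministic order."""
    missing = [c for c in RESULT_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"results table missing column(s): {missing}")
    _check_vocabulary(table["variable"])
    out = (
        table[RESULT_COLUMNS]
        .sort_values(RESULT_COLUMNS[:-1], kind="mergesort")
        .reset_index(drop=True)
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)
    return path


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != RESULT_COLUMNS:
        raise FormatError(f"results columns {list(df.columns)} != {RESULT_COLUMNS}")
    _check_vocabulary(df["variable"])
    return df
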