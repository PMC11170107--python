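"""Reading and writing of spike lists, plate maps, configs and reports.

All on-disk artefacts are plain text: CSV for tabular data (comma separated,
UTF-8, ``.`` decimal) and JSON for configuration.  Spike times are seconds,
0-based from the start of each phase; baseline and treated phases are stored
as separate recordings.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PHASES = ("baseline", "treated")
ROLES = ("vehicle", "negative_control", "positive_control", "test")

#: Hazard labels in increasing order of severity, with their display colors.
HAZARD_LABELS = ("non-neuroactive", "neuroactive", "hazard", "high hazard")
HAZARD_COLORS = {
    "non-neuroactive": "green",
    "neuroactive": "yellow",
    "hazard": "orange",
    "high hazard": "red",
}

#: Column aliases accepted in vendor spike-list exports.
SPIKE_LIST_ALIASES = {
    "time (s)": "time_s",
    "time": "time_s",
    "timestamp": "time_s",
    "electrode": "electrode",
    "well": "well",
    "phase": "phase",
}


class FormatError(ValueError):
    """A file does not conform to the expected schema."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpikeTrain:
    """Spike timestamps of one electrode, seconds from recording start."""

    electrode_id: str
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        if ts.ndim != 1:
            raise ValidationError("timestamps must be one-dimensional")
        if ts.size and (np.any(np.diff(ts) <= 0) or ts[0] < 0):
            raise ValidationError(
                f"timestamps of electrode {self.electrode_id!r} must be "
                "non-negative and strictly increasing"
            )

    @property
    def n_spikes(self) -> int:
        return int(self.timestamps.size)


@dataclass
class WellRecording:
    """Spike trains of (up to) 16 electrodes of one well, one phase."""

    well_id: str
    phase: str
    trains: dict[str, SpikeTrain]
    duration_s: float = 1800.0
    plate_id: str = "plate1"
    n_electrodes: int = 16

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValidationError(
                f"phase must be one of {PHASES}, got {self.phase!r}"
            )
        if self.duration_s <= 0:
            raise ValidationError("duration_s must be positive")
        if len(self.trains) > self.n_electrodes:
            raise ValidationError(
                f"well {self.well_id}: {len(self.trains)} trains exceed the "
                f"{self.n_electrodes}-electrode layout"
            )
        for train in self.trains.values():
            if train.timestamps.size and train.timestamps[-1] > self.duration_s:
                raise ValidationError(
                    f"well {self.well_id}: spike at "
                    f"{train.timestamps[-1]:.3f}s beyond duration "
                    f"{self.duration_s}s"
                )

    @property
    def total_spikes(self) -> int:
        return sum(t.n_spikes for t in self.trains.values())


@dataclass(frozen=True)
class WellAssignment:
    role: str
    compound: str = ""
    concentration_um: float = 0.0
    replicate_group: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(
                f"unknown role {self.role!r}; allowed roles: {', '.join(ROLES)}"
            )
        if self.concentration_um < 0:
            raise ValidationError("concentration_uM must be non-negative")
        if self.role == "vehicle" and (self.compound or self.concentration_um):
            raise ValidationError(
                "vehicle wells must have empty compound and zero concentration"
            )


@dataclass
class PlateMap:
    """Assignment of wells to roles / compounds / concentrations."""

    wells: dict[str, WellAssignment]

    def __len__(self) -> int:
        return len(self.wells)

    def __getitem__(self, well_id: str) -> WellAssignment:
        return self.wells[well_id]

    def wells_with_role(self, role: str) -> list[str]:
        return [w for w, a in self.wells.items() if a.role == role]

    def check_covers(self, recordings: Iterable[WellRecording]) -> None:
        missing = sorted(
            {r.well_id for r in recordings} - set(self.wells)
        )
        if missing:
            raise ValidationError(
                f"wells absent from plate map: {', '.join(missing)}"
            )


# ---------------------------------------------------------------------------
# scoring matrix & config
# ---------------------------------------------------------------------------

ZONES = ("no_effect", "mild_down", "mild_up", "strong_down", "strong_up")

#: The four continuous key parameters entering the zone-based scoring.
KEY_PARAMETERS = (
    "wmfr_hz",
    "mean_burst_duration_s",
    "aucc",
    "median_over_mean_isi",
)

_DEFAULT_POINTS = {
    "no_effect": 0,
    "mild_down": 1,
    "mild_up": 1,
    "strong_down": 2,
    "strong_up": 2,
}


@dataclass
class ScoringMatrix:
    """Zone -> weighted points per parameter plus score-range -> label map.

    Points are severity magnitudes (non-negative); the direction of the
    effect is carried by the zone name.  ``label_ranges`` is an ordered list
    of ``[min_total, max_total_or_null, label]`` covering all attainable
    totals exactly once.
    """

    points: dict[str, dict[str, int]] = field(
        default_factory=lambda: {
            p: dict(_DEFAULT_POINTS) for p in KEY_PARAMETERS
        }
    )
    fs_points: int = 3
    ns_points: int = 2
    label_ranges: list[tuple[int, int | None, str]] = field(
        default_factory=lambda: [
            (0, 0, "non-neuroactive"),
            (1, 2, "neuroactive"),
            (3, 4, "hazard"),
            (5, None, "high hazard"),
        ]
    )

    def __post_init__(self) -> None:
        for param, zp in self.points.items():
            if zp.get("no_effect", 0) != 0:
                raise ValidationError(
                    f"{param}: no_effect points must be 0"
                )
            for d in ("up", "down"):
                if abs(zp[f"strong_{d}"]) < abs(zp[f"mild_{d}"]):
                    raise ValidationError(
                        f"{param}: |strong_{d}| must be >= |mild_{d}|"
                    )
        labels = [r[2] for r in self.label_ranges]
        if set(labels) - set(HAZARD_LABELS):
            raise ValidationError(
                f"unknown labels {set(labels) - set(HAZARD_LABELS)}"
            )

    def label_for(self, total: int) -> str:
        for lo, hi, label in self.label_ranges:
            if total >= lo and (hi is None or total <= hi):
                return label
        raise ValidationError(f"total score {total} outside label ranges")

    def to_dict(self) -> dict:
        return {
            "points": self.points,
            "fs_points": self.fs_points,
            "ns_points": self.ns_points,
            "label_ranges": [list(r) for r in self.label_ranges],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScoringMatrix":
        return cls(
            points={k: dict(v) for k, v in d["points"].items()},
            fs_points=int(d["fs_points"]),
            ns_points=int(d["ns_points"]),
            label_ranges=[
                (int(lo), None if hi is None else int(hi), str(label))
                for lo, hi, label in d["label_ranges"]
            ],
        )


@dataclass
class ScoringConfig:
    """All tunables of the pipeline, round-trippable through JSON."""

    # QC
    qc_electrode_rate_hz: float = 0.1
    qc_active_fraction: float = 0.40
    # tolerance intervals
    ti_coverage: float = 0.95
    ti_confidence: float = 0.95
    ti_method: str = "auto"  # auto | normal | nonparametric
    normality_alpha: float = 0.01
    # burst detection (Poisson Surprise)
    surprise_threshold: float = 10.0
    min_burst_spikes: int = 3
    max_burst_spikes: int = 200
    # cross-correlation
    aucc_bin_s: float = 0.005
    aucc_max_lag_s: float = 0.100
    aucc_on_bursts: bool = False
    # network bursts
    nb_participation_fraction: float = 0.5
    nb_merge_gap_s: float = 0.100
    # cessation flags
    fs_fraction: float = 0.05
    # normalization
    vehicle_norm: str = "subtract"  # subtract | divide
    significance_gate: bool = False
    significance_alpha: float = 0.05
    # evaluation
    fcmax_fold_window: float = 30.0
    # misc
    seed: int = 0
    matrix: ScoringMatrix = field(default_factory=ScoringMatrix)
    cutoffs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "qc_active_fraction",
            "ti_coverage",
            "ti_confidence",
            "normality_alpha",
            "significance_alpha",
        ):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must be in (0, 1), got {v}")
        if self.vehicle_norm not in ("subtract", "divide"):
            raise ValidationError("vehicle_norm must be 'subtract' or 'divide'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["matrix"] = self.matrix.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScoringConfig":
        d = dict(d)
        if "matrix" in d:
            d["matrix"] = ScoringMatrix.from_dict(d["matrix"])
        return cls(**d)


def read_scoring_config(path: str | Path) -> ScoringConfig:
    with open(path, encoding="utf-8") as fh:
        return ScoringConfig.from_dict(json.load(fh))


def write_scoring_config(cfg: ScoringConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(cfg.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# spike lists
# ---------------------------------------------------------------------------


def _canonical_columns(columns: Sequence[str]) -> dict[str, str]:
    mapping = {}
    for col in columns:
        key = col.strip().lower()
        if key in SPIKE_LIST_ALIASES:
            mapping[col] = SPIKE_LIST_ALIASES[key]
    return mapping


def read_spike_list(
    path: str | Path,
    duration_s: float = 1800.0,
    plate_id: str | None = None,
) -> list[WellRecording]:
    """Read a spike-list CSV into one :class:`WellRecording` per (well, phase).

    Expected columns: ``well, electrode, phase, time_s`` (vendor aliases such
    as ``Time (s)`` / ``Electrode`` are auto-mapped; extra columns ignored).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    df = df.rename(columns=_canonical_columns(df.columns))
    for col in ("well", "electrode", "phase", "time_s"):
        if col not in df.columns:
            raise FormatError(
                f"{path.name}: missing mandatory column {col!r}"
            )
    if len(df) == 0:
        return []

    times = pd.to_numeric(df["time_s"], errors="coerce")
    bad = times.isna() | (times < 0)
    if bad.any():
        # +2: header line and 1-based numbering
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise FormatError(
            f"{path.name} line {line}: negative or non-numeric time "
            f"{df['time_s'].iloc[line - 2]!r}"
        )
    df = df.assign(time_s=times.astype(float))

    n_before = len(df)
    df = df.drop_duplicates(subset=["well", "electrode", "phase", "time_s"])
    if len(df) < n_before:
        msg = f"{path.name}: collapsed {n_before - len(df)} duplicate spike rows"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)

    recs: list[WellRecording] = []
    for (well, phase), group in sorted(
        df.groupby(["well", "phase"], sort=True), key=lambda kv: kv[0]
    ):
        trains = {}
        for electrode, sub in sorted(group.groupby("electrode", sort=True)):
            ts = np.sort(sub["time_s"].to_numpy())
            trains[str(electrode)] = SpikeTrain(str(electrode), ts)
        recs.append(
            WellRecording(
                well_id=str(well),
                phase=str(phase),
                trains=trains,
                duration_s=duration_s,
                plate_id=plate_id or path.stem,
            )
        )
    return recs


def write_spike_list(recordings: Iterable[WellRecording], path: str | Path) -> None:
    rows = []
    for rec in recordings:
        for eid in sorted(rec.trains):
            for t in rec.trains[eid].timestamps:
                rows.append((rec.well_id, eid, rec.phase, t))
    df = pd.DataFrame(rows, columns=["well", "electrode", "phase", "time_s"])
    df.to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# plate maps
# ---------------------------------------------------------------------------


def read_plate_map(path: str | Path) -> PlateMap:
    path = Path(path)
    df = pd.read_csv(path, dtype=str).fillna("")
    for col in ("well", "role", "compound", "concentration_uM"):
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing mandatory column {col!r}")
    wells = {}
    for _, row in df.iterrows():
        conc = float(row["concentration_uM"]) if row["concentration_uM"] else 0.0
        wells[str(row["well"])] = WellAssignment(
            role=str(row["role"]),
            compound=str(row["compound"]),
            concentration_um=conc,
            replicate_group=str(row.get("replicate_group", "")),
        )
    return PlateMap(wells)


def write_plate_map(pmap: PlateMap, path: str | Path) -> None:
    rows = [
        (w, a.role, a.compound, a.concentration_um, a.replicate_group)
        for w, a in sorted(pmap.wells.items())
    ]
    pd.DataFrame(
        rows,
        columns=["well", "role", "compound", "concentration_uM", "replicate_group"],
    ).to_csv(path, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def write_report(results: Sequence, path: str | Path) -> None:
    """Write hazard results (one row per compound/concentration) to CSV."""
    if not results:
        raise ValidationError("cannot write an empty report")
    rows = []
    for r in results:
        row = {
            "compound": r.compound,
            "concentration_uM": r.concentration_um,
            "total_score": r.total_score,
            "label": r.label,
            "color": r.color,
            "firing_cessation": r.firing_cessation,
            "network_cessation": r.network_cessation,
        }
        if getattr(r, "fold_fcmax", None) is not None:
            row["fold_fcmax"] = r.fold_fcmax
        for param in sorted(r.zones):
            row[f"zone.{param}"] = r.zones[param]
            row[f"points.{param}"] = r.points[param]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def read_report(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    bad = set(df["label"]) - set(HAZARD_LABELS)
    if bad:
        raise FormatError(f"unknown hazard labels in report: {sorted(bad)}")
    return df


# ---------------------------------------------------------------------------
# feature / effect tables
# ---------------------------------------------------------------------------


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_effect_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.12g")


def read_effect_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
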