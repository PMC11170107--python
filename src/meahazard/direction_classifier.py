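"""Random-Forest classification of effect profiles: inhibitory / excitatory
/ vehicle-like, with calibrated class probabilities per condition."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .io_formats import ValidationError
from .spike_features import PARAMETER_PANEL

DIRECTION_CLASSES = ("excitatory", "inhibitory", "vehicle")


@dataclass(frozen=True)
class DirectionProbabilities:
    p_inhibitory: float
    p_excitatory: float
    p_vehicle: float
    predicted: str

    def __post_init__(self) -> None:
        total = self.p_inhibitory + self.p_excitatory + self.p_vehicle
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"probabilities sum to {total}, not 1")


@dataclass
class DirectionModel:
    forest: RandomForestClassifier
    columns: tuple[str, ...]
    oob_accuracy: float


def fit_direction_model(
    X: pd.DataFrame,
    y,
    n_trees: int = 500,
    seed: int = 0,
) -> DirectionModel:
    """Fit the bagged decision-tree ensemble on dd% effect profiles.

    ``y`` labels must include all three of inhibitory / excitatory / vehicle.
    Rows are sorted internally so the fit is invariant to input row order.
    """
    y = np.asarray(y)
    missing = set(DIRECTION_CLASSES) - set(np.unique(y))
    if missing:
        raise ValidationError(
            f"training data missing class(es): {', '.join(sorted(missing))}"
        )
    X = X.fillna(X.median(numeric_only=True)).fillna(0.0)
    order = np.lexsort(
        (np.arange(len(X)), *[X[c].to_numpy() for c in reversed(X.columns)], y)
    )
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        random_state=seed,
        oob_score=True,
        n_jobs=1,
    )
    forest.fit(X.to_numpy(dtype=float)[order], y[order])
    return DirectionModel(
        forest=forest,
        columns=tuple(X.columns),
        oob_accuracy=float(forest.oob_score_),
    )


def predict_direction(
    model: DirectionModel, effects: pd.DataFrame | dict
) -> list[DirectionProbabilities]:
    """Vote-fraction class probabilities for one or more effect profiles."""
    if isinstance(effects, dict):
        effects = pd.DataFrame([effects])
    got, want = set(effects.columns), set(model.columns)
    if got != want:
        raise ValidationError(
            f"column mismatch: missing {sorted(want - got)}, "
            f"unexpected {sorted(got - want)}"
        )
    X = effects[list(model.columns)].fillna(0.0).to_numpy(dtype=float)
    proba = model.forest.predict_proba(X)
    classes = list(model.forest.classes_)
    out = []
    for row in proba:
        p = dict(zip(classes, row))
        pred = classes[int(np.argmax(row))]
        out.append(
            DirectionProbabilities(
                p_inhibitory=float(p.get("inhibitory", 0.0)),
                p_excitatory=float(p.get("excitatory", 0.0)),
                p_vehicle=float(p.get("vehicle", 0.0)),
                predicted=pred,
            )
        )
    return out


def make_direction_benchmark(
    n_per_class: int = 50, noise_sd: float = 10.0, seed: int = 0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Packaged separable 3-class benchmark over the dd% parameter panel.

    Inhibitory profiles center at WMFR dd% ~ -70 (with burst/synchrony
    depression), excitatory at +70 with an AuCC shift, vehicle at 0; all
    other panel columns are pure noise.
    """
    rng = np.random.default_rng(seed)
    centroids = {
        "inhibitory": {
            "wmfr_hz": -70.0,
            "mean_burst_duration_s": -30.0,
            "aucc": -40.0,
            "median_over_mean_isi": 10.0,
        },
        "excitatory": {
            "wmfr_hz": 70.0,
            "mean_burst_duration_s": 25.0,
            "aucc": 45.0,
            "median_over_mean_isi": -10.0,
        },
        "vehicle": {},
    }
    rows, labels = [], []
    for cls in DIRECTION_CLASSES:
        for _ in range(n_per_class):
            row = {
                p: rng.normal(centroids[cls].get(p, 0.0), noise_sd)
                for p in PARAMETER_PANEL
            }
            rows.append(row)
            labels.append(cls)
    return pd.DataFrame(rows), np.asarray(labels)


def save_model(model: DirectionModel, path: str | Path) -> None:
    """Persist the fitted ensemble (versioned JSON + sklearn pickle-free
    re-fit is out of scope; trees are stored via joblib-compatible pickle)."""
    import pickle

    payload = {
        "format_version": 1,
        "columns": model.columns,
        "oob_accuracy": model.oob_accuracy,
    }
    path = Path(path)
    with open(path, "wb") as fh:
        pickle.dump({"meta": payload, "forest": model.forest}, fh)
    with open(path.with_suffix(path.suffix + ".json"), "w", encoding="utf-8") as fh:
        json.dump({k: list(v) if isinstance(v, tuple) else v for k, v in payload.items()}, fh, indent=2)


def load_model(path: str | Path) -> DirectionModel:
    import pickle

    with open(path, "rb") as fh:
        blob = pickle.load(fh)
    return DirectionModel(
        forest=blob["forest"],
        columns=tuple(blob["meta"]["columns"]),
        oob_accuracy=float(blob["meta"]["oob_accuracy"]),
    )
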