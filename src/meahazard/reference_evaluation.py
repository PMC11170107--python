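"""Predictivity of the hazard scores against reference risk classes.

A compound's call is its worst hazard label across tested concentrations
within a fold-of-fCmax window; each evaluated risk class then gets a
one-vs-rest confusion matrix under a user-supplied mapping of risk classes
and hazard labels to the positive side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .hazard_scoring import HazardResult
from .io_formats import HAZARD_LABELS, ValidationError
from .parameter_selection import ConfusionMetrics, classification_metrics

RISK_CLASSES = ("no_risk", "low_risk", "neuroactive", "high_seizure_risk")

_LABEL_ORDER = {label: i for i, label in enumerate(HAZARD_LABELS)}


@dataclass(frozen=True)
class ReferenceLabel:
    compound: str
    risk_class: str
    fcmax_um: float | None = None

    def __post_init__(self) -> None:
        if self.risk_class not in RISK_CLASSES:
            raise ValidationError(
                f"unknown risk class {self.risk_class!r}; "
                f"allowed: {', '.join(RISK_CLASSES)}"
            )
        if self.fcmax_um is not None and self.fcmax_um <= 0:
            raise ValidationError("fcmax_um must be positive when given")


@dataclass(frozen=True)
class ClassMapping:
    """Positive/negative partition for one evaluated class."""

    name: str
    positive_risk_classes: frozenset
    positive_hazard_labels: frozenset


DEFAULT_MAPPINGS = (
    ClassMapping(
        "seizure_risk",
        frozenset({"high_seizure_risk"}),
        frozenset({"hazard", "high hazard"}),
    ),
    ClassMapping(
        "neuroactive",
        frozenset({"neuroactive"}),
        frozenset({"neuroactive"}),
    ),
)


@dataclass
class PredictivityReport:
    metrics: dict[str, ConfusionMetrics]
    mappings: tuple[ClassMapping, ...]
    n_evaluated: int
    excluded: list[str] = field(default_factory=list)


def worst_label(
    results: list[HazardResult],
    fcmax_um: float | None,
    fold_window: float = 30.0,
) -> str:
    """Most severe label among concentrations within fold_window x fCmax.

    Without an fCmax, all tested concentrations count.
    """
    eligible = [
        r
        for r in results
        if fcmax_um is None or r.concentration_um <= fold_window * fcmax_um
    ]
    if not eligible:
        eligible = results
    return max(eligible, key=lambda r: _LABEL_ORDER[r.label]).label


def evaluate_panel(
    hazard_results: dict[str, list[HazardResult]],
    labels: list[ReferenceLabel],
    mappings: tuple[ClassMapping, ...] = DEFAULT_MAPPINGS,
    fold_window: float = 30.0,
) -> PredictivityReport:
    """One-vs-rest confusion metrics per evaluated class.

    Compounds lacking either results or a reference label are excluded with
    a warning and listed in the report.
    """
    by_compound = {lab.compound: lab for lab in labels}
    shared = sorted(set(hazard_results) & set(by_compound))
    excluded = sorted(
        (set(hazard_results) | set(by_compound)) - set(shared)
    )
    if not shared:
        raise ValidationError("no compounds with both results and labels")
    if excluded:
        import warnings

        warnings.warn(
            f"excluded compounds without both a result and a label: "
            f"{', '.join(excluded)}",
            stacklevel=2,
        )
    calls = {
        c: worst_label(
            hazard_results[c], by_compound[c].fcmax_um, fold_window
        )
        for c in shared
    }
    metrics = {}
    for mapping in mappings:
        tp = fp = tn = fn = 0
        for c in shared:
            truth = by_compound[c].risk_class in mapping.positive_risk_classes
            pred = calls[c] in mapping.positive_hazard_labels
            if truth and pred:
                tp += 1
            elif truth:
                fn += 1
            elif pred:
                fp += 1
            else:
                tn += 1
        if tp + fn == 0 or tn + fp == 0:
            import warnings

            warnings.warn(
                f"class {mapping.name!r}: no positive or no negative "
                "compounds in the panel; metrics not evaluable",
                stacklevel=2,
            )
            continue
        metrics[mapping.name] = classification_metrics(tp, fp, tn, fn)
    return PredictivityReport(
        metrics=metrics,
        mappings=mappings,
        n_evaluated=len(shared),
        excluded=excluded,
    )


def read_reference_labels(path: str | Path) -> list[ReferenceLabel]:
    df = pd.read_csv(path)
    for col in ("compound", "risk_class"):
        if col not in df.columns:
            raise ValidationError(f"reference labels: missing column {col!r}")
    labels = []
    for _, row in df.iterrows():
        fcmax = row.get("fcmax_um")
        fcmax = None if pd.isna(fcmax) else float(fcmax)
        labels.append(
            ReferenceLabel(str(row["compound"]), str(row["risk_class"]), fcmax)
        )
    if len({lab.compound for lab in labels}) != len(labels):
        raise ValidationError("duplicate compounds in reference labels")
    return labels


def report_to_frame(report: PredictivityReport) -> pd.DataFrame:
    rows = []
    for name, m in report.metrics.items():
        rows.append(
            {
                "class": name,
                "tp": m.tp,
                "fp": m.fp,
                "tn": m.tn,
                "fn": m.fn,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "balanced_accuracy": m.balanced_accuracy,
                "ber": m.ber,
                "ppv": m.ppv,
                "npv": m.npv,
                "kappa": m.kappa,
            }
        )
    return pd.DataFrame(rows)
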