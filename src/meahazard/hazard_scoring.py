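"""Weighted hazard scoring: dd% zones -> points -> total score -> label.

The scoring matrix is data, not algorithm: zone points per parameter, the
points of the two binary cessation flags, and the score-range -> label map
all live in :class:`~meahazard.io_formats.ScoringMatrix` (JSON on disk).
The default matrix uses severity magnitudes mild = 1 / strong = 2 per
continuous key parameter, FS = 3 and NS = 2, with totals 0 / 1-2 / 3-4 / >=5
mapping to non-neuroactive / neuroactive / hazard / high hazard.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .cutoff_calibration import ZoneCutoffs
from .effect_normalization import EffectSize
from .io_formats import (
    HAZARD_COLORS,
    KEY_PARAMETERS,
    ScoringMatrix,
    ValidationError,
)

#: Zone severity used by the boundary tie rule and monotonicity checks.
ZONE_SEVERITY = {
    "no_effect": 0,
    "mild_down": 1,
    "mild_up": 1,
    "strong_down": 2,
    "strong_up": 2,
}


@dataclass
class HazardResult:
    compound: str
    concentration_um: float
    zones: dict[str, str]
    points: dict[str, int]
    firing_cessation: bool
    network_cessation: bool
    total_score: int
    label: str
    color: str
    annotations: dict[str, str] = field(default_factory=dict)
    fold_fcmax: float | None = None


def assign_zone(dd_pct: float, cutoffs: ZoneCutoffs) -> tuple[str, str | None]:
    """Zone containing ``dd_pct``; boundary values go to the more severe zone.

    Returns (zone, annotation); a missing dd% maps to ``no_effect`` with a
    ``"not evaluable"`` annotation.
    """
    if dd_pct is None or math.isnan(dd_pct):
        return "no_effect", "not evaluable"
    if dd_pct >= cutoffs.strong_up_edge:
        return "strong_up", None
    if dd_pct <= cutoffs.strong_down_edge:
        return "strong_down", None
    if dd_pct >= cutoffs.mild_up_edge:
        return "mild_up", None
    if dd_pct <= cutoffs.mild_down_edge:
        return "mild_down", None
    return "no_effect", None


def score_condition(
    effects: dict[str, EffectSize | float],
    flags: tuple[bool, bool],
    matrix: ScoringMatrix,
    cutoffs: dict[str, ZoneCutoffs],
    compound: str = "",
    concentration_um: float = 0.0,
    significance_gate: bool = False,
    significance_alpha: float = 0.05,
) -> HazardResult:
    """Total weighted score and hazard label for one compound/concentration.

    ``effects`` maps each continuous key parameter to its EffectSize (or a
    bare dd% float); ``flags`` is (firing_cessation, network_cessation).
    With ``significance_gate`` enabled, a parameter only contributes points
    when its rank-sum p-value is below ``significance_alpha``.
    """
    zones: dict[str, str] = {}
    points: dict[str, int] = {}
    annotations: dict[str, str] = {}
    for param in KEY_PARAMETERS:
        if param not in effects:
            raise ValidationError(
                f"missing key parameter {param!r} in effects for {compound!r}"
            )
        if param not in cutoffs:
            raise ValidationError(
                f"no calibrated cutoffs for parameter {param!r}"
            )
        eff = effects[param]
        if isinstance(eff, EffectSize):
            dd = eff.dd_pct
            p_value = eff.p_value
        else:
            dd = float(eff)
            p_value = math.nan
        zone, note = assign_zone(dd, cutoffs[param])
        if note:
            annotations[param] = note
        pts = matrix.points[param][zone]
        if (
            significance_gate
            and zone != "no_effect"
            and not math.isnan(p_value)
            and p_value >= significance_alpha
        ):
            pts = 0
            annotations[param] = "not significant"
        zones[param] = zone
        points[param] = pts

    fs, ns = flags
    total = sum(points.values())
    total += matrix.fs_points if fs else 0
    total += matrix.ns_points if ns else 0
    label = matrix.label_for(total)
    return HazardResult(
        compound=compound,
        concentration_um=concentration_um,
        zones=zones,
        points=points,
        firing_cessation=bool(fs),
        network_cessation=bool(ns),
        total_score=total,
        label=label,
        color=HAZARD_COLORS[label],
        annotations=annotations,
    )


def score_concentration_series(
    results: list[HazardResult], fcmax_um: float | None = None
) -> list[HazardResult]:
    """Order results by concentration; attach fold-over-fCmax when known."""
    if not results:
        raise ValidationError("empty concentration series")
    ordered = sorted(results, key=lambda r: r.concentration_um)
    if fcmax_um is not None:
        if fcmax_um <= 0:
            raise ValidationError("fcmax_um must be positive")
        for r in ordered:
            r.fold_fcmax = r.concentration_um / fcmax_um
    return ordered
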