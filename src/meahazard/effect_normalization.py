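"""Baseline-corrected, vehicle-normalized effect sizes per condition.

Each well serves as its own control: every parameter is first expressed as
the percent change from the well's baseline phase, then normalized to the
same-plate vehicle wells (by subtracting the vehicle mean percent change,
giving the dd% = vehicle-normalized delta-delta percent change; division by
the vehicle mean is available as a config option).  Conditions are compared
to vehicle with the exact two-sided Wilcoxon-Mann-Whitney rank-sum test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import PlateMap, ScoringConfig, ValidationError
from .spike_features import PARAMETER_PANEL, WellFeatures, cessation_flags

logger = logging.getLogger(__name__)

#: Combined sample size up to which the exact rank-sum null is enumerated.
EXACT_RANKSUM_MAX_N = 20


@dataclass(frozen=True)
class EffectSize:
    compound: str
    concentration_um: float
    parameter: str
    dd_pct: float
    sem: float
    n_wells: int
    p_value: float  # NaN when not testable

    def __post_init__(self) -> None:
        if self.n_wells < 1:
            raise ValidationError("n_wells must be >= 1")
        if not math.isnan(self.sem) and self.sem < 0:
            raise ValidationError("sem must be non-negative")


def baseline_pct_change(
    baseline: WellFeatures, treated: WellFeatures, parameter: str
) -> float:
    """100 x (treated - baseline)/|baseline| for one parameter.

    NaN when the baseline value is missing or zero (logged).
    """
    b = baseline.value(parameter)
    t = treated.value(parameter)
    if math.isnan(b) or math.isnan(t):
        return math.nan
    if b == 0:
        logger.info(
            "well %s parameter %s: baseline is 0, percent change undefined",
            baseline.well_id,
            parameter,
        )
        return math.nan
    return 100.0 * (t - b) / abs(b)


def vehicle_normalize(
    well_changes: np.ndarray | list[float],
    vehicle_changes: np.ndarray | list[float],
    mode: str = "subtract",
) -> np.ndarray:
    """dd% = per-well percent change normalized to the vehicle mean change.

    ``subtract`` (default): change - mean(vehicle changes); the vehicle wells'
    own mean dd% is 0 by construction.  ``divide``: 100 x (change - m)/|m|.
    """
    wc = np.asarray(well_changes, dtype=float)
    vc = np.asarray(vehicle_changes, dtype=float)
    vc = vc[~np.isnan(vc)]
    if vc.size == 0:
        raise ValidationError("no QC-passing vehicle wells to normalize against")
    m = vc.mean()
    if mode == "subtract":
        return wc - m
    if mode == "divide":
        if m == 0:
            raise ValidationError("vehicle mean change is 0; cannot divide")
        return 100.0 * (wc - m) / abs(m)
    raise ValidationError(f"unknown normalization mode {mode!r}")


def rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon-Mann-Whitney p-value, exact for small samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        return math.nan
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if x.size + y.size <= EXACT_RANKSUM_MAX_N and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def aggregate_condition(
    dd: np.ndarray | list[float],
    vehicle_dd: np.ndarray | list[float],
    compound: str,
    concentration_um: float,
    parameter: str,
) -> EffectSize:
    """Mean +/- SEM of per-well dd% with the rank-sum p-value vs vehicle."""
    dd = np.asarray(dd, dtype=float)
    dd = dd[~np.isnan(dd)]
    if dd.size == 0:
        raise ValidationError(
            f"{compound} @ {concentration_um}: no wells with a value for {parameter}"
        )
    sem = float(stats.sem(dd, ddof=1)) if dd.size > 1 else 0.0
    return EffectSize(
        compound=compound,
        concentration_um=concentration_um,
        parameter=parameter,
        dd_pct=float(dd.mean()),
        sem=sem,
        n_wells=int(dd.size),
        p_value=rank_sum_p(dd, np.asarray(vehicle_dd, dtype=float)),
    )


# ---------------------------------------------------------------------------
# plate-level driver
# ---------------------------------------------------------------------------


def well_changes_table(
    features: dict[tuple[str, str], WellFeatures],
    pmap: PlateMap,
    cfg: ScoringConfig,
) -> pd.DataFrame:
    """Per-well percent changes (and cessation flags) for one plate.

    ``features`` maps (well_id, phase) -> WellFeatures.  Wells whose baseline
    fails QC are excluded; wells silenced only after treatment are retained
    (their silencing is the signal behind the FS/NS flags).
    """
    rows = []
    for well_id, assignment in sorted(pmap.wells.items()):
        base = features.get((well_id, "baseline"))
        treat = features.get((well_id, "treated"))
        if base is None or treat is None:
            continue
        if not base.qc_pass:
            logger.info("well %s: baseline fails QC, excluded", well_id)
            continue
        fs, ns = cessation_flags(base, treat, cfg)
        row = {
            "well": well_id,
            "role": assignment.role,
            "compound": assignment.compound,
            "concentration_uM": assignment.concentration_um,
            "firing_cessation": fs,
            "network_cessation": ns,
        }
        for param in PARAMETER_PANEL:
            row[param] = baseline_pct_change(base, treat, param)
        rows.append(row)
    return pd.DataFrame(rows)


def normalize_plate(changes: pd.DataFrame, cfg: ScoringConfig) -> pd.DataFrame:
    """Replace percent changes with vehicle-normalized dd% values."""
    vehicle = changes[changes["role"] == "vehicle"]
    if vehicle.empty:
        raise ValidationError("plate has no QC-passing vehicle wells")
    out = changes.copy()
    for param in PARAMETER_PANEL:
        if param not in changes.columns:
            continue
        vc = vehicle[param].to_numpy()
        if np.all(np.isnan(vc)):
            continue
        out[param] = vehicle_normalize(
            changes[param].to_numpy(), vc, mode=cfg.vehicle_norm
        )
    return out


def condition_effects(
    dd_table: pd.DataFrame, cfg: ScoringConfig
) -> list[EffectSize]:
    """Aggregate a plate's dd% table into per-condition effect sizes."""
    vehicle = dd_table[dd_table["role"] == "vehicle"]
    effects: list[EffectSize] = []
    test_rows = dd_table[dd_table["role"] != "vehicle"]
    for (compound, conc), group in test_rows.groupby(
        ["compound", "concentration_uM"], sort=True
    ):
        for param in PARAMETER_PANEL:
            vals = group[param].to_numpy()
            if np.all(np.isnan(vals)):
                continue
            effects.append(
                aggregate_condition(
                    vals,
                    vehicle[param].to_numpy(),
                    compound=compound,
                    concentration_um=float(conc),
                    parameter=param,
                )
            )
    return effects


def effects_to_frame(effects: list[EffectSize]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "compound": e.compound,
                "concentration_uM": e.concentration_um,
                "parameter": e.parameter,
                "dd_pct": e.dd_pct,
                "sem": e.sem,
                "n_wells": e.n_wells,
                "p_value": e.p_value,
            }
            for e in effects
        ]
    )


def condition_flags(dd_table: pd.DataFrame) -> pd.DataFrame:
    """Majority-vote FS/NS flags per condition from per-well flags."""
    rows = []
    test_rows = dd_table[dd_table["role"] != "vehicle"]
    for (compound, conc), group in test_rows.groupby(
        ["compound", "concentration_uM"], sort=True
    ):
        rows.append(
            {
                "compound": compound,
                "concentration_uM": float(conc),
                "firing_cessation": bool(
                    group["firing_cessation"].mean() > 0.5
                ),
                "network_cessation": bool(
                    group["network_cessation"].mean() > 0.5
                ),
            }
        )
    return pd.DataFrame(rows)
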