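"""In-process orchestration shared by the CLI, tests and reports."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import effect_normalization as en
from . import hazard_scoring as hs
from . import spike_features as sf
from .cutoff_calibration import ZoneCutoffs, derive_cutoffs
from .io_formats import KEY_PARAMETERS, PlateMap, ScoringConfig, WellRecording


def compute_plate_features(
    recordings: list[WellRecording], cfg: ScoringConfig
) -> dict[tuple[str, str], sf.WellFeatures]:
    return {
        (rec.well_id, rec.phase): sf.compute_features(rec, cfg)
        for rec in recordings
    }


def features_frame(
    features: dict[tuple[str, str], sf.WellFeatures]
) -> pd.DataFrame:
    rows = [sf.features_to_row(f) for _, f in sorted(features.items())]
    return pd.DataFrame(rows)


def plate_dd_table(
    features: dict[tuple[str, str], sf.WellFeatures],
    pmap: PlateMap,
    cfg: ScoringConfig,
) -> pd.DataFrame:
    changes = en.well_changes_table(features, pmap, cfg)
    return en.normalize_plate(changes, cfg)


def calibration_samples(
    dd_table: pd.DataFrame,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Pooled per-well vehicle / positive-control dd% per key parameter."""
    veh = dd_table[dd_table["role"] == "vehicle"]
    pos = dd_table[dd_table["role"] == "positive_control"]
    veh_by = {p: veh[p].to_numpy() for p in KEY_PARAMETERS}
    pos_by = {p: pos[p].to_numpy() for p in KEY_PARAMETERS}
    return veh_by, pos_by


def calibrate_cutoffs(
    dd_tables: list[pd.DataFrame], cfg: ScoringConfig
) -> dict[str, ZoneCutoffs]:
    """Derive per-parameter zone cutoffs from one or more plates (pooled)."""
    pooled = pd.concat(dd_tables, ignore_index=True)
    veh_by, pos_by = calibration_samples(pooled)
    return derive_cutoffs(veh_by, pos_by, cfg)


def score_plate(
    dd_table: pd.DataFrame,
    cfg: ScoringConfig,
    cutoffs: dict[str, ZoneCutoffs],
) -> list[hs.HazardResult]:
    """Hazard results for every non-vehicle condition of a dd% table."""
    effects = en.condition_effects(dd_table, cfg)
    flags = en.condition_flags(dd_table)
    by_cond: dict[tuple[str, float], dict] = {}
    for eff in effects:
        by_cond.setdefault((eff.compound, eff.concentration_um), {})[
            eff.parameter
        ] = eff
    results = []
    for _, row in flags.iterrows():
        key = (row["compound"], float(row["concentration_uM"]))
        cond_effects = by_cond.get(key, {})
        for param in KEY_PARAMETERS:
            cond_effects.setdefault(param, float("nan"))
        results.append(
            hs.score_condition(
                cond_effects,
                (bool(row["firing_cessation"]), bool(row["network_cessation"])),
                cfg.matrix,
                cutoffs,
                compound=key[0],
                concentration_um=key[1],
                significance_gate=cfg.significance_gate,
                significance_alpha=cfg.significance_alpha,
            )
        )
    return results
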