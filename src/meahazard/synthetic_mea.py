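"""Seeded synthetic MEA plates: vehicle variability plus drug-effect profiles.

Each well is background Poisson firing per electrode plus a common
network-burst driver: burst events occur at plate-free Poisson times and
every participating electrode emits a packet of spikes at the event time
plus Gaussian jitter.  Treated phases apply an :class:`EffectProfile`
(rate/burst-duration multipliers, jitter change, network decoupling, full
silencing, ISI regularization); vehicle wells get an independent draw of the
per-well lognormal rate factor, so vehicle dd% distributions are
non-degenerate for tolerance-interval calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .io_formats import (
    PlateMap,
    SpikeTrain,
    ValidationError,
    WellAssignment,
    WellRecording,
)

VEHICLE_PROFILE_NAME = "vehicle"


@dataclass(frozen=True)
class EffectProfile:
    rate_multiplier: float = 1.0
    burst_duration_multiplier: float = 1.0
    burst_rate_multiplier: float = 1.0
    packet_size_multiplier: float = 1.0  # scales spikes per burst packet
    synchrony_jitter_ms: float | None = None  # None: keep design jitter
    decouple_network: bool = False
    silence: bool = False
    isi_regularization: float = 0.0  # 0 = Poisson, 1 = perfectly regular

    def __post_init__(self) -> None:
        if self.rate_multiplier <= 0 or self.burst_duration_multiplier <= 0:
            raise ValidationError("multipliers must be positive")
        if not 0.0 <= self.isi_regularization <= 1.0:
            raise ValidationError("isi_regularization must be in [0, 1]")


VEHICLE = EffectProfile()

#: A few canonical profiles used by tests and the simulate subcommand.
#: ``rate_multiplier`` scales the whole well activity (background rate and
#: network-burst event rate together).
PROFILES = {
    "vehicle": VEHICLE,
    "strong_excitatory": EffectProfile(
        rate_multiplier=2.5,
        burst_duration_multiplier=2.0,
        synchrony_jitter_ms=2.0,
    ),
    "strong_inhibitory": EffectProfile(
        rate_multiplier=0.15,
        burst_duration_multiplier=0.5,
        synchrony_jitter_ms=20.0,
    ),
    # mild profiles scale background and packet size together while the
    # event rate is compensated, so only the firing rate moves
    "mild_inhibitory": EffectProfile(
        rate_multiplier=0.55,
        burst_rate_multiplier=1.0 / 0.55,
        packet_size_multiplier=0.55,
    ),
    "mild_excitatory": EffectProfile(
        rate_multiplier=1.5,
        burst_rate_multiplier=1.0 / 1.5,
        packet_size_multiplier=1.5,
    ),
    "silencing": EffectProfile(silence=True),
    "decoupling": EffectProfile(decouple_network=True),
}


@dataclass
class Condition:
    compound: str
    concentration_um: float
    profile: EffectProfile
    n_wells: int = 8
    role: str = "test"

    def __post_init__(self) -> None:
        if not 1 <= self.n_wells:
            raise ValidationError("n_wells must be >= 1")


@dataclass
class SimulationDesign:
    n_wells: int = 48
    electrodes_per_well: int = 16
    duration_s: float = 1800.0
    background_rate_hz: float = 1.0
    network_burst_rate_hz: float = 0.15
    burst_spikes: int = 12
    burst_duration_s: float = 0.15
    participation_p: float = 0.9
    synchrony_jitter_ms: float = 5.0
    well_noise_sd: float = 0.10  # sd of the per-well lognormal rate factor
    burst_interval_cv: float = 0.2  # network bursts are quasi-periodic
    n_vehicle_wells: int = 8
    conditions: list[Condition] = field(default_factory=list)
    seed: int = 0
    plate_id: str = "simplate"

    def __post_init__(self) -> None:
        if self.background_rate_hz < 0 or self.network_burst_rate_hz < 0:
            raise ValidationError("rates must be >= 0")
        used = self.n_vehicle_wells + sum(c.n_wells for c in self.conditions)
        if used > self.n_wells:
            raise ValidationError(
                f"design uses {used} wells but the plate has {self.n_wells}"
            )


def default_design(seed: int = 0, **overrides) -> SimulationDesign:
    """48-well default: 8 vehicle wells + 5 canonical profiles x 8 wells."""
    conditions = [
        Condition("excitotoxin", 10.0, PROFILES["strong_excitatory"]),
        Condition("depressant", 10.0, PROFILES["strong_inhibitory"]),
        Condition("mild_depressant", 1.0, PROFILES["mild_inhibitory"]),
        Condition("silencer", 10.0, PROFILES["silencing"]),
        Condition("decoupler", 10.0, PROFILES["decoupling"]),
    ]
    return SimulationDesign(seed=seed, conditions=conditions, **overrides)


def _well_names(n: int) -> list[str]:
    rows = "ABCDEFGH"
    cols = (n + 7) // 8
    names = [f"{r}{c + 1}" for r in rows for c in range(8)]
    return names[:n]


def _regularize(isis: np.ndarray, r: float) -> np.ndarray:
    if r <= 0 or isis.size == 0:
        return isis
    return (1.0 - r) * isis + r * isis.mean()


def _event_times(
    rng: np.random.Generator, rate_hz: float, duration_s: float, cv: float
) -> np.ndarray:
    """Quasi-periodic event times: mean interval 1/rate, lognormal jitter."""
    if rate_hz <= 0:
        return np.empty(0)
    mean_iv = 1.0 / rate_hz
    n_max = int(rate_hz * duration_s * 2) + 10
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    ivs = mean_iv * rng.lognormal(-0.5 * sigma * sigma, sigma, size=n_max)
    t = rng.uniform(0.0, mean_iv) + np.cumsum(ivs)
    return t[t < duration_s]


def _poisson_train(
    rng: np.random.Generator, rate_hz: float, duration_s: float, regularize: float
) -> np.ndarray:
    if rate_hz <= 0:
        return np.empty(0)
    n = rng.poisson(rate_hz * duration_s)
    if n == 0:
        return np.empty(0)
    if regularize > 0:
        isis = rng.exponential(1.0 / rate_hz, size=n)
        t = np.cumsum(_regularize(isis, regularize))
        return t[t < duration_s]
    return np.sort(rng.uniform(0.0, duration_s, size=n))


def simulate_well(
    design: SimulationDesign,
    profile: EffectProfile,
    well_id: str,
    phase: str,
    seed_seq: np.random.SeedSequence,
) -> WellRecording:
    """One well, one phase.  Deterministic in ``seed_seq``."""
    rng = np.random.default_rng(seed_seq)
    dur = design.duration_s
    if phase == "baseline":
        profile = VEHICLE

    # the well-activity factor scales background and network rates together,
    # so vehicle variability moves WMFR without distorting synchrony
    well_factor = float(
        np.exp(rng.normal(0.0, design.well_noise_sd))
    )
    if profile.silence:
        bg_rate = 0.0
        nb_rate = 0.0
    else:
        bg_rate = design.background_rate_hz * well_factor * profile.rate_multiplier
        nb_rate = (
            design.network_burst_rate_hz
            * well_factor
            * profile.rate_multiplier
            * profile.burst_rate_multiplier
        )
    jitter_s = (
        design.synchrony_jitter_ms
        if profile.synchrony_jitter_ms is None
        else profile.synchrony_jitter_ms
    ) / 1000.0
    burst_dur = design.burst_duration_s * profile.burst_duration_multiplier
    packet_n = max(2, int(round(design.burst_spikes * profile.packet_size_multiplier)))

    # common quasi-periodic network-burst event times (shared driver)
    event_times = _event_times(rng, nb_rate, dur, design.burst_interval_cv)

    trains = {}
    for e in range(design.electrodes_per_well):
        eid = f"e{e + 1:02d}"
        spikes = [_poisson_train(rng, bg_rate, dur, profile.isi_regularization)]
        if profile.decouple_network:
            # same burst statistics, but private event times per electrode
            my_events = _event_times(
                rng, nb_rate, dur, design.burst_interval_cv
            )
        else:
            my_events = event_times[
                rng.random(event_times.size) < design.participation_p
            ]
        for t0 in my_events:
            start = t0 + rng.normal(0.0, jitter_s)
            packet = start + np.sort(
                rng.uniform(0.0, burst_dur, size=packet_n)
            )
            spikes.append(packet)
        t = np.concatenate(spikes)
        t = t[(t >= 0.0) & (t < dur)]
        t = np.unique(t)
        trains[eid] = SpikeTrain(eid, t)

    return WellRecording(
        well_id=well_id,
        phase=phase,
        trains=trains,
        duration_s=dur,
        plate_id=design.plate_id,
        n_electrodes=design.electrodes_per_well,
    )


def simulate_plate(
    design: SimulationDesign,
) -> tuple[list[WellRecording], PlateMap]:
    """Baseline and treated recordings for every well, plus the plate map.

    Randomness flows from ``design.seed`` via named substreams per
    (well, phase), so identical designs give bit-identical plates.
    """
    names = _well_names(design.n_wells)
    assignments: dict[str, WellAssignment] = {}
    profiles: dict[str, EffectProfile] = {}
    i = 0
    for _ in range(design.n_vehicle_wells):
        assignments[names[i]] = WellAssignment(role="vehicle", replicate_group="vehicle")
        profiles[names[i]] = VEHICLE
        i += 1
    for cond in design.conditions:
        for _ in range(cond.n_wells):
            assignments[names[i]] = WellAssignment(
                role=cond.role,
                compound=cond.compound,
                concentration_um=cond.concentration_um,
                replicate_group=f"{cond.compound}@{cond.concentration_um}",
            )
            profiles[names[i]] = cond.profile
            i += 1
    while i < design.n_wells:
        assignments[names[i]] = WellAssignment(role="vehicle", replicate_group="vehicle")
        profiles[names[i]] = VEHICLE
        i += 1

    root = np.random.SeedSequence(design.seed)
    children = root.spawn(2 * design.n_wells)
    recordings = []
    for w, well_id in enumerate(names):
        for p, phase in enumerate(("baseline", "treated")):
            recordings.append(
                simulate_well(
                    design,
                    profiles[well_id],
                    well_id,
                    phase,
                    children[2 * w + p],
                )
            )
    return recordings, PlateMap(assignments)


def positive_control_design(seed: int = 0, **overrides) -> SimulationDesign:
    """Calibration plate: vehicle wells plus a strong inhibitory positive
    control (the canonical direction for seizure-liability controls)."""
    base = default_design(seed=seed, **overrides)
    return replace(
        base,
        conditions=[
            Condition(
                "positive_control",
                10.0,
                PROFILES["strong_inhibitory"],
                n_wells=base.n_wells - base.n_vehicle_wells,
                role="positive_control",
            )
        ],
    )
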