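"""Per-well electrophysiology parameters from spike trains.

Implements the four continuous key parameters — weighted mean firing rate,
mean burst duration (Poisson-Surprise bursts), area under cross-correlation
and median/mean inter-spike interval — the two binary cessation flags, and
an extended 43-name parameter panel, together with electrode/well QC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .io_formats import ScoringConfig, SpikeTrain, ValidationError, WellRecording

__all__ = [
    "BurstEvent",
    "NetworkBurstEvent",
    "WellFeatures",
    "PARAMETER_PANEL",
    "active_electrodes",
    "well_qc",
    "weighted_mean_firing_rate",
    "detect_bursts",
    "mean_burst_duration",
    "median_over_mean_isi",
    "area_under_cross_correlation",
    "network_bursts",
    "cessation_flags",
    "compute_features",
    "features_to_row",
]

#: Fixed names of the extended per-well parameter panel (43 names, the four
#: continuous key parameters first).  The selection machinery operates on
#: this space.
PARAMETER_PANEL = (
    "wmfr_hz",
    "mean_burst_duration_s",
    "aucc",
    "median_over_mean_isi",
    "n_spikes_total",
    "n_active_electrodes",
    "active_electrode_fraction",
    "mean_firing_rate_hz",
    "firing_rate_cv",
    "max_electrode_rate_hz",
    "electrode_rate_iqr_hz",
    "spike_count_skewness",
    "isi_mean_s",
    "isi_median_s",
    "isi_cv",
    "isi_skewness",
    "n_bursts",
    "burst_rate_per_min",
    "bursting_electrode_fraction",
    "mean_spikes_per_burst",
    "spikes_per_burst_cv",
    "median_burst_duration_s",
    "burst_duration_cv",
    "pct_spikes_in_bursts",
    "mean_burst_surprise",
    "intra_burst_rate_hz",
    "mean_isi_within_bursts_s",
    "mean_isi_outside_bursts_s",
    "inter_burst_interval_mean_s",
    "inter_burst_interval_cv",
    "burst_rate_cv",
    "n_network_bursts",
    "network_burst_rate_per_min",
    "mean_network_burst_duration_s",
    "network_burst_duration_cv",
    "mean_network_burst_participation",
    "network_burst_size_mean",
    "network_burst_size_cv",
    "pct_spikes_in_network_bursts",
    "network_ibi_mean_s",
    "network_ibi_cv",
    "zero_lag_sync",
    "cross_correlation_peak",
)

assert len(PARAMETER_PANEL) == 43


@dataclass(frozen=True)
class BurstEvent:
    electrode_id: str
    start_s: float
    end_s: float
    n_spikes: int
    surprise: float

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValidationError("burst must have start_s < end_s")
        if self.surprise < 0:
            raise ValidationError("surprise must be non-negative")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class NetworkBurstEvent:
    start_s: float
    end_s: float
    participating_electrodes: frozenset

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class WellFeatures:
    """The key parameters plus the extended panel for one well/phase."""

    well_id: str
    phase: str
    wmfr_hz: float
    mean_burst_duration_s: float  # NaN when no bursts
    aucc: float  # NaN when < 2 active electrodes
    median_over_mean_isi: float  # NaN when < 2 spikes on active electrodes
    n_active_electrodes: int
    qc_pass: bool
    firing_cessation: bool = False
    network_cessation: bool = False
    extended: dict[str, float] = field(default_factory=dict)

    def value(self, parameter: str) -> float:
        if parameter in self.extended:
            return self.extended[parameter]
        return getattr(self, parameter, math.nan)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def active_electrodes(
    rec: WellRecording, rate_threshold_hz: float = 0.1
) -> set[str]:
    """Electrodes with mean rate *strictly* above the threshold.

    An electrode at exactly the threshold rate is excluded.
    """
    if rec.duration_s <= 0:
        raise ValidationError("recording duration must be positive")
    return {
        eid
        for eid, train in rec.trains.items()
        if train.n_spikes / rec.duration_s > rate_threshold_hz
    }


def well_qc(rec: WellRecording, cfg: ScoringConfig) -> bool:
    """True iff strictly more than ``qc_active_fraction`` of the 16
    electrodes are active.  Absent electrodes count in the denominator."""
    n_active = len(active_electrodes(rec, cfg.qc_electrode_rate_hz))
    return n_active / rec.n_electrodes > cfg.qc_active_fraction


# ---------------------------------------------------------------------------
# firing-rate parameters
# ---------------------------------------------------------------------------


def weighted_mean_firing_rate(rec: WellRecording, active: set[str]) -> float:
    """Total spikes on active electrodes / (duration x n_active); 0 if none."""
    if not active:
        return 0.0
    total = sum(rec.trains[eid].n_spikes for eid in active if eid in rec.trains)
    return total / (rec.duration_s * len(active))


def median_over_mean_isi(train: SpikeTrain) -> float:
    """median(ISI)/mean(ISI); NaN for trains with fewer than 2 spikes.

    Equals 1 for perfectly regular trains and ln 2 in the limit for
    exponential (Poisson) ISIs.
    """
    if train.n_spikes < 2:
        return math.nan
    isis = np.diff(train.timestamps)
    return float(np.median(isis) / np.mean(isis))


# ---------------------------------------------------------------------------
# Poisson Surprise burst detection
# ---------------------------------------------------------------------------


def _log10_poisson_sf(n: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """log10 P(Poisson(mu) >= n), stable for deeply improbable windows.

    P(N >= n) equals the regularized lower incomplete gamma P(n, mu); where
    that underflows we switch to the leading-term expansion
    ln P ~= n ln mu - mu - ln n! + ln(sum_j prod_k mu/(n+k)).
    """
    n = np.asarray(n, dtype=float)
    mu = np.asarray(mu, dtype=float)
    p = special.gammainc(n, mu)
    out = np.full(np.broadcast(n, mu).shape, -np.inf)
    ok = p > 1e-290
    np.log10(p, where=ok, out=out)
    small = ~ok & (mu > 0)
    if np.any(small):
        ns, mus = np.broadcast_arrays(n, mu)
        ns, mus = ns[small], mus[small]
        # sum_{k>=n} mu^k e^-mu / k! = (mu^n e^-mu / n!) * sum_j prod mu/(n+1..n+j)
        ratio = np.ones_like(mus)
        acc = np.ones_like(mus)
        for j in range(1, 60):
            ratio = ratio * mus / (ns + j)
            acc += ratio
            if np.all(ratio < 1e-18):
                break
        ln_p = ns * np.log(mus) - mus - special.gammaln(ns + 1) + np.log(acc)
        out[small] = ln_p / math.log(10.0)
    return out


def surprise(n_spikes: int, window_s: float, rate_hz: float) -> float:
    """Poisson Surprise S = -log10 P(N >= n in window | Poisson rate)."""
    if window_s <= 0 or rate_hz <= 0:
        return math.inf if n_spikes > 0 else 0.0
    return float(-_log10_poisson_sf(np.array(n_spikes), np.array(rate_hz * window_s)))


def detect_bursts(
    train: SpikeTrain,
    duration_s: float,
    rate_hz: float | None = None,
    min_spikes: int = 3,
    surprise_threshold: float = 10.0,
    max_burst_spikes: int = 200,
) -> list[BurstEvent]:
    """Poisson-Surprise burst detection (Legendy & Salcman style).

    Every window of consecutive spikes (``min_spikes`` to ``max_burst_spikes``
    spikes) is scored by S = -log10 P(N >= n in its span | Poisson at the
    train's mean rate).  Maximal non-overlapping windows with S >= threshold
    are reported greedily by decreasing S; ties resolve to the earliest,
    then shortest window.  On short trains this is an exhaustive maximizer.
    """
    t = train.timestamps
    n = t.size
    if n < min_spikes:
        return []
    if rate_hz is None:
        rate_hz = n / duration_s
    if rate_hz <= 0:
        return []

    kmax = min(max_burst_spikes, n) - 1  # window of k+1 spikes
    ks = np.arange(min_spikes - 1, kmax + 1)
    if ks.size == 0:
        return []
    # S[a, j] for window starting at spike a spanning ks[j] extra spikes
    n_starts = n - ks[0]
    starts_col = np.arange(n_starts)[:, None]
    idx = starts_col + ks[None, :]
    valid = idx < n
    span = np.where(valid, t[np.minimum(idx, n - 1)] - t[starts_col], np.inf)
    mu = rate_hz * span
    # windows with S < threshold can never be selected: skip their S outright
    mu_max = special.gammaincinv(ks + 1.0, 10.0 ** (-surprise_threshold))
    cand = valid & (mu <= mu_max[None, :])
    S = np.full(span.shape, -np.inf)
    nwin = np.broadcast_to(ks[None, :] + 1.0, span.shape)
    S[cand] = -_log10_poisson_sf(nwin[cand], mu[cand])

    bursts: list[BurstEvent] = []
    while True:
        flat = int(np.argmax(S))  # row-major: ties -> smallest start, then k
        a, j = divmod(flat, ks.size)
        s_best = S[a, j]
        if not np.isfinite(s_best) or s_best < surprise_threshold:
            break
        k = int(ks[j])
        b = a + k
        bursts.append(
            BurstEvent(
                electrode_id=train.electrode_id,
                start_s=float(t[a]),
                end_s=float(t[b]),
                n_spikes=k + 1,
                surprise=float(s_best),
            )
        )
        # invalidate every window sharing a spike with [a, b]
        starts = np.arange(n_starts)
        overlap = (starts[:, None] <= b) & (starts[:, None] + ks[None, :] >= a)
        S[overlap] = -np.inf
    bursts.sort(key=lambda ev: ev.start_s)
    return bursts


def mean_burst_duration(bursts: list[BurstEvent]) -> float:
    """Arithmetic mean of burst durations; NaN when there are no bursts."""
    if not bursts:
        return math.nan
    return float(np.mean([b.duration_s for b in bursts]))


# ---------------------------------------------------------------------------
# cross-correlation synchrony
# ---------------------------------------------------------------------------


def _pair_correlogram(
    t1: np.ndarray,
    t2: np.ndarray,
    duration_s: float,
    bin_s: float,
    max_lag_s: float,
) -> tuple[np.ndarray, float]:
    """Normalized cross-correlogram counts per bin and the chance level.

    Counts of time differences t2 - t1 in bins over [-max_lag, +max_lag],
    divided by the per-bin chance level n1*n2*bin/T so that independent
    trains give ~1 per bin.
    """
    nbins = int(round(2 * max_lag_s / bin_s))
    edges = -max_lag_s + bin_s * np.arange(nbins + 1)
    lo = np.searchsorted(t2, t1 - max_lag_s, side="left")
    hi = np.searchsorted(t2, t1 + max_lag_s, side="right")
    counts_per = hi - lo
    m = int(counts_per.sum())
    if m:
        offsets = np.repeat(np.cumsum(counts_per) - counts_per, counts_per)
        flat = np.repeat(lo, counts_per) + (np.arange(m) - offsets)
        diffs = t2[flat] - np.repeat(t1, counts_per)
    else:
        diffs = np.empty(0)
    counts, _ = np.histogram(diffs, bins=edges)
    chance = t1.size * t2.size * bin_s / duration_s
    return counts.astype(float), chance


def area_under_cross_correlation(
    rec: WellRecording,
    active: set[str] | None = None,
    bin_s: float = 0.005,
    max_lag_s: float = 0.100,
    rate_threshold_hz: float = 0.1,
    _extras: dict | None = None,
) -> float:
    """Mean over active-electrode pairs of the correlogram area above chance.

    Per pair, area = sum_bins (count/chance - 1) * bin width; the mean over
    pairs is clipped at 0.  NaN with fewer than 2 active electrodes.
    """
    if active is None:
        active = active_electrodes(rec, rate_threshold_hz)
    ids = sorted(active)
    if len(ids) < 2:
        return math.nan
    areas = []
    zero_lag = []
    peaks = []
    nbins = int(round(2 * max_lag_s / bin_s))
    mid = nbins // 2
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            t1 = rec.trains[ids[i]].timestamps
            t2 = rec.trains[ids[j]].timestamps
            counts, chance = _pair_correlogram(
                t1, t2, rec.duration_s, bin_s, max_lag_s
            )
            if chance <= 0:
                continue
            norm = counts / chance
            areas.append(float(np.sum(norm - 1.0) * bin_s))
            # mean of the two central bins: symmetric in electrode order
            zero_lag.append(float(0.5 * (norm[mid - 1] + norm[mid])))
            peaks.append(float(norm.max()))
    if not areas:
        return math.nan
    if _extras is not None:
        _extras["zero_lag_sync"] = float(np.mean(zero_lag))
        _extras["cross_correlation_peak"] = float(np.mean(peaks))
    return max(0.0, float(np.mean(areas)))


# ---------------------------------------------------------------------------
# network bursts & cessation
# ---------------------------------------------------------------------------


def network_bursts(
    bursts_by_electrode: dict[str, list[BurstEvent]],
    n_active: int,
    participation_fraction: float = 0.5,
    merge_gap_s: float = 0.100,
) -> list[NetworkBurstEvent]:
    """Intervals where >= participation_fraction of active electrodes burst
    concurrently; adjacent intervals closer than ``merge_gap_s`` merge."""
    if n_active <= 0:
        return []
    events = []  # (time, +1/-1, electrode)
    for eid, bursts in bursts_by_electrode.items():
        for b in bursts:
            events.append((b.start_s, 1, eid))
            events.append((b.end_s, -1, eid))
    if not events:
        return []
    events.sort(key=lambda e: (e[0], -e[1]))  # starts before ends at ties
    need = participation_fraction * n_active
    count = 0
    open_start = None
    raw: list[tuple[float, float]] = []
    for time, delta, _ in events:
        count += delta
        if open_start is None and count >= need:
            open_start = time
        elif open_start is not None and count < need:
            raw.append((open_start, time))
            open_start = None
    if open_start is not None:
        raw.append((open_start, events[-1][0]))
    raw = [(s, e) for s, e in raw if e > s]
    if not raw:
        return []
    merged = [list(raw[0])]
    for s, e in raw[1:]:
        if s - merged[-1][1] < merge_gap_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    out = []
    for s, e in merged:
        participants = frozenset(
            eid
            for eid, bursts in bursts_by_electrode.items()
            if any(b.start_s < e and b.end_s > s for b in bursts)
        )
        out.append(NetworkBurstEvent(s, e, participants))
    return out


def cessation_flags(
    baseline: WellFeatures,
    treated: WellFeatures,
    cfg: ScoringConfig,
) -> tuple[bool, bool]:
    """(firing cessation, network cessation) of treated vs own baseline.

    FS: treated WMFR below ``fs_fraction`` of baseline WMFR, or the treated
    well no longer passes the active-well QC.  NS: network bursts present at
    baseline but absent after treatment.
    """
    if not baseline.qc_pass:
        raise ValidationError(
            f"well {baseline.well_id}: cessation flags require a QC-passing baseline"
        )
    fs = (
        treated.wmfr_hz < cfg.fs_fraction * baseline.wmfr_hz
        or treated.n_active_electrodes / 16 <= cfg.qc_active_fraction
    )
    nb_base = baseline.extended.get("n_network_bursts", 0)
    nb_treat = treated.extended.get("n_network_bursts", 0)
    ns = nb_base > 0 and nb_treat == 0
    return bool(fs), bool(ns)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def _cv(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.size < 2 or np.mean(x) == 0:
        return math.nan
    return float(np.std(x, ddof=1) / np.mean(x))


def _skew(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.size < 3 or np.std(x) == 0:
        return math.nan
    return float(stats.skew(x))


def compute_features(rec: WellRecording, cfg: ScoringConfig) -> WellFeatures:
    """Compute the full parameter panel for one recording.

    Parameters whose defining event set is empty come out as NaN.  The
    result is invariant under relabeling of electrode ids.
    """
    active = active_electrodes(rec, cfg.qc_electrode_rate_hz)
    n_active = len(active)
    qc = n_active / rec.n_electrodes > cfg.qc_active_fraction
    wmfr = weighted_mean_firing_rate(rec, active)

    active_ids = sorted(active)
    rates = np.array(
        [rec.trains[eid].n_spikes / rec.duration_s for eid in active_ids]
    )
    counts_all = np.array(
        [t.n_spikes for t in rec.trains.values()], dtype=float
    )
    total_spikes = float(counts_all.sum())
    active_spikes = float(
        sum(rec.trains[eid].n_spikes for eid in active_ids)
    )

    # per-electrode ISIs and median/mean ratio (mean over active electrodes)
    ratios, all_isis = [], []
    for eid in active_ids:
        train = rec.trains[eid]
        r = median_over_mean_isi(train)
        if not math.isnan(r):
            ratios.append(r)
        if train.n_spikes >= 2:
            all_isis.append(np.diff(train.timestamps))
    mom_isi = float(np.mean(ratios)) if ratios else math.nan
    isis = np.concatenate(all_isis) if all_isis else np.empty(0)

    # bursts on active electrodes
    bursts_by_el: dict[str, list[BurstEvent]] = {}
    for eid in active_ids:
        bursts_by_el[eid] = detect_bursts(
            rec.trains[eid],
            rec.duration_s,
            min_spikes=cfg.min_burst_spikes,
            surprise_threshold=cfg.surprise_threshold,
            max_burst_spikes=cfg.max_burst_spikes,
        )
    all_bursts = [b for bl in bursts_by_el.values() for b in bl]
    mbd = mean_burst_duration(all_bursts)

    extras: dict[str, float] = {}
    aucc = area_under_cross_correlation(
        rec,
        active,
        bin_s=cfg.aucc_bin_s,
        max_lag_s=cfg.aucc_max_lag_s,
        _extras=extras,
    )

    nbs = network_bursts(
        bursts_by_el,
        n_active,
        participation_fraction=cfg.nb_participation_fraction,
        merge_gap_s=cfg.nb_merge_gap_s,
    )

    ext: dict[str, float] = {
        "n_spikes_total": total_spikes,
        "n_active_electrodes": float(n_active),
        "active_electrode_fraction": n_active / rec.n_electrodes,
        "mean_firing_rate_hz": float(np.mean(rates)) if rates.size else 0.0,
        "firing_rate_cv": _cv(rates),
        "max_electrode_rate_hz": float(rates.max()) if rates.size else 0.0,
        "electrode_rate_iqr_hz": (
            float(np.subtract(*np.percentile(rates, [75, 25])))
            if rates.size
            else math.nan
        ),
        "spike_count_skewness": _skew(counts_all),
        "isi_mean_s": float(np.mean(isis)) if isis.size else math.nan,
        "isi_median_s": float(np.median(isis)) if isis.size else math.nan,
        "isi_cv": _cv(isis),
        "isi_skewness": _skew(isis),
        "zero_lag_sync": extras.get("zero_lag_sync", math.nan),
        "cross_correlation_peak": extras.get("cross_correlation_peak", math.nan),
    }

    # burst statistics
    ext["n_bursts"] = float(len(all_bursts))
    if all_bursts:
        durs = np.array([b.duration_s for b in all_bursts])
        sizes = np.array([b.n_spikes for b in all_bursts], dtype=float)
        in_burst = float(sizes.sum())
        per_el_rates = np.array(
            [len(bursts_by_el[eid]) / rec.duration_s * 60 for eid in active_ids]
        )
        ext.update(
            burst_rate_per_min=len(all_bursts)
            / max(n_active, 1)
            / rec.duration_s
            * 60.0,
            bursting_electrode_fraction=(
                sum(1 for eid in active_ids if bursts_by_el[eid]) / n_active
            ),
            mean_spikes_per_burst=float(sizes.mean()),
            spikes_per_burst_cv=_cv(sizes),
            median_burst_duration_s=float(np.median(durs)),
            burst_duration_cv=_cv(durs),
            pct_spikes_in_bursts=100.0 * in_burst / active_spikes
            if active_spikes
            else math.nan,
            mean_burst_surprise=float(
                np.mean([b.surprise for b in all_bursts])
            ),
            intra_burst_rate_hz=float(np.sum(sizes - 1) / np.sum(durs))
            if np.sum(durs) > 0
            else math.nan,
            burst_rate_cv=_cv(per_el_rates),
        )
        within, outside = [], []
        for eid in active_ids:
            t = rec.trains[eid].timestamps
            if t.size < 2:
                continue
            isi = np.diff(t)
            mask = np.zeros(isi.size, dtype=bool)
            for b in bursts_by_el[eid]:
                i0 = np.searchsorted(t, b.start_s)
                i1 = np.searchsorted(t, b.end_s, side="right") - 1
                mask[i0:i1] = True
            within.append(isi[mask])
            outside.append(isi[~mask])
        w = np.concatenate(within) if within else np.empty(0)
        o = np.concatenate(outside) if outside else np.empty(0)
        ext["mean_isi_within_bursts_s"] = float(w.mean()) if w.size else math.nan
        ext["mean_isi_outside_bursts_s"] = float(o.mean()) if o.size else math.nan
        ibis = []
        for eid in active_ids:
            bl = bursts_by_el[eid]
            if len(bl) >= 2:
                ibis.append(
                    np.array(
                        [bl[i + 1].start_s - bl[i].end_s for i in range(len(bl) - 1)]
                    )
                )
        ibi = np.concatenate(ibis) if ibis else np.empty(0)
        ext["inter_burst_interval_mean_s"] = (
            float(ibi.mean()) if ibi.size else math.nan
        )
        ext["inter_burst_interval_cv"] = _cv(ibi)
    else:
        for name in (
            "burst_rate_per_min",
            "bursting_electrode_fraction",
            "mean_spikes_per_burst",
            "spikes_per_burst_cv",
            "median_burst_duration_s",
            "burst_duration_cv",
            "pct_spikes_in_bursts",
            "mean_burst_surprise",
            "intra_burst_rate_hz",
            "mean_isi_within_bursts_s",
            "mean_isi_outside_bursts_s",
            "inter_burst_interval_mean_s",
            "inter_burst_interval_cv",
            "burst_rate_cv",
        ):
            ext[name] = math.nan

    ext["n_network_bursts"] = float(len(nbs))
    if nbs:
        ndurs = np.array([nb.duration_s for nb in nbs])
        nsizes = []
        spikes_in_nb = 0.0
        for nb in nbs:
            size = 0
            for eid in active_ids:
                t = rec.trains[eid].timestamps
                size += int(
                    np.searchsorted(t, nb.end_s, side="right")
                    - np.searchsorted(t, nb.start_s)
                )
            nsizes.append(float(size))
            spikes_in_nb += size
        nsizes = np.array(nsizes)
        ext.update(
            network_burst_rate_per_min=len(nbs) / rec.duration_s * 60.0,
            mean_network_burst_duration_s=float(ndurs.mean()),
            network_burst_duration_cv=_cv(ndurs),
            mean_network_burst_participation=float(
                np.mean(
                    [len(nb.participating_electrodes) / n_active for nb in nbs]
                )
            ),
            network_burst_size_mean=float(nsizes.mean()),
            network_burst_size_cv=_cv(nsizes),
            pct_spikes_in_network_bursts=100.0 * spikes_in_nb / active_spikes
            if active_spikes
            else math.nan,
        )
        if len(nbs) >= 2:
            nibi = np.array(
                [nbs[i + 1].start_s - nbs[i].end_s for i in range(len(nbs) - 1)]
            )
            ext["network_ibi_mean_s"] = float(nibi.mean())
            ext["network_ibi_cv"] = _cv(nibi)
        else:
            ext["network_ibi_mean_s"] = math.nan
            ext["network_ibi_cv"] = math.nan
    else:
        for name in (
            "network_burst_rate_per_min",
            "mean_network_burst_duration_s",
            "network_burst_duration_cv",
            "mean_network_burst_participation",
            "network_burst_size_mean",
            "network_burst_size_cv",
            "pct_spikes_in_network_bursts",
            "network_ibi_mean_s",
            "network_ibi_cv",
        ):
            ext[name] = math.nan

    ext["wmfr_hz"] = wmfr
    ext["mean_burst_duration_s"] = mbd
    ext["aucc"] = aucc
    ext["median_over_mean_isi"] = mom_isi

    return WellFeatures(
        well_id=rec.well_id,
        phase=rec.phase,
        wmfr_hz=wmfr,
        mean_burst_duration_s=mbd,
        aucc=aucc,
        median_over_mean_isi=mom_isi,
        n_active_electrodes=n_active,
        qc_pass=qc,
        extended=ext,
    )


def features_from_row(row: dict) -> WellFeatures:
    """Rebuild a WellFeatures from a feature-table row (inverse of
    :func:`features_to_row`)."""
    ext = {name: float(row[name]) for name in PARAMETER_PANEL if name in row}
    return WellFeatures(
        well_id=str(row["well"]),
        phase=str(row["phase"]),
        wmfr_hz=ext["wmfr_hz"],
        mean_burst_duration_s=ext["mean_burst_duration_s"],
        aucc=ext["aucc"],
        median_over_mean_isi=ext["median_over_mean_isi"],
        n_active_electrodes=int(ext["n_active_electrodes"]),
        qc_pass=bool(row["qc_pass"]),
        firing_cessation=bool(row.get("firing_cessation", False)),
        network_cessation=bool(row.get("network_cessation", False)),
        extended=ext,
    )


def features_to_row(feat: WellFeatures) -> dict:
    """Flatten a WellFeatures into a table row over the fixed panel."""
    row = {
        "well": feat.well_id,
        "phase": feat.phase,
        "qc_pass": feat.qc_pass,
        "firing_cessation": feat.firing_cessation,
        "network_cessation": feat.network_cessation,
    }
    for name in PARAMETER_PANEL:
        row[name] = feat.extended.get(name, math.nan)
    return row
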