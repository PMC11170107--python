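"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorized implementations: plain
Python loops and direct probability summation, so that agreement between
the two routes is meaningful.
"""

from __future__ import annotations

import math


def log10_poisson_tail(n: int, mu: float, terms: int = 2000) -> float:
    """log10 P(Poisson(mu) >= n) by direct log-space term summation."""
    if mu <= 0:
        return 0.0 if n <= 0 else -math.inf
    # terms k = n, n+1, ... in log space, summed via log-sum-exp
    logs = []
    for k in range(n, n + terms):
        lt = k * math.log(mu) - mu - math.lgamma(k + 1)
        logs.append(lt)
        if len(logs) > 5 and lt < logs[0] - 40:
            break
    m = max(logs)
    total = m + math.log(sum(math.exp(x - m) for x in logs))
    return total / math.log(10.0)


def surprise_of_window(timestamps, a: int, b: int, rate_hz: float) -> float:
    """-log10 P(N >= b-a+1 in the window's span | Poisson rate)."""
    span = timestamps[b] - timestamps[a]
    return -log10_poisson_tail(b - a + 1, rate_hz * span)


def brute_force_bursts(
    timestamps,
    duration_s: float,
    rate_hz: float | None = None,
    min_spikes: int = 3,
    surprise_threshold: float = 10.0,
) -> list[tuple[int, int, float]]:
    """Exhaustive maximal non-overlapping burst windows, greedy by surprise.

    Scores every window of >= min_spikes consecutive spikes; repeatedly
    accepts the highest-surprise window at or above the threshold (ties:
    earliest start, then shortest) and removes overlapping windows.
    Returns (start index, end index, surprise) triples sorted by start.
    """
    n = len(timestamps)
    if n < min_spikes:
        return []
    if rate_hz is None:
        rate_hz = n / duration_s
    windows = []
    for a in range(n):
        for b in range(a + min_spikes - 1, n):
            windows.append(
                (surprise_of_window(timestamps, a, b, rate_hz), a, b)
            )
    accepted: list[tuple[int, int, float]] = []
    alive = list(windows)
    while alive:
        best = max(alive, key=lambda w: (w[0], -w[1], w[1] - w[2]))
        s, a, b = best
        if s < surprise_threshold:
            break
        accepted.append((a, b, s))
        alive = [w for w in alive if w[2] < a or w[1] > b]
    return sorted(accepted)


def brute_force_wmfr(trains: dict, duration_s: float, threshold_hz: float) -> float:
    """count/(n*T) over electrodes strictly above the rate threshold."""
    active = [
        eid
        for eid, ts in trains.items()
        if len(ts) / duration_s > threshold_hz
    ]
    if not active:
        return 0.0
    total = sum(len(trains[eid]) for eid in active)
    return total / (duration_s * len(active))


def brute_force_median_over_mean(timestamps) -> float:
    if len(timestamps) < 2:
        return math.nan
    isis = sorted(
        timestamps[i + 1] - timestamps[i] for i in range(len(timestamps) - 1)
    )
    k = len(isis)
    med = (
        isis[k // 2]
        if k % 2
        else 0.5 * (isis[k // 2 - 1] + isis[k // 2])
    )
    return med / (sum(isis) / k)


def exact_rank_sum_two_sided(x, y) -> float:
    """Exact two-sided rank-sum p by complete enumeration of orderings."""
    from itertools import combinations

    pooled = sorted(list(x) + list(y))

    def rank_of(v):  # midrank, handles ties
        less = sum(1 for p in pooled if p < v)
        equal = sum(1 for p in pooled if p == v)
        return less + (equal + 1) / 2

    obs = sum(rank_of(v) for v in x)
    n = len(pooled)
    nx = len(x)
    mean = nx * (n + 1) / 2
    count = 0
    total = 0
    all_ranks = [rank_of(v) for v in pooled]
    for combo in combinations(range(n), nx):
        s = sum(all_ranks[i] for i in combo)
        total += 1
        if abs(s - mean) >= abs(obs - mean) - 1e-12:
            count += 1
    return count / total


def cohens_kappa_agreement(tp: int, fp: int, tn: int, fn: int) -> float:
    """Cohen's kappa from the agreement definition (po - pe)/(1 - pe)."""
    n = tp + fp + tn + fn
    po = (tp + tn) / n
    p_yes = ((tp + fp) / n) * ((tp + fn) / n)
    p_no = ((fn + tn) / n) * ((fp + tn) / n)
    pe = p_yes + p_no
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1.0 - pe)
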