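"""Peri-event time histograms and event-response statistics.

The analysis chain per unit and event type is:

1. ``compute_peth``: trial-averaged firing rate in uniform bins around the
   event.
2. ``zscore_peth``: Z-scoring against a pre-event baseline window.
3. ``test_event_response``: two-sided Mann-Whitney U test of per-trial
   baseline vs response window spike counts; the response direction
   (activated / inhibited) is the sign of the median rate difference when
   significant.
4. ``response_latency``: time of the Z-score extremum inside the response
   window.

Population-level utilities compare outcome conditions within units
(Wilcoxon signed-rank across units, excluding units with <5 trials in
either condition), tabulate the 27 possible (+/0/-) response combinations
over cue/reward/punishment, and compare responsive fractions between unit
groups with a 2x2 chi-square test (no continuity correction).

Window defaults (baseline [-0.5, 0) s, response [0, 0.5) s, latency window
[0, 0.6] s, 20 ms bins) fit inside the cue-to-reinforcement epoch and are
all configurable.  Windows are half-open ``[start, end)``.  No
multiple-comparison correction is applied across units when fractions are
reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from .exceptions import (DegenerateDataError, InsufficientDataError,
                         ParameterError)
from .session import SpikeTrain

EVENT_LABELS = ("cue", "cue_reward", "cue_punish", "reward", "punishment",
                "omission_virtual")

DEFAULT_ALPHA = 0.001
MIN_TRIALS_PER_CONDITION = 5


@dataclass
class Peth:
    """Trial-averaged peri-event time histogram."""

    bin_centers: np.ndarray   # seconds relative to the event
    rate: np.ndarray          # Hz per bin
    n_trials: int
    event_label: str = ""
    z: np.ndarray | None = None
    baseline_win: tuple[float, float] | None = None
    smoothing_sd_s: float = 0.0

    @property
    def bin_s(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0])


@dataclass
class ResponseResult:
    """Outcome of the per-unit event-response test."""

    unit_id: str
    event_label: str
    direction: str            # "activated" | "inhibited" | "none"
    p_value: float
    effect_hz: float          # mean response-window rate minus baseline rate
    latency_s: float | None = None

    @property
    def sign(self) -> int:
        return {"activated": 1, "inhibited": -1, "none": 0}[self.direction]


def counts_in_windows(times, events, window) -> np.ndarray:
    """Per-event spike counts in the half-open window ``[e+w0, e+w1)``."""
    t = np.asarray(times if not isinstance(times, SpikeTrain) else times.times, dtype=float)
    events = np.asarray(events, dtype=float)
    lo = np.searchsorted(t, events + window[0], side="left")
    hi = np.searchsorted(t, events + window[1], side="left")
    return (hi - lo).astype(float)


def compute_peth(spikes, events, window=(-1.0, 1.0), bin_s: float = 0.02,
                 event_label: str = "", smooth_sd_s: float = 0.0) -> Peth:
    """Trial-averaged firing rate around events.

    ``rate[b] = (spike count in bin b summed over trials) / (n_trials * bin_s)``
    so the rate integrates exactly to the mean per-trial in-window spike
    count.  Raises :class:`InsufficientDataError` without events.
    """
    events = np.asarray(events, dtype=float)
    if len(events) == 0:
        raise InsufficientDataError("PETH needs at least one event")
    if bin_s <= 0:
        raise ParameterError("bin_s must be positive")
    t = np.asarray(spikes.times if isinstance(spikes, SpikeTrain) else spikes, dtype=float)
    n_bins = int(round((window[1] - window[0]) / bin_s))
    edges = window[0] + np.arange(n_bins + 1) * bin_s
    counts = np.zeros(n_bins)
    for e in events:
        lo = np.searchsorted(t, e + window[0], side="left")
        hi = np.searchsorted(t, e + edges[-1], side="left")
        rel = t[lo:hi] - e
        idx = np.floor((rel - window[0]) / bin_s).astype(int)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        counts += np.bincount(idx, minlength=n_bins)
    rate = counts / (len(events) * bin_s)
    if smooth_sd_s > 0:
        rate = gaussian_filter1d(rate, sigma=smooth_sd_s / bin_s, mode="nearest")
    centers = edges[:-1] + bin_s / 2
    return Peth(bin_centers=centers, rate=rate, n_trials=len(events),
                event_label=event_label, smoothing_sd_s=smooth_sd_s)


def zscore_peth(peth: Peth, baseline=(-0.5, 0.0)) -> Peth:
    """Z-score a PETH against its own baseline window.

    Baseline bins have mean 0 and SD 1 after the transform by construction.
    A zero baseline SD raises :class:`DegenerateDataError` (callers flag the
    unit rather than crash a cohort run).
    """
    mask = (peth.bin_centers >= baseline[0]) & (peth.bin_centers < baseline[1])
    if not mask.any():
        raise ParameterError("baseline window contains no PETH bins")
    mu = float(peth.rate[mask].mean())
    sd = float(peth.rate[mask].std())
    if sd == 0:
        raise DegenerateDataError("zero baseline SD; unit cannot be Z-scored")
    return replace(peth, z=(peth.rate - mu) / sd, baseline_win=tuple(baseline))


def test_event_response(spikes, events,
                        baseline_win=(-0.5, 0.0), response_win=(0.0, 0.5),
                        alpha: float = DEFAULT_ALPHA,
                        event_label: str = "") -> ResponseResult:
    """Rank-sum test of per-trial baseline vs response window firing.

    Spike counts are converted to rates so the two windows may differ in
    length.  Two-sided Mann-Whitney U; when ``p < alpha`` the direction is
    the sign of the median rate difference (mean difference breaks median
    ties).  Needs at least 2 events.
    """
    events = np.asarray(events, dtype=float)
    if len(events) < 2:
        raise InsufficientDataError("need >= 2 events to test a response")
    unit_id = spikes.unit_id if isinstance(spikes, SpikeTrain) else ""
    base = counts_in_windows(spikes, events, baseline_win) / (baseline_win[1] - baseline_win[0])
    resp = counts_in_windows(spikes, events, response_win) / (response_win[1] - response_win[0])

    if np.all(base == base[0]) and np.all(resp == base[0]):
        p = 1.0
    else:
        _, p = stats.mannwhitneyu(resp, base, alternative="two-sided")
    effect = float(resp.mean() - base.mean())
    direction = "none"
    if p < alpha:
        diff = float(np.median(resp) - np.median(base))
        if diff == 0:
            diff = effect
        if diff > 0:
            direction = "activated"
        elif diff < 0:
            direction = "inhibited"
    return ResponseResult(unit_id=unit_id, event_label=event_label,
                          direction=direction, p_value=float(p), effect_hz=effect)


def response_latency(zpeth: Peth, direction: str,
                     response_win=(0.0, 0.6)) -> float:
    """Latency of the Z-score extremum inside the response window: the bin
    center of the maximum (activated) or minimum (inhibited) Z."""
    if direction not in ("activated", "inhibited"):
        raise ParameterError("latency is defined only for significant responses")
    if zpeth.z is None:
        raise ParameterError("PETH must be Z-scored first")
    mask = (zpeth.bin_centers >= response_win[0]) & (zpeth.bin_centers <= response_win[1])
    if not mask.any():
        raise ParameterError("response window contains no PETH bins")
    z = zpeth.z[mask]
    centers = zpeth.bin_centers[mask]
    i = int(np.argmax(z)) if direction == "activated" else int(np.argmin(z))
    return float(centers[i])


def classify_response(spikes, events, *,
                      window=(-1.0, 1.0), bin_s: float = 0.02,
                      baseline_win=(-0.5, 0.0), response_win=(0.0, 0.5),
                      latency_win=(0.0, 0.6), alpha: float = DEFAULT_ALPHA,
                      event_label: str = "") -> ResponseResult:
    """Convenience wrapper: significance test plus latency when significant."""
    res = test_event_response(spikes, events, baseline_win=baseline_win,
                              response_win=response_win, alpha=alpha,
                              event_label=event_label)
    if res.direction != "none":
        peth = compute_peth(spikes, events, window=window, bin_s=bin_s,
                            event_label=event_label)
        try:
            zp = zscore_peth(peth, baseline=baseline_win)
        except DegenerateDataError:
            return res
        res.latency_s = response_latency(zp, res.direction, response_win=latency_win)
    return res


@dataclass
class ConditionComparison:
    """Population comparison of response-window counts across two outcome
    conditions (within-unit differences, signed-rank test across units)."""

    deltas: pd.Series          # per included unit: mean count (a) - (b)
    excluded: list[str]        # unit ids with <5 trials in a condition
    statistic: float
    p_value: float

    @property
    def median_delta(self) -> float:
        return float(self.deltas.median()) if len(self.deltas) else float("nan")


def response_count_delta(spikes, events_a, events_b, response_win=(0.0, 0.5),
                         min_trials: int = MIN_TRIALS_PER_CONDITION) -> float | None:
    """Mean response-window spike-count difference between two conditions,
    or None when either condition has fewer than ``min_trials`` trials."""
    events_a = np.asarray(events_a, dtype=float)
    events_b = np.asarray(events_b, dtype=float)
    if len(events_a) < min_trials or len(events_b) < min_trials:
        return None
    ca = counts_in_windows(spikes, events_a, response_win)
    cb = counts_in_windows(spikes, events_b, response_win)
    return float(ca.mean() - cb.mean())


def compare_outcome_conditions(units, events_a, events_b,
                               response_win=(0.0, 0.5),
                               min_trials: int = MIN_TRIALS_PER_CONDITION
                               ) -> ConditionComparison:
    """Per-unit response-count differences between two event sets of one
    session, with a two-sided Wilcoxon signed-rank test on the differences.

    Units with fewer than ``min_trials`` trials in either condition are
    excluded (recorded in the result, not fatal).
    """
    deltas, excluded = {}, []
    for st in units:
        d = response_count_delta(st, events_a, events_b, response_win, min_trials)
        if d is None:
            excluded.append(st.unit_id)
        else:
            deltas[st.unit_id] = d
    if not deltas:
        raise InsufficientDataError("no unit has enough trials in both conditions")
    vals = np.asarray(list(deltas.values()))
    if np.all(vals == 0):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.wilcoxon(vals, alternative="two-sided")
    return ConditionComparison(deltas=pd.Series(deltas), excluded=excluded,
                               statistic=float(stat), p_value=float(p))


_SIGNS = ("+", "0", "-")


def response_combination_table(results: dict[str, dict[str, ResponseResult]],
                               events=("cue", "reward", "punishment")) -> pd.DataFrame:
    """Counts of units over the 27 (+/0/-)^3 response-sign combinations.

    ``results`` maps unit id -> {event label -> ResponseResult}.  Units
    missing any of the three events are dropped with a warning.  Marginal
    sums over the table equal the per-event responsive counts.
    """
    sign_of = {1: "+", 0: "0", -1: "-"}
    table = {combo: 0 for combo in product(_SIGNS, repeat=len(events))}
    for unit_id, per_event in results.items():
        if any(ev not in per_event for ev in events):
            warnings.warn(f"unit {unit_id} missing an event test; dropped from table")
            continue
        combo = tuple(sign_of[per_event[ev].sign] for ev in events)
        table[combo] += 1
    df = pd.DataFrame(
        [dict(zip(events, combo), n_units=n) for combo, n in table.items()])
    return df


def compare_group_fractions(n_resp_a: int, n_a: int,
                            n_resp_b: int, n_b: int) -> tuple[float, float]:
    """2x2 chi-square (no continuity correction) comparing responsive
    fractions between two unit groups.  Returns ``(chi2, p)``."""
    if min(n_resp_a, n_resp_b) < 0 or n_resp_a > n_a or n_resp_b > n_b:
        raise ParameterError("counts must satisfy 0 <= n_resp <= n")
    table = np.array([[n_resp_a, n_a - n_resp_a], [n_resp_b, n_b - n_resp_b]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateDataError("a row or column of the 2x2 table is empty")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)
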