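"""ISI-rule burst parsing and burst vs single-spike response dissociation.

A burst starts at a spike whose next inter-spike interval is shorter than
``first_isi_max_ms`` (default 10 ms) and extends while subsequent intervals
stay below ``intra_isi_max_ms`` (default 15 ms); both thresholds are strict.
A spike already inside a burst cannot start a new one.  All remaining spikes
are single spikes.  The parse partitions the train exactly.

For event alignment each burst is represented by its first spike (the
"burst event train"); an all-burst-spikes mode is available.  Bursts and
single spikes are then tested separately for event responses, which can
dissociate — e.g. burst rate dropping while single-spike rate rises after
the same event.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError, ParameterError
from .session import SpikeTrain

LABEL_BURST_FIRST = "burst_first"
LABEL_BURST_MEMBER = "burst_member"
LABEL_SINGLE = "single"


class DissociationCategory(str, Enum):
    """Joint burst/single-spike response category of one unit and event."""

    CONCORDANT = "concordant"
    OPPOSITE = "opposite"
    BURST_ONLY = "burst_only"
    SINGLE_ONLY = "single_only"
    NEITHER = "neither"


@dataclass
class BurstParse:
    """Partition of one spike train into bursts and single spikes."""

    unit_id: str
    times: np.ndarray                 # seconds, as in the input train
    spike_labels: np.ndarray          # str per spike
    burst_onsets: np.ndarray          # times of burst_first spikes
    single_times: np.ndarray
    burst_sizes: np.ndarray           # spikes per burst, each >= 2

    @property
    def n_bursts(self) -> int:
        return len(self.burst_sizes)

    @property
    def n_burst_spikes(self) -> int:
        return int(self.burst_sizes.sum()) if self.n_bursts else 0

    def burst_spike_times(self) -> np.ndarray:
        """Times of every spike inside a burst (all-burst-spikes mode)."""
        mask = self.spike_labels != LABEL_SINGLE
        return self.times[mask]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "unit_id": self.unit_id,
            "spike_time_s": self.times,
            "label": self.spike_labels,
        })


def parse_bursts(spikes: SpikeTrain,
                 first_isi_max_ms: float = 10.0,
                 intra_isi_max_ms: float = 15.0) -> BurstParse:
    """Split a sorted train into bursts and single spikes by the ISI rule.

    Left-to-right scan: a burst starts at spike *i* if the interval to spike
    *i+1* is below ``first_isi_max_ms``; the burst extends while following
    intervals stay below ``intra_isi_max_ms``.  Strict inequalities.
    """
    if first_isi_max_ms <= 0 or intra_isi_max_ms <= 0:
        raise ParameterError("ISI thresholds must be positive")
    t = spikes.times
    n = len(t)
    labels = np.full(n, LABEL_SINGLE, dtype=object)
    sizes = []
    isis_ms = np.diff(t) * 1000.0
    i = 0
    while i < n - 1:
        if isis_ms[i] < first_isi_max_ms:
            labels[i] = LABEL_BURST_FIRST
            j = i + 1
            labels[j] = LABEL_BURST_MEMBER
            while j < n - 1 and isis_ms[j] < intra_isi_max_ms:
                j += 1
                labels[j] = LABEL_BURST_MEMBER
            sizes.append(j - i + 1)
            i = j + 1
        else:
            i += 1
    return BurstParse(
        unit_id=spikes.unit_id,
        times=t.copy(),
        spike_labels=labels,
        burst_onsets=t[labels == LABEL_BURST_FIRST],
        single_times=t[labels == LABEL_SINGLE],
        burst_sizes=np.asarray(sizes, dtype=int),
    )


def detect_rate_dissociation(parse: BurstParse, events,
                             baseline_win=(-0.5, 0.0),
                             response_win=(0.0, 0.5),
                             alpha: float = 0.01,
                             align: str = "onsets") -> DissociationCategory:
    """Joint response category of a unit's bursts and single spikes.

    Runs the event-response rank-sum test separately on the burst event
    train (one event per burst, or all burst spikes with ``align="all"``)
    and on the single-spike train, both at ``alpha``, and combines the two
    directions.  "opposite" requires both trains significant with opposite
    signs.
    """
    from .responses import test_event_response  # local import avoids a cycle

    events = np.asarray(events, dtype=float)
    if len(events) < 2:
        raise InsufficientDataError("need >= 2 events for dissociation testing")
    if align == "onsets":
        burst_times = parse.burst_onsets
    elif align == "all":
        burst_times = parse.burst_spike_times()
    else:
        raise ParameterError(f"align must be 'onsets' or 'all', got {align!r}")

    rb = test_event_response(
        SpikeTrain(parse.unit_id + "/bursts", burst_times), events,
        baseline_win=baseline_win, response_win=response_win, alpha=alpha)
    rs = test_event_response(
        SpikeTrain(parse.unit_id + "/singles", parse.single_times), events,
        baseline_win=baseline_win, response_win=response_win, alpha=alpha)

    b_sig, s_sig = rb.direction != "none", rs.direction != "none"
    if b_sig and s_sig:
        if rb.direction == rs.direction:
            return DissociationCategory.CONCORDANT
        return DissociationCategory.OPPOSITE
    if b_sig:
        return DissociationCategory.BURST_ONLY
    if s_sig:
        return DissociationCategory.SINGLE_ONLY
    return DissociationCategory.NEITHER
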