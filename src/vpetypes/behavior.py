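"""Licking behavior: anticipatory discrimination of the predictive cues.

Anticipatory licking — licks between cue onset and reinforcement — indexes
the learned value of a cue.  The anticipatory window of each trial is
``[t_cue_on, t_reinforcement)`` (virtual reinforcement time on omission
trials), so it never overlaps post-reinforcement consumption.  Per-trial
lick counts are normalized by the window length and compared between the
two cue types.

Trials of the two cue types are unpaired, so the default test is the
two-sided rank-sum (Mann-Whitney U) test; a paired session-block mode
(trial *k* of one cue vs trial *k* of the other, signed-rank) is provided
for comparability with analyses that paired trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InsufficientDataError
from .responses import Peth, compute_peth, counts_in_windows
from .session import LickTrain, TrialTable


@dataclass
class BehaviorSummary:
    """Per-subject anticipatory lick discrimination."""

    subject_id: str
    n_trials_reward_cue: int
    n_trials_punish_cue: int
    lick_rate_reward_cue: float   # Hz over the anticipatory window
    lick_rate_punish_cue: float
    discrimination_delta: float   # mean rate difference, Hz
    p_discrimination: float


def lick_peth(licks: LickTrain, events, window=(-1.0, 3.0), bin_s: float = 0.05,
              event_label: str = "") -> Peth:
    """Trial-averaged lick-rate histogram around events (see compute_peth)."""
    return compute_peth(licks.times, events, window=window, bin_s=bin_s,
                        event_label=event_label)


def anticipatory_lick_rates(licks: LickTrain, trials: TrialTable):
    """Per-trial anticipatory lick rates (Hz), split by cue type.

    The anticipatory window is cue onset to (virtual) reinforcement; rates
    are counts normalized by each trial's window length.
    """
    df = trials.df
    starts = df["t_cue_on_s"].to_numpy(dtype=float)
    ends = trials.virtual_reinforcement_times()
    lengths = ends - starts
    if np.any(lengths <= 0):
        raise InsufficientDataError("trial with non-positive anticipatory window")
    lo = np.searchsorted(licks.times, starts, side="left")
    hi = np.searchsorted(licks.times, ends, side="left")
    rates = (hi - lo) / lengths
    is_rw = (df["cue"] == "likely_reward").to_numpy()
    return rates[is_rw], rates[~is_rw]


def anticipatory_lick_test(licks: LickTrain, trials: TrialTable,
                           subject_id: str = "", min_trials: int = 5,
                           paired: bool = False) -> BehaviorSummary:
    """Test whether the animal licked more after the reward-predicting cue.

    Needs at least ``min_trials`` trials of each cue type.  With no lick
    rate variation at all (e.g. zero licks throughout) the test is
    degenerate and is reported as non-discriminating (p = 1).
    """
    rw, pu = anticipatory_lick_rates(licks, trials)
    if len(rw) < min_trials or len(pu) < min_trials:
        raise InsufficientDataError(
            f"need >= {min_trials} trials per cue, got {len(rw)}/{len(pu)}")
    pooled = np.concatenate([rw, pu])
    if np.all(pooled == pooled[0]):
        p = 1.0
    elif paired:
        k = min(len(rw), len(pu))
        d = rw[:k] - pu[:k]
        p = 1.0 if np.all(d == 0) else float(stats.wilcoxon(d, alternative="two-sided")[1])
    else:
        p = float(stats.mannwhitneyu(rw, pu, alternative="two-sided")[1])
    return BehaviorSummary(
        subject_id=subject_id,
        n_trials_reward_cue=len(rw), n_trials_punish_cue=len(pu),
        lick_rate_reward_cue=float(rw.mean()), lick_rate_punish_cue=float(pu.mean()),
        discrimination_delta=float(rw.mean() - pu.mean()),
        p_discrimination=p,
    )


def correlate_discrimination_with_responsiveness(deltas, fractions) -> tuple[float, float]:
    """Spearman rank correlation of per-subject behavioral discrimination
    (anticipatory lick-rate difference) with neural responsive fraction.

    Returns ``(rho, p)``; with a constant input the correlation is
    undefined and reported as NaN with a warning.
    """
    d = np.asarray(deltas, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if len(d) != len(f):
        raise ValueError("deltas and fractions must be the same length")
    if len(d) < 3:
        raise InsufficientDataError("need >= 3 subjects")
    if np.all(d == d[0]) or np.all(f == f[0]):
        warnings.warn("constant input; rank correlation undefined")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(d, f)
    return float(rho), float(p)
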