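"""Seeded generator of complete synthetic Pavlovian sessions.

Every analysis stage in this package is validated against sessions produced
here, with known ground truth.  The generator emulates:

* the probabilistic task: two cues with outcome contingencies 80/10/10
  (likely reward) and 25/65/10 (likely punishment), reinforcement delivered
  a uniform 400-600 ms after cue offset, omission trials with no
  reinforcement;
* units of distinct e-types — plain Poisson firers, bursting units (a
  Poisson process of burst initiations, each burst carrying 1 + Poisson(mu)
  extra spikes at 3-8 ms intra-burst intervals, superposed on Poisson
  single spikes), and rhythmic units (at most one spike per oscillation
  cycle, fired with fixed probability at a cycle clock whose period
  jitters as a random walk; see note below);
* event-locked rate modulation: multiplicative alpha-function (or boxcar)
  kernels per event type, so inhibition can never drive a rate negative;
* pairwise coupling: common input copied into two or more units with
  per-copy Gaussian timing jitter, and synaptic-like coupling adding a
  delayed extra spike to the postsynaptic unit;
* anticipatory licking that differs by cue, plus a consumption burst after
  reward.

Rhythmic-unit note: a sinusoidally rate-modulated Poisson process with
modulation depth m has an autocorrelogram modulated only by m^2/2 <= 1/2,
which caps any peak-vs-baseline rhythmicity ratio at 1/3 — too weak for a
unit that a peak-based classifier should call rhythmic, and unlike real
fast-rhythmic units, which rarely fire twice within a cycle.  The per-cycle
Bernoulli model used here produces the empirically observed ACG shape:
near-silent short lags and a tall peak at the oscillation period that
decays over cycles as the clock drifts.

All generators are deterministic functions of (config, seed); child random
streams are spawned from one ``numpy`` SeedSequence.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .session import (CUES, LickTrain, Session, SpikeTrain, TrialTable,
                      write_session_bundle)

DEFAULT_CONTINGENCIES = {
    "likely_reward": (0.80, 0.10, 0.10),       # (p_reward, p_punishment, p_omission)
    "likely_punishment": (0.25, 0.65, 0.10),
}
OUTCOME_ORDER = ("reward", "punishment", "omission")


# ---------------------------------------------------------------------------
# specs

@dataclass
class ResponseKernel:
    """Multiplicative event-response kernel of one unit.

    The firing rate is multiplied by ``max(0, 1 + amplitude * k(t - t_ev))``
    where ``k`` is an alpha function ``(x/tau) * exp(1 - x/tau)`` (unit
    peak at ``latency + tau`` after the event) or a boxcar of length
    ``tau`` starting at ``latency``.
    """

    event: str                    # one of session.TrialTable event labels
    amplitude: float              # signed; -1 <= amplitude silences the unit at peak
    latency_s: float = 0.02
    tau_s: float = 0.06
    shape: str = "alpha"          # "alpha" | "boxcar"

    @property
    def sign(self) -> int:
        return 1 if self.amplitude > 0 else (-1 if self.amplitude < 0 else 0)

    @property
    def peak_latency_s(self) -> float:
        return self.latency_s + (self.tau_s if self.shape == "alpha" else self.tau_s / 2)

    def support_s(self) -> float:
        return self.latency_s + (8 * self.tau_s if self.shape == "alpha" else self.tau_s)


@dataclass
class UnitSpec:
    """Generative specification of one unit."""

    unit_id: str
    etype: str = "poisson"        # "poisson" | "bursting" | "rhythmic"
    baseline_hz: float = 10.0     # poisson rate / singles rate / rhythmic mean rate
    # bursting
    burst_rate_hz: float = 2.0
    burst_extra_mean: float = 2.0             # bursts carry 1 + Poisson(mu) extra spikes
    intra_burst_isi_ms: tuple = (3.0, 8.0)
    # rhythmic
    rhythm_freq_hz: float = 40.0
    rhythm_depth: float = 0.8                 # fraction of rate that is cycle-locked
    cycle_jitter_ms: float = 2.0              # SD of the per-cycle period noise
    responses: list = field(default_factory=list)
    dv_um: float | None = None

    def validate(self):
        if self.baseline_hz < 0 or self.burst_rate_hz < 0:
            raise ConfigError(f"unit {self.unit_id}: negative rate")
        if not 0 <= self.rhythm_depth <= 1:
            raise ConfigError(f"unit {self.unit_id}: rhythm_depth must be in [0, 1]")
        if self.etype not in ("poisson", "bursting", "rhythmic"):
            raise ConfigError(f"unit {self.unit_id}: unknown etype {self.etype!r}")
        if self.etype == "rhythmic":
            p = self.rhythm_depth * self.baseline_hz / self.rhythm_freq_hz
            if p > 1:
                raise ConfigError(
                    f"unit {self.unit_id}: locked rate exceeds one spike per cycle")


@dataclass
class PairSpec:
    """Generative coupling between two units (added on top of their trains)."""

    kind: str                     # "common_input" | "synaptic"
    unit_a: str
    unit_b: str
    rate_hz: float = 2.0          # shared-drive event rate (common_input)
    copy_prob: float = 0.3
    copy_jitter_sd_ms: float = 0.5
    p_syn: float = 0.15           # per-presynaptic-spike extra-spike probability
    delay_ms: float = 2.0
    delay_sd_ms: float = 0.3

    def validate(self):
        if self.kind not in ("common_input", "synaptic"):
            raise ConfigError(f"unknown pair kind {self.kind!r}")
        for p in (self.copy_prob, self.p_syn):
            if not 0 <= p <= 1:
                raise ConfigError("probabilities must be within [0, 1]")

    @property
    def expected_class(self) -> str:
        if self.kind == "synaptic":
            return "mono_excitation"
        return "narrow_sync" if self.copy_jitter_sd_ms < 1.5 else "broad_sync"


@dataclass
class AssemblySpec:
    """One shared drive copied into several units (common input over a group)."""

    unit_ids: list
    rate_hz: float = 2.0
    copy_prob: float = 0.3
    copy_jitter_sd_ms: float = 0.5


@dataclass
class LickSpec:
    """Piecewise-constant lick-rate model."""

    baseline_hz: float = 1.0
    anticipatory_reward_hz: float = 6.0       # after the likely-reward cue
    anticipatory_punish_hz: float = 2.0       # after the likely-punishment cue
    consumption_hz: float = 8.0               # after reward delivery
    consumption_s: float = 1.0

    def validate(self):
        rates = (self.baseline_hz, self.anticipatory_reward_hz,
                 self.anticipatory_punish_hz, self.consumption_hz)
        if any(r < 0 for r in rates):
            raise ConfigError("lick rates must be >= 0")
        if min(self.anticipatory_reward_hz, self.anticipatory_punish_hz,
               self.consumption_hz) < self.baseline_hz:
            raise ConfigError("anticipatory/consumption rates must be >= baseline")


@dataclass
class SimConfig:
    """Full synthetic-session configuration; ``seed`` is mandatory."""

    seed: int
    n_trials: int = 300
    contingencies: dict = field(default_factory=lambda: dict(DEFAULT_CONTINGENCIES))
    cue_duration_s: float = 0.5
    reinforcement_delay_s: tuple = (0.4, 0.6)
    iti_s: tuple = (2.0, 4.0)
    post_trial_gap_s: float = 1.5
    units: list = field(default_factory=list)
    pairs: list = field(default_factory=list)
    assemblies: list = field(default_factory=list)
    licks: LickSpec = field(default_factory=LickSpec)
    subject: str = "sim_subject"

    def validate(self):
        for cue, probs in self.contingencies.items():
            if cue not in CUES:
                raise ConfigError(f"unknown cue {cue!r}")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigError(f"contingency for {cue!r} does not sum to 1")
        for u in self.units:
            u.validate()
        for p in self.pairs:
            p.validate()
        self.licks.validate()


# ---------------------------------------------------------------------------
# elementary generators

def _poisson_train(rate_hz: float, duration_s: float, rng) -> np.ndarray:
    if rate_hz <= 0 or duration_s <= 0:
        return np.empty(0)
    n = rng.poisson(rate_hz * duration_s)
    return np.sort(rng.uniform(0.0, duration_s, n))


def _strictly_increasing(t: np.ndarray) -> np.ndarray:
    """Sort and nudge exact duplicates apart by 1 ns (keeps invariants)."""
    t = np.sort(t)
    for _ in range(3):
        d = np.diff(t)
        if not np.any(d <= 0):
            break
        t[1:][d <= 0] += 1e-9
        t = np.sort(t)
    return t


def _rate_multiplier(t: np.ndarray, kernels, trials: TrialTable | None) -> np.ndarray:
    """Event-response multiplier evaluated at times ``t`` (clipped at 0)."""
    m = np.ones_like(t, dtype=float)
    if trials is None or not kernels:
        return m
    for k in kernels:
        events = trials.events(k.event)
        support = k.support_s()
        for e in events:
            lo = np.searchsorted(t, e + k.latency_s, side="right")
            hi = np.searchsorted(t, e + support, side="right")
            if hi <= lo:
                continue
            x = t[lo:hi] - e - k.latency_s
            if k.shape == "alpha":
                shape = (x / k.tau_s) * np.exp(1.0 - x / k.tau_s)
            elif k.shape == "boxcar":
                shape = (x < k.tau_s).astype(float)
            else:
                raise ConfigError(f"unknown kernel shape {k.shape!r}")
            m[lo:hi] += k.amplitude * shape
    return np.clip(m, 0.0, None)


def _modulated_poisson(rate_hz: float, duration_s: float, kernels,
                       trials, rng) -> np.ndarray:
    """Inhomogeneous Poisson by thinning a homogeneous envelope process."""
    if rate_hz <= 0 or duration_s <= 0:
        return np.empty(0)
    envelope = 1.0 + sum(max(k.amplitude, 0.0) for k in kernels)
    cand = _poisson_train(rate_hz * envelope, duration_s, rng)
    if len(cand) == 0:
        return cand
    m = _rate_multiplier(cand, kernels, trials)
    keep = rng.uniform(0.0, envelope, len(cand)) < m
    return cand[keep]


# ---------------------------------------------------------------------------
# operations

def simulate_trials(config: SimConfig, seed: int | None = None) -> TrialTable:
    """Draw a trial table: equiprobable cues, outcomes per cue contingency,
    reinforcement a uniform 400-600 ms after cue offset, no reinforcement
    time on omission trials.  Deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    t = float(rng.uniform(*config.iti_s))
    d_lo, d_hi = config.reinforcement_delay_s
    for i in range(config.n_trials):
        cue = CUES[int(rng.integers(len(CUES)))]
        outcome = OUTCOME_ORDER[int(rng.choice(len(OUTCOME_ORDER),
                                               p=config.contingencies[cue]))]
        t_on = t
        t_off = t_on + config.cue_duration_s
        if outcome == "omission":
            t_reinf = np.nan
        else:
            t_reinf = t_off + float(rng.uniform(d_lo, d_hi))
        rows.append({"trial_id": i, "cue": cue, "outcome": outcome,
                     "t_cue_on_s": t_on, "t_cue_off_s": t_off,
                     "t_reinforcement_s": t_reinf})
        t = t_off + d_hi + config.post_trial_gap_s + float(rng.uniform(*config.iti_s))
    return TrialTable(pd.DataFrame(rows))


def session_duration(trials: TrialTable, tail_s: float = 5.0) -> float:
    df = trials.df
    last = float(np.nanmax([df["t_cue_off_s"].max(), df["t_reinforcement_s"].max()]))
    return last + tail_s


def simulate_unit(spec: UnitSpec, trials: TrialTable | None, duration_s: float,
                  seed: int | None = None, rng=None) -> tuple[SpikeTrain, dict]:
    """Generate one unit's spike train plus its ground-truth record."""
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(seed)
    k = spec.responses

    if spec.etype == "poisson":
        t = _modulated_poisson(spec.baseline_hz, duration_s, k, trials, rng)
        gt_extra = {}
    elif spec.etype == "bursting":
        onsets = _modulated_poisson(spec.burst_rate_hz, duration_s, k, trials, rng)
        extras = rng.poisson(spec.burst_extra_mean, len(onsets))
        spikes = [onsets]
        if len(onsets) and extras.sum() > 0:
            isis = rng.uniform(spec.intra_burst_isi_ms[0], spec.intra_burst_isi_ms[1],
                               int(extras.sum())) / 1000.0
            start = 0
            burst_spike_times = []
            for on, ext in zip(onsets, extras):
                if ext:
                    burst_spike_times.append(on + np.cumsum(isis[start:start + ext]))
                    start += ext
            spikes.append(np.concatenate(burst_spike_times))
        singles = _modulated_poisson(spec.baseline_hz, duration_s, k, trials, rng)
        spikes.append(singles)
        t = np.concatenate(spikes)
        t = t[(t >= 0) & (t < duration_s)]
        gt_extra = {"expected_burst_spike_fraction":
                    (spec.burst_rate_hz * (1 + spec.burst_extra_mean))
                    / (spec.burst_rate_hz * (1 + spec.burst_extra_mean) + spec.baseline_hz)}
    elif spec.etype == "rhythmic":
        period = 1.0 / spec.rhythm_freq_hz
        n_cycles = int(duration_s / period * 1.2) + 10
        noise = rng.normal(0.0, spec.cycle_jitter_ms / 1000.0, n_cycles)
        periods = np.clip(period + noise, 0.2 * period, None)
        cycles = float(rng.uniform(0, period)) + np.cumsum(periods)
        cycles = cycles[cycles < duration_s]
        p_lock = spec.rhythm_depth * spec.baseline_hz / spec.rhythm_freq_hz
        m = _rate_multiplier(cycles, k, trials)
        locked = cycles[rng.uniform(0, 1, len(cycles)) < np.minimum(p_lock * m, 1.0)]
        background = _modulated_poisson((1 - spec.rhythm_depth) * spec.baseline_hz,
                                        duration_s, k, trials, rng)
        t = np.concatenate([locked, background])
        gt_extra = {"rhythm_freq_hz": spec.rhythm_freq_hz}
    else:  # pragma: no cover - spec.validate rejects this
        raise ConfigError(f"unknown etype {spec.etype!r}")

    t = _strictly_increasing(t[(t >= 0) & (t < duration_s)])
    train = SpikeTrain(unit_id=spec.unit_id, times=t, dv_position=spec.dv_um)
    gt = {"unit_id": spec.unit_id, "etype": spec.etype,
          "baseline_hz": spec.baseline_hz,
          "responses": [{"event": r.event, "sign": r.sign,
                         "peak_latency_s": r.peak_latency_s} for r in spec.responses],
          **gt_extra}
    return train, gt


def _common_input_copies(shared: np.ndarray, copy_prob: float,
                         jitter_sd_ms: float, rng) -> np.ndarray:
    take = shared[rng.uniform(0, 1, len(shared)) < copy_prob]
    return take + rng.normal(0.0, jitter_sd_ms / 1000.0, len(take))


def simulate_pair(spec: PairSpec, duration_s: float, seed: int | None = None,
                  background_hz: float = 5.0) -> tuple[SpikeTrain, SpikeTrain, dict]:
    """Standalone coupled pair (background Poisson plus the coupling).

    common_input: a shared Poisson event train copied into each unit with
    ``copy_prob`` and independent Gaussian timing jitter.  synaptic: unit b
    receives an extra spike after each unit-a spike with probability
    ``p_syn`` at a Normal(delay, 0.3 ms) latency.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    a_bg = _poisson_train(background_hz, duration_s, rng)
    b_bg = _poisson_train(background_hz, duration_s, rng)
    if spec.kind == "common_input":
        shared = _poisson_train(spec.rate_hz, duration_s, rng)
        a = np.concatenate([a_bg, _common_input_copies(
            shared, spec.copy_prob, spec.copy_jitter_sd_ms, rng)])
        b = np.concatenate([b_bg, _common_input_copies(
            shared, spec.copy_prob, spec.copy_jitter_sd_ms, rng)])
    else:
        a = a_bg
        extra = a_bg[rng.uniform(0, 1, len(a_bg)) < spec.p_syn]
        extra = extra + rng.normal(spec.delay_ms / 1000.0,
                                   spec.delay_sd_ms / 1000.0, len(extra))
        b = np.concatenate([b_bg, extra])
    a = _strictly_increasing(a[(a >= 0) & (a < duration_s)])
    b = _strictly_increasing(b[(b >= 0) & (b < duration_s)])
    gt = {"unit_a": spec.unit_a, "unit_b": spec.unit_b, "kind": spec.kind,
          "expected_class": spec.expected_class}
    return (SpikeTrain(spec.unit_a, a), SpikeTrain(spec.unit_b, b), gt)


def simulate_licks(trials: TrialTable, lick_spec: LickSpec, duration_s: float,
                   seed: int | None = None, rng=None) -> LickTrain:
    """Inhomogeneous Poisson licking: session-wide baseline, cue-dependent
    anticipatory rate from cue onset to reinforcement, and a consumption
    burst after reward.  Elevated-interval rates are generated as excess
    over baseline, so rates must dominate the baseline (checked)."""
    lick_spec.validate()
    if rng is None:
        rng = np.random.default_rng(seed)
    parts = [_poisson_train(lick_spec.baseline_hz, duration_s, rng)]
    df = trials.df
    ends = trials.virtual_reinforcement_times()
    for i, row in df.iterrows():
        antic = (lick_spec.anticipatory_reward_hz if row["cue"] == "likely_reward"
                 else lick_spec.anticipatory_punish_hz)
        excess = antic - lick_spec.baseline_hz
        w = ends[i] - row["t_cue_on_s"]
        if excess > 0 and w > 0:
            parts.append(row["t_cue_on_s"] + np.sort(
                rng.uniform(0, w, rng.poisson(excess * w))))
        if row["outcome"] == "reward":
            excess_c = lick_spec.consumption_hz - lick_spec.baseline_hz
            if excess_c > 0:
                parts.append(row["t_reinforcement_s"] + np.sort(
                    rng.uniform(0, lick_spec.consumption_s,
                                rng.poisson(excess_c * lick_spec.consumption_s))))
    t = np.concatenate(parts)
    return LickTrain(_strictly_increasing(t[(t >= 0) & (t < duration_s)]))


def simulate_session(config: SimConfig, out_dir=None) -> tuple[Session, dict]:
    """Compose trials, units, couplings and licks into a full session.

    Couplings add correlated spikes on top of the named units' base trains
    (one shared drive per assembly/common-input spec; delayed extras for
    synaptic specs).  When ``out_dir`` is given the session bundle and a
    ``ground_truth.json`` are written there.  Fully reproducible from
    (config, seed).
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    n_streams = 3 + len(config.units) + len(config.pairs) + len(config.assemblies)
    streams = [np.random.default_rng(s) for s in root.spawn(n_streams)]
    it = iter(streams)

    trials = simulate_trials(config)
    duration = session_duration(trials)

    trains: dict[str, np.ndarray] = {}
    gt_units = []
    dv = {}
    for spec in config.units:
        train, gt = simulate_unit(spec, trials, duration, rng=next(it))
        trains[spec.unit_id] = train.times
        dv[spec.unit_id] = spec.dv_um
        gt_units.append(gt)

    gt_pairs = []
    couplings = list(config.assemblies) + [
        AssemblySpec(unit_ids=[p.unit_a, p.unit_b], rate_hz=p.rate_hz,
                     copy_prob=p.copy_prob, copy_jitter_sd_ms=p.copy_jitter_sd_ms)
        if p.kind == "common_input" else p
        for p in config.pairs
    ]
    for spec in couplings:
        rng = next(it)
        if isinstance(spec, AssemblySpec):
            shared = _poisson_train(spec.rate_hz, duration, rng)
            for uid in spec.unit_ids:
                if uid not in trains:
                    raise ConfigError(f"coupling references unknown unit {uid!r}")
                trains[uid] = np.concatenate([
                    trains[uid], _common_input_copies(
                        shared, spec.copy_prob, spec.copy_jitter_sd_ms, rng)])
            cls = "narrow_sync" if spec.copy_jitter_sd_ms < 1.5 else "broad_sync"
            ids = list(spec.unit_ids)
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    gt_pairs.append({"unit_a": ids[i], "unit_b": ids[j],
                                     "kind": "common_input", "expected_class": cls})
        else:  # synaptic PairSpec
            if spec.unit_a not in trains or spec.unit_b not in trains:
                raise ConfigError("coupling references unknown unit")
            pre = trains[spec.unit_a]
            extra = pre[rng.uniform(0, 1, len(pre)) < spec.p_syn]
            extra = extra + rng.normal(spec.delay_ms / 1000.0,
                                       spec.delay_sd_ms / 1000.0, len(extra))
            trains[spec.unit_b] = np.concatenate([trains[spec.unit_b], extra])
            gt_pairs.append({"unit_a": spec.unit_a, "unit_b": spec.unit_b,
                             "kind": "synaptic", "expected_class": "mono_excitation"})

    spike_trains = []
    for spec in config.units:
        t = trains[spec.unit_id]
        t = _strictly_increasing(t[(t >= 0) & (t < duration)])
        spike_trains.append(SpikeTrain(spec.unit_id, t, dv_position=dv[spec.unit_id],
                                       session_id=config.subject))

    licks = simulate_licks(trials, config.licks, duration, rng=next(it))

    meta = {
        "subject": config.subject,
        "synthetic": True,
        "seed": int(config.seed),
        "contingencies": {k: list(v) for k, v in config.contingencies.items()},
        "n_trials": int(config.n_trials),
        "generator": {
            "cue_duration_s": config.cue_duration_s,
            "reinforcement_delay_s": list(config.reinforcement_delay_s),
            "iti_s": list(config.iti_s),
            "n_units": len(config.units),
        },
    }
    session = Session(spike_trains=spike_trains, trials=trials, licks=licks, meta=meta)
    ground_truth = {
        "seed": int(config.seed),
        "units": gt_units,
        "pairs": gt_pairs,
        "outcomes": trials.df["outcome"].tolist(),
        "lick_params": asdict(config.licks),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        write_session_bundle(session, out_dir)
        with open(out_dir / "ground_truth.json", "w", encoding="utf-8") as fh:
            json.dump(ground_truth, fh, indent=1, sort_keys=True)
    return session, ground_truth


# ---------------------------------------------------------------------------
# canonical cohorts and demo configuration

def bursting_cohort_specs(n_bursting: int = 100, n_poisson: int = 100) -> list[UnitSpec]:
    """Default labeled cohort for burst-classification recovery: bursting
    units (2 Hz burst initiations, 1 + Poisson(2) spikes per burst, 2 Hz
    singles) and plain 8 Hz Poisson units."""
    specs = [UnitSpec(unit_id=f"burst{i:03d}", etype="bursting", baseline_hz=2.0,
                      burst_rate_hz=2.0, burst_extra_mean=2.0)
             for i in range(n_bursting)]
    specs += [UnitSpec(unit_id=f"pois{i:03d}", etype="poisson", baseline_hz=8.0)
              for i in range(n_poisson)]
    return specs


def rhythmic_cohort_specs(n_beta: int = 6, n_gamma: int = 34,
                          seed: int = 0) -> list[UnitSpec]:
    """Rhythmic cohort mirroring the detected 6 beta + 34 gamma units;
    frequencies drawn uniformly inside each band (away from the shared
    30 Hz edge so the ground-truth band label is unambiguous)."""
    rng = np.random.default_rng(seed)
    specs = [UnitSpec(unit_id=f"beta{i:02d}", etype="rhythmic", baseline_hz=8.0,
                      rhythm_freq_hz=float(rng.uniform(15.0, 28.0)), rhythm_depth=0.8)
             for i in range(n_beta)]
    specs += [UnitSpec(unit_id=f"gamma{i:02d}", etype="rhythmic", baseline_hz=12.0,
                       rhythm_freq_hz=float(rng.uniform(35.0, 85.0)), rhythm_depth=0.8)
              for i in range(n_gamma)]
    return specs


def response_cohort_specs(event: str = "reward", n_activated: int = 30,
                          n_inhibited: int = 30) -> list[UnitSpec]:
    """Units with known response sign and peak latency for direction and
    latency recovery.  Activated units carry a sharp alpha kernel (tau
    40 ms) whose peak (90 ms) sits on a PETH bin center, so the true
    latency is well defined at 20 ms resolution; inhibited units carry a
    slower, deeper kernel on a higher baseline, because suppressed spike
    *mass* (kernel integral times baseline rate) is what the rank-sum test
    detects from ~60 trials."""
    act = [UnitSpec(unit_id=f"act{i:03d}", etype="poisson", baseline_hz=10.0,
                    responses=[ResponseKernel(event=event, amplitude=2.5,
                                              latency_s=0.05, tau_s=0.04)])
           for i in range(n_activated)]
    inh = [UnitSpec(unit_id=f"inh{i:03d}", etype="poisson", baseline_hz=20.0,
                    responses=[ResponseKernel(event=event, amplitude=-0.85,
                                              latency_s=0.02, tau_s=0.1)])
           for i in range(n_inhibited)]
    return act + inh


def depth_graded_cohort_specs(n: int = 200, dv_range=(0.0, 1000.0)) -> list[UnitSpec]:
    """Cohort whose burst propensity decreases linearly with dorsoventral
    position (dorsal units burst more), for index-vs-depth correlation."""
    dvs = np.linspace(dv_range[0], dv_range[1], n)
    specs = []
    for i, dv in enumerate(dvs):
        frac = 1.0 - (dv - dv_range[0]) / (dv_range[1] - dv_range[0])
        specs.append(UnitSpec(unit_id=f"dv{i:03d}", etype="bursting",
                              baseline_hz=4.0, burst_rate_hz=0.2 + 2.8 * frac,
                              burst_extra_mean=2.0, dv_um=float(dv)))
    return specs


def sync_response_cohort(seed: int = 0, n_groups: int = 25, group_size: int = 8,
                         n_sync_pairs: int = 20, n_trials: int = 150,
                         p_resp_sync: float = 0.7, p_resp_async: float = 0.25):
    """Cohort in which common-drive units also carry event responses.

    Units are organized into recording groups (as tetrode bundles would be);
    pairwise synchrony is only assessed within a group.  The first
    ``n_sync_pairs`` groups each contain one narrow-sync common-input pair;
    sync-pair units carry a reward-response kernel with probability
    ``p_resp_sync``, all other units with probability ``p_resp_async``.

    Returns ``(trials, trains, groups, truth)`` where ``groups`` is a list
    of unit-id lists and ``truth`` records sync membership and response
    carriers.
    """
    root = np.random.SeedSequence(seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    cfg = SimConfig(seed=int(root.generate_state(1)[0] >> 1), n_trials=n_trials)
    trials = simulate_trials(cfg)
    duration = session_duration(trials)
    kernel = ResponseKernel(event="reward", amplitude=1.8, latency_s=0.03, tau_s=0.05)

    trains, groups = [], []
    truth = {"sync_units": set(), "responsive_units": set()}
    uid = 0
    for g in range(n_groups):
        group = []
        sync_pair = [] if g >= n_sync_pairs else [0, 1]
        shared = _poisson_train(2.0, duration, rng) if sync_pair else None
        for k in range(group_size):
            unit_id = f"u{uid:03d}"
            uid += 1
            group.append(unit_id)
            is_sync = k in sync_pair
            p_resp = p_resp_sync if is_sync else p_resp_async
            responsive = bool(rng.uniform() < p_resp)
            spec = UnitSpec(unit_id=unit_id, etype="poisson", baseline_hz=5.0,
                            responses=[kernel] if responsive else [])
            st, _ = simulate_unit(spec, trials, duration, rng=rng)
            t = st.times
            if is_sync:
                t = np.concatenate([t, _common_input_copies(shared, 0.3, 0.5, rng)])
                truth["sync_units"].add(unit_id)
            if responsive:
                truth["responsive_units"].add(unit_id)
            trains.append(SpikeTrain(unit_id, _strictly_increasing(
                t[(t >= 0) & (t < duration)])))
        groups.append(group)
    return trials, trains, groups, truth


def demo_config(seed: int = 0, n_trials: int = 300) -> SimConfig:
    """Default demonstration session: 20 units spanning all e-types, one
    5-unit narrow-sync assembly, one broad-sync pair and one synaptic pair,
    event responses on half the units, cue-discriminating licking."""
    units = []
    resp = [ResponseKernel(event="reward", amplitude=2.0, latency_s=0.03, tau_s=0.05),
            ResponseKernel(event="punishment", amplitude=1.5, latency_s=0.02, tau_s=0.04)]
    for i in range(8):
        units.append(UnitSpec(unit_id=f"p{i:02d}", etype="poisson", baseline_hz=6.0,
                              responses=list(resp) if i % 2 == 0 else [],
                              dv_um=200.0 + 40 * i))
    for i in range(6):
        units.append(UnitSpec(unit_id=f"b{i:02d}", etype="bursting", baseline_hz=2.0,
                              burst_rate_hz=2.0, burst_extra_mean=2.0,
                              responses=list(resp) if i % 2 == 0 else [],
                              dv_um=450.0 + 40 * i))
    for i, f in enumerate((40.0, 55.0, 70.0)):
        units.append(UnitSpec(unit_id=f"g{i:02d}", etype="rhythmic", baseline_hz=12.0,
                              rhythm_freq_hz=f, rhythm_depth=0.8, dv_um=700.0 + 40 * i))
    units.append(UnitSpec(unit_id="be00", etype="rhythmic", baseline_hz=8.0,
                          rhythm_freq_hz=20.0, rhythm_depth=0.8, dv_um=820.0))
    for i in range(2):
        units.append(UnitSpec(unit_id=f"x{i:02d}", etype="poisson", baseline_hz=5.0,
                              dv_um=860.0 + 40 * i))
    return SimConfig(
        seed=seed, n_trials=n_trials, units=units,
        assemblies=[AssemblySpec(unit_ids=["p00", "p01", "p02", "p03", "p04"],
                                 rate_hz=2.0, copy_prob=0.3, copy_jitter_sd_ms=0.5)],
        pairs=[PairSpec(kind="common_input", unit_a="b00", unit_b="b01",
                        rate_hz=4.0, copy_prob=0.4, copy_jitter_sd_ms=3.0),
               PairSpec(kind="synaptic", unit_a="x00", unit_b="x01",
                        p_syn=0.15, delay_ms=2.0)],
    )
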