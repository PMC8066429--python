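# vpetypes

Spike-train analysis of ventral pallidal (VP) recordings during
probabilistic Pavlovian conditioning: electrophysiological cell-type
("e-type") classification, burst vs single-spike response dissociation,
event-response statistics, anticipatory-lick behavior, and
cross-correlogram synchrony / cell-assembly detection — together with a
fully seeded synthetic-session generator so that every stage of the
pipeline can be validated against known ground truth.

It is written for systems neuroscientists who have sorted extracellular
spike trains from a cued-outcome task (two auditory cues predicting reward
/ punishment / omission with fixed contingencies) and want a tested,
reproducible implementation of the standard analysis chain.

## What it computes

**Correlograms.** Auto- and cross-correlograms (ACG/CCG) with half-open
bins centered on lag 0; the ACG excludes its zero-lag bin. Counting is
sort-merge (`O(n log n + pairs)`) and is tested for exact equality against
brute-force pair enumeration.

**E-types.** Units are classified from the ACG with one bounded,
scale-free index form,

    index = (P − B) / max(P, B) ∈ [−1, 1],

where `P` is the peak smoothed ACG count in a feature lag range and `B`
the mean count over a long-lag baseline (180–200 ms). The *burst index*
uses lags 1–10 ms (bursting when BI ≥ 0.2; units with < 100 spikes are
excluded); the *beta* and *gamma rhythmicity indices* use the period
ranges of 13–30 Hz and 30–100 Hz (rhythmic when RI ≥ 0.35, band by
argmax, frequency `f = 1000 / lag_peak`). Indices can be correlated with
dorsoventral recording position.

**Burst parsing.** Bursts are parsed by the inter-spike interval rule:
a burst begins at a spike whose next ISI < 10 ms and extends while ISIs
< 15 ms; everything else is a single spike. Burst events (onsets) and
single spikes are then tested separately for event responses, which can
be concordant, opposite, or specific to one spike class.

**Event responses.** Peri-event time histograms (PETHs), baseline
Z-scoring, a two-sided Mann–Whitney U test of per-trial baseline
([−0.5, 0) s) vs response ([0, 0.5) s) spike counts at α = 0.001,
response latency as the Z extremum time, expectation contrasts across
outcome conditions (Wilcoxon signed-rank over units; units with < 5 trials
in a condition excluded), the 27-cell (+/0/−)³ response-combination table,
and 2×2 chi-square comparisons of responsive fractions between groups.

**Behavior.** Anticipatory lick rates per trial (cue onset →
reinforcement), rank-sum cue discrimination per subject, and Spearman
correlation of behavioral discrimination with neural responsiveness.

**Synchrony and assemblies.** CCGs (0.5 ms bins, ±50 ms) against
spike-time jitter surrogates (±25 ms uniform, 1000 surrogates, pointwise
95% bands). Supra-band runs (≥ 2 consecutive bins) are classified as
narrow (< 3 ms) or broad (≥ 3 ms) zero-lag synchrony, or putative
monosynaptic excitation (≤ 2 ms wide, centered 1–4 ms from zero).
Synchronous units and their connected components (assemblies ≥ 2 units)
are built with networkx.

**Simulator.** Seeded generators for the trial table (contingencies
80/10/10 and 25/65/10, reinforcement 400–600 ms after cue offset), units
of each e-type, multiplicative event-response kernels, common-input and
synaptic-like couplings, and cue-dependent licking, with a
`ground_truth.json` alongside every bundle.

## Worked example

```
vpetypes simulate --seed 1 --out demo/bundle --n-trials 200
vpetypes run-all demo/bundle --out demo/results
vpetypes report demo/results
```

Output of the last command for this seed (abridged):

```
{
 "behavior": {"delta_hz": 3.906, "p": 1.91e-22},
 "n_assemblies": 2,
 "n_bursting": 6,
 "n_rhythmic": 10,
 "n_synchronous": 7,
 "n_trials": 200,
 "n_units": 20,
 "recovery": {"etype_label_accuracy": 1.0, "n_units_scored": 20}
}
```

Reading: the simulated animal licked 3.9 Hz more after the reward-
predicting cue (rank-sum p ≈ 2e-22); 6 of 20 units were labeled bursting
and 7 synchronous, forming 2 assemblies — including the injected 5-unit
common-drive group; and because the bundle carries ground truth, the run
reports that every unit's e-type label was recovered correctly. Full
per-unit tables (`etypes.csv`, `responses.csv`, `pairs.csv`, ...) are
written next to `summary.json`.

The same can be done from Python:

```python
from vpetypes import demo_config, simulate_session, classify_etype

session, truth = simulate_session(demo_config(seed=1, n_trials=200))
profile = classify_etype(session.spike_trains[0], duration_s=1500.0)
print(profile.burst_index, profile.rhythm_band)
```

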