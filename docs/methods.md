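# Methods

This note documents the analysis choices in `vpetypes`: what each stage
assumes, which parameters matter and why their defaults were chosen, what
the synthetic-data generator does and does not emulate, and where the
design was genuinely open.

## Conventions

All event times are seconds on one session clock; milliseconds appear only
on correlogram lag axes. Every binning window is half-open `[start, end)`,
so no event is counted twice at a bin edge. Correlogram lag bins are
centered on integer multiples of the bin width; the bin at lag `k·Δ`
covers `[kΔ − Δ/2, kΔ + Δ/2)`.

## Correlograms

The ACG counts ordered spike pairs in both directions, is symmetric by
construction, and has its zero-lag bin cleared (self-coincidences carry no
information; note this also removes genuine sub-half-bin pairs, which is
why the total-count invariant is stated excluding the zero bin). Defaults:
ACG 1 ms bins, ±500 ms window — wide enough to resolve the < 10 ms burst
peak, beta-period lags up to ~77 ms, and a long-lag baseline; CCG 0.5 ms
bins, ±50 ms — fine enough to resolve 1–2 ms synchrony features.
Implementation is sort-merge; correctness is defined by, and tested
against, exhaustive pair enumeration. Smoothing is a Gaussian kernel
(default SD 1 ms for index computation); kernel SD 0 is the identity.

## E-type indices

Both indices use `(P − B)/max(P, B)` with `B` the mean smoothed ACG count
at 180–200 ms lag. This form is bounded in [−1, 1], zero for a flat ACG,
and invariant to uniform count rescaling, so it compares across firing
rates. The burst peak range is 1–10 ms (the short-latency ACG peak that
defines bursting in extracellular work); band lag ranges are the period
ranges of beta (13–30 Hz) and gamma (30–100 Hz). The exact index formulas
used in the original analyses of this preparation are not published; this
reconstruction is a declared surrogate and every range and threshold is a
configuration key.

Thresholds: bursting at BI ≥ 0.2, rhythmic at RI ≥ 0.35, fixed from the
separation analysis below before cohort testing. A homogeneous Poisson
train's BI noise floor (max-of-10-bins bias over a 21-bin baseline mean,
after 1 ms smoothing) is ≈ 0.05–0.1 at 10 Hz × 1200 s, well under 0.2;
simulated bursters sit near 0.9. Rhythmic units generated as per-cycle
spikers reach RI ≈ 0.4–0.8; Poisson units stay ≈ 0.1. Units with fewer
than 100 spikes are excluded from the bursting label (too few pairs for a
stable short-lag peak). Burst and rhythm labels are independent: a fast
gamma unit whose period approaches 10 ms can legitimately carry both.

The rhythm frequency is `1000 / lag_peak` from the band-range ACG peak.
At 1 ms bins this quantizes frequency (~8% at 90 Hz), which is the main
contributor to the ≤ 10% recovery error and why the default gamma cohort
draws frequencies in 35–85 Hz rather than at the extreme band edge.

## Burst parsing

The ISI rule is applied with strict inequalities as stated (first ISI
< 10 ms, subsequent < 15 ms); a spike inside a burst cannot start a new
one. For event alignment a burst is represented by its first spike
("burst event train") — one event per physiological burst; an
all-burst-spikes mode exists because published analyses are ambiguous on
this point. The intra-burst cutoff is configurable up to 30 ms to
reproduce the slow-burst robustness variant. Burst/single dissociation
runs the standard response test on both derived trains at α = 0.01 and
combines directions; "opposite" requires both significant with opposite
signs.

## Event responses

Per-trial spike counts in baseline [−0.5, 0) s and response [0, 0.5) s
windows (rates, so windows may differ in length) are compared with a
two-sided Mann–Whitney U test. α = 0.001 for response classification,
the one level consistently attached to responsive-fraction claims in this
literature; no multiple-comparison correction across units is applied when
fractions are reported (fractions are descriptive), and this is recorded
in the output metadata. The response/baseline windows fit inside the
cue-to-reinforcement epoch (cue 0.5 s + 0.4–0.6 s delay); the exact
windows used in the original analyses are unpublished, so all are
configuration keys.

Latency is the time of the Z-scored PETH extremum (max for activations,
min for inhibitions) within [0, 0.6] s at 20 ms bins. A latency at this
resolution is meaningful only for responses with a sharp temporal peak;
for slow inhibitions the extremum time is intrinsically diffuse, which is
why the recovery tests assert latency accuracy on excitatory responses.

Expectation contrasts compute per-unit mean response-window count
differences between two outcome conditions and test the population of
differences with a two-sided Wilcoxon signed-rank; units with fewer than
5 trials in either condition are excluded (recorded, not fatal).

Omission responses are tested against *virtual* omission events placed at
cue offset + 0.5 s — the midpoint of the 400–600 ms reinforcement delay —
since nothing is delivered on omission trials.

## Behavior

The anticipatory window is cue onset to (virtual) reinforcement, per
trial, so it never overlaps consumption. Because trials of the two cue
types are unpaired, the default discrimination test is the rank-sum test;
a paired mode (k-th trial vs k-th trial, signed-rank) is provided for
comparability with analyses that paired trials, but the unpaired test is
the statistically defensible default. A session with no lick-rate
variation is reported as non-discriminating (p = 1) rather than an error.

## Synchrony

The null for CCG features is a spike-time jitter surrogate: each target
spike displaced uniformly within ±25 ms. This destroys coupling at and
below the 10–30 ms co-firing timescale while preserving slower rate
comodulation, making the bands a test of fine-timescale synchrony
specifically. Bands are pointwise 2.5/97.5 percentiles over 1000
surrogates; features must span ≥ 2 consecutive supra-band bins, a guard
against isolated exceedances among the ~200 bins tested. A false sync
label additionally requires the run to contain lag 0, which makes the
per-pair sync false-positive rate ≈ 0.1% at defaults (measured ≤ 5% bound
holds with large margin).

Width rules are applied to the FWHM of the above-chance excess (counts
minus the surrogate-band midpoint, lightly smoothed) around the run peak,
not to the raw run length: supra-band run length grows with peak
*strength*, whereas FWHM measures the physical peak width that the
narrow/broad distinction refers to. Narrow < 3 ms (the 2–3 ms gap between
the described "1–2 ms" narrow and "≥ 3 ms" broad classes is resolved to
narrow), monosynaptic ≤ 2 ms wide with count-weighted center 1–4 ms from
zero. Only excitatory (peak) features are classified; inhibitory troughs
are out of scope. Surrogates are seeded, so the whole pipeline is
deterministic given the configuration.

The implementation enumerates pairs once out to window + jitter and
re-bins them per surrogate (a jittered pair can enter the window only from
that margin), which is exact and makes 1000 surrogates cheap.

## Synthetic sessions

The generator reproduces the task conditions: equiprobable cues, outcome
contingencies 80/10/10 (likely reward) and 25/65/10 (likely punishment),
cue duration 0.5 s, reinforcement uniform 400–600 ms after cue offset,
omissions with no reinforcement, inter-trial intervals uniform 2–4 s plus
a 1.5 s post-outcome gap (cue duration and ITI are not published for this
preparation; these values give realistic session lengths of ~20 min for
300 trials).

Units: plain Poisson; bursting = Poisson burst initiations (default 2 Hz)
each carrying 1 + Poisson(2) extra spikes at uniform 3–8 ms intra-burst
ISIs (inside the < 10/< 15 ms parse rule with margin), superposed on 2 Hz
Poisson singles; rhythmic = at most one spike per oscillation cycle, fired
with probability `depth·rate/f` at a cycle clock whose period jitters as a
random walk (SD 2 ms per cycle), plus a `(1 − depth)` Poisson background.
The per-cycle model (rather than a sinusoidally rate-modulated Poisson) is
deliberate: a sinusoidal rate with modulation depth m yields an ACG
modulated by only m²/2, capping any peak-over-baseline rhythmicity ratio
at 1/3 regardless of m — weaker than what a peak-based classifier should
call rhythmic — and, unlike real fast-rhythmic units, lets two spikes fall
within one cycle. The per-cycle model produces the empirically observed
ACG shape: suppressed short lags (so rhythmic units are not mislabeled
bursting), a tall first-period peak, and peaks decaying over cycles as the
clock drifts (so the first-period band wins the argmax and the band label
is unambiguous).

Event responses are multiplicative rate kernels — alpha function
`(x/τ)e^{1−x/τ}` or boxcar, signed amplitude, clipped at zero — so
inhibition can never drive a rate negative; spike trains are produced by
exact thinning of a homogeneous envelope process. Couplings add correlated
spikes onto base trains: a shared Poisson drive copied into each member
with per-copy Gaussian timing jitter (an assembly spec generalizes the
pair spec to ≥ 2 units), or synaptic-like delayed extras (delay Normal
(2 ms, 0.3 ms), probability per presynaptic spike). Licking is piecewise-
constant-rate Poisson: baseline, cue-dependent anticipatory rate, and a
consumption burst after reward.

Everything is a deterministic function of (config, seed) via one numpy
SeedSequence; bundles re-simulate byte-identically.

### Default cohorts (study conditions for the recovery tests)

* Bursting cohort: 100 bursting (2 Hz bursts, μ = 2, 2 Hz singles) +
  100 Poisson (8 Hz) units, 600 s each.
* Rhythmic cohort: 6 beta (15–28 Hz) + 34 gamma (35–85 Hz) units,
  depth 0.8, 600 s.
* Coupling cohorts (1200 s, 5 Hz backgrounds): narrow sync — shared drive
  2 Hz, copy probability 0.3, copy jitter SD 0.5 ms; broad sync — 4 Hz,
  0.4, 3 ms (the broad drive is stronger because a 3 ms-jittered peak
  spreads its coincidences over ~6× more bins); monosynaptic —
  p = 0.15 per presynaptic spike at 2 ± 0.3 ms.
* Response cohort: 30 activated units (amplitude 2.5 alpha kernel,
  latency 50 ms, τ 40 ms — peak at 90 ms, on a 20 ms-bin center so the
  true latency is well defined at PETH resolution) and 30 inhibited units
  (amplitude −0.85, τ 100 ms, baseline 20 Hz: the rank-sum test detects
  suppressed spike mass ≈ |amp|·e·τ·rate, which requires a slow kernel
  and a high baseline at ~60 trials).
* Correlated-drive response cohort: 200 units in 25 groups of 8 (pairs
  are only tested within a group, as with tetrode bundles), 20 narrow-sync
  pairs whose members carry a reward kernel with probability 0.7 vs 0.25
  elsewhere.
* Depth-graded cohort: 200 bursting units whose burst-initiation rate
  falls linearly from 3 to 0.2 Hz across 0–1000 µm dorsoventral position
  (dorsal units burst more).

Cohort durations and sizes were chosen so each recovery statistic is
comfortably powered while the whole suite stays desk-scale.

### What the simulator does not emulate

Point-process surrogates only: no biophysical burst mechanisms, no
refractory periods on Poisson units, no spike-sorting noise or unit drift,
no session-to-session unit overlap, no omission-evoked dopamine-like
dynamics, no learning within a session (contingencies are stationary).
Passing recovery tests therefore demonstrates correctness of the analysis
chain under the stated generative assumptions, not robustness to every
failure mode of real tetrode data.

## Numerical notes

Exact duplicate timestamps after superposition are nudged apart by 1 ns to
preserve strict ordering; bundle timestamps are written with 9 decimals
(round trip ≤ 1 µs). Degenerate cases are explicit: zero baseline SD
(Z-scoring) flags the unit; an all-constant rank test reports p = 1; an
empty group in a 2×2 table raises a degenerate-table error; a constant
input to a rank correlation returns NaN with a warning.

## Known limitations

* The burst/rhythmicity index formulas and all statistical windows are
  reconstructions; absolute index values are not comparable to analyses
  using different definitions, though orderings and labels are robust to
  the threshold keys exposed in the configuration.
* Inhibition latencies at 20 ms bins are diffuse by nature; treat them as
  indicative only.
* The jitter surrogate conditions on slow rate structure; synchrony
  produced by comodulation faster than the jitter window but slower than
  the feature widths can in principle inflate band exceedances.
* The assembly graph uses transitive closure over pairwise edges; it does
  not test higher-order synchrony.
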