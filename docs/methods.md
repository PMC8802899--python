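# Methods

## Circuit model

### Neuron and coupling contract

All populations use the exponential integrate-and-fire (EIF) membrane
equation

    τ dv/dt = −(v − v_rest) + Δ_T · exp((v − v_thres)/Δ_T)

with v_rest = −70 mV, Δ_T = 1.48 mV, v_thres = −56 mV (the soft,
spike-initiation threshold) and τ = 3.3 ms. A membrane crossing
v_spike = −51 mV counts as a spike and resets to v_reset = −70 mV;
t_refractory defaults to 0 ms. The −51 mV cutoff sits just above the
equation's unstable fixed point (≈ −52.5 mV under these constants), so once
the exponential term takes over, a spike is inevitable and the cutoff's
exact value is immaterial. v_spike, v_reset and t_refractory are simulation
conventions, exposed in `NeuronParameters`.

Populations are coupled by rates, not by individual spikes: a connection
(efficacy ε mV, count n, delay d ms) delivers to each target neuron an
independent Poisson event stream whose rate is n × the source population's
firing rate delayed by d, each event stepping the membrane instantaneously
by ε. External inputs (background, cortical drive, three afferent channels)
enter through the identical contract; background rates are constant
(300 Hz to the interneuron pools and InhibRF, 320 Hz to the motor pools,
ε = 0.1 mV, n = 100) and the scheduled inputs are piecewise-linear in time.

### Monte-Carlo ensemble

Each population is simulated as an ensemble of independent neurons (default
500 per population; dt = 0.1 ms Euler steps; rates reported as spike counts
per 2 ms bin / (ensemble × bin width)). The instantaneous rate each
population presents to its targets is exponentially smoothed with a 1 ms
time constant before delivery — undamped per-step estimates inject
artificial feedback noise at small ensemble sizes — and delays run through
a ring buffer. One `numpy` generator seeded from the network seed drives
every draw in a fixed order, so equal specifications give bit-identical
output.

### Membrane noise and the operating point

With the published connection table and nothing else, the subthreshold
operating point is too deep for any activity: the mean background
depolarisation puts the motor pools near −59.4 mV with Poisson shot noise
of only σ ≈ 0.7 mV, about nine standard deviations from spike initiation —
every population is exactly silent, the interneuron afferent chain works,
but there is no baseline activity and none of the baseline-dependent
synergy structure. A population-density solver realises the same mean-field
contract but with its own effective diffusion; the event-driven ensemble
must model that diffusion explicitly. Each neuron therefore carries a
membrane-noise term σ·√dt·N(0,1) (`sigma_noise`, mV/√ms), representing the
synaptic and channel noise sources that the pure rate-coupling contract
omits.

σ was calibrated once, by a parameter sweep, to the circuit's described
operating regime — background input produces a low nonzero baseline rate
(a few Hz), the senFlInt→FlexorInterneuron response stays strongly graded
over 0–150 Hz, and every population stays within 0–200 Hz across all
condition presets — giving the default σ = 1.25 mV/√ms. At that point the
baseline is ≈ 7 Hz in the motor pools and ≈ 2–3 Hz in the interneuron
pools, and the position-1/0° preset drives the extensor pools to ≈ 40 Hz
while suppressing the flexor pools. One consequence of a nonzero baseline:
InhibRF is tonically mildly active, so MN-RF rests a few percent below the
other motor pools even with senInhRF = 0; the four pools without a
dedicated inhibitor are statistically indistinguishable.

### Condition presets

The cortical drive is a trapezoid: 0 → 20 Hz over 1 s, 5 s hold, 1 s down,
preceded by a 500 ms settling period that is excluded from all analysis
windows. Afferent inputs follow the same trapezoidal envelope scaled to
their plateau:

| position | angle | senFlInt | senInhRF |
|---|---|---|---|
| 1 | 0/20/60/90° | 150 / 75 / 38 / 0 Hz | 0 |
| 2 | 0/20/60/90° | 150 / 38 / 19 / 0 Hz | 0 / 50 / 50 / 50 Hz |

senExtInt is 0 Hz in every preset; it exists to flip the synergy-2 bias
(diagnostic runs use 15 Hz). The position-2 value at 60° (19 Hz,
continuing the halving pattern) and the 50 Hz senInhRF level are modelling
choices exposed in configuration; only the 0°→20° drop and the "slightly
greater in position 2" direction are fixed by the described behaviour.

## Synergy pipeline

Recordings are rectified, segmented into equal-length single-burst windows,
low-pass filtered per burst (4 Hz, second-order Butterworth, single-pass
causal by default; a zero-phase flag exists), decimated to a 100 Hz
envelope rate (the envelope carries nothing above the 4 Hz cutoff; the
analysis rate is an efficiency choice), clipped at zero against filter
undershoot, and row-normalized to unit maximum.

**Burst segmentation** detects onsets on a reference channel with a
hysteresis rule: onset threshold = baseline envelope mean + max(3 × SD of
the raw rectified baseline, 30% of the burst excursion); a burst starts
when the envelope crosses it and stays up 0.25 s, ends only after 0.5 s
below a lower offset threshold, and each onset is refined back to a 10%
low-threshold crossing. Because the protocol repeats identical
contractions at a fixed cadence, the per-burst estimates are snapped to the
best-fitting periodic grid (Theil–Sen slope, inlier refit). If detection on
the first channel does not yield the expected count, the remaining channels
are tried in order. At the default generator noise the detector's onset
error is ~120 ms median, ~250 ms at the 95th percentile, with occasional
300–600 ms excursions in weak-amplitude conditions.

**Channel QC** drops channels whose 1 Hz-envelope 90th/10th percentile
ratio falls below 2.0 — electrodes that never rise above their own
baseline, like the discarded calf/shin channels the cohort can emulate.

**NMF** minimises ‖D − WC‖²_F by multiplicative updates from a
nonnegative-double-SVD start (exact zeros filled with a small ε so updates
can repopulate them), stopping at a relative objective change < 10⁻⁶ or
10,000 iterations. The initialization is deterministic, so identical input
gives identical synergies; components are ordered by energy so synergy 1 is
always the dominant coactivation pattern. Multiplicative updates converge
linearly and stall near optima: an exactly rank-2 matrix is recovered to a
VAF deficit of ~10⁻⁵, not machine precision. VAF is uncentered
(1 − SSE/SST), globally and per muscle row — baselines are meaningful
activity here, so centered R² would be wrong. Rank selection scans 1..5
ascending and returns the first rank with global VAF ≥ 0.90; a selection is
flagged discarded when no rank reaches the threshold or a per-muscle VAF
stays below it (both thresholds 0.90; the description gives only "below
90%"). `normalize_synergies` rescales W columns and C rows to unit maximum
for cross-subject comparison — this deliberately breaks the product WC,
and energy-based quantities (e.g. the cancellation check) must use the
unnormalized decomposition.

**Identifiability.** NMF recovers the extreme rays of the data cone, not a
unique basis: a burst built as b·baseline + a·trapezoid equals
(a+b)·trapezoid + b·(1 − trapezoid), and which pair the updates return
depends on the noise. Recovery of the generator's latent templates is
therefore judged in the span sense — the cosine between a template and its
best nonnegative reconstruction from the fitted components — except where
the data contain near-pure rows, where direct greedy cosine pairing is
meaningful.

## Synthetic cohort

One recording per (subject, position, angle) holds six bursts
(0.5 s ramps, 5 s plateau, 2 s gaps, 1 s lead) of five channels at 2 kHz:

    x(t) = (b + a · trapezoid(t)) · m(t) · ξ(t)

with per-condition plateau amplitude `a` and baseline `b` (arbitrary
units), a mean-one lognormal slow drift m(t) (σ = 0.2, 3 Hz knots,
independent per channel) for effort nonstationarity, and a unit-variance
Gaussian carrier ξ(t) band-limited to 10 Hz. The carrier bandwidth is the
load-bearing realism choice: white noise at 2 kHz averages to an
implausibly clean envelope under the 4 Hz filter, whereas the band-limited
carrier leaves the ~30% stochastic envelope fluctuation that maximal-effort
recordings show — which is exactly what holds a rank-1 factorization below
the 90% VAF threshold (rank-1 ≈ 0.87, rank-2 ≈ 0.92 on average) so that
the minimum-rank rule lands on two synergies, as it does on the real data.
Both noise parameters were calibrated once against that published VAF
structure and then frozen. Setting `carrier_cutoff_hz=0` and `drift_sd=0`
recovers the clean closed-form regime (rectified plateau mean
(a+b)·√(2/π)).

The trend table (`default_trend`) encodes the reported contrasts as ratios
(units are arbitrary — sEMG amplitudes are not comparable across muscles):
quadriceps amplitudes fall ~30% from 0° to 20° and ~36% from 20° to 60° in
position 1; in position 2 the whole ~55–65% drop happens by 20°; RF runs
~25% lower in position 2 at flexed angles; ST roughly doubles its weak 0°
activity by 20° and keeps a raised baseline in position 1 away from full
extension. Hamstring baselines sit near their (weak) contraction levels —
ST at 0° is largely baseline — which is what loads the second synergy onto
the antagonists at low angles. Subject heterogeneity is a lognormal
per-subject-per-muscle gain (σ = 0.2) constant across conditions, like an
electrode/anatomy factor.

What the generator does **not** emulate: motor-unit discharge structure and
its spectral detail, volume conduction and electrode crosstalk between
muscles, fatigue across the session, movement artifacts, and any
within-burst temporal strategy differences between muscles. Passing tests
therefore show that the analysis chain recovers the encoded amplitude/
baseline structure under realistic envelope noise — not that it would be
robust to every artifact of real recordings.

## Statistics

Contraction activity is the mean of the central 4 s of each burst envelope
(window anchored to the burst-window midpoint; shortened to the plateau
duration for briefer synthetic bursts), averaged over a condition's six
bursts so the subject is the unit of observation. Condition comparisons are
two-sided Welch t tests (α = 0.05) on adjacent angle pairs within position
and between positions within angle; a pooled-variance flag exists. No
multiple-testing correction is applied, matching the original reporting;
the output records raw p-values. The trend checklist reduces each reported
qualitative finding to a boolean computed from these contrasts and from the
model decompositions; "synergy 2 eliminated" means its reconstruction
energy share is < 1% or its contribution vector is flat across muscles
(CV < 0.1, configurable).

## Numerical choices and degenerate inputs

- EIF exponent clamped at 20 (anything that far past threshold spikes
  within the step); drift stays finite for any finite v.
- dt = 0.1 ms: a tenfold refinement changes single-population rates by
  < 1% (the suite checks 5%).
- Schedules are held at their final rate beyond their last breakpoint.
- NMF denominators carry an ε = 10⁻¹²; all-zero muscle rows stay zero and
  get zero weights; an all-zero matrix has no defined VAF and is rejected.
- Zero vectors are rejected in cosine similarity; max-normalization maps
  all-zero rows/columns to themselves.
- Rank-selection ties: the ascending scan takes the first rank over
  threshold. Component pairing across decompositions is greedy by cosine.
- Seed fan-out: per-stage seeds are SHA-256 hashes of
  (master seed, stage, keys), below 2³¹, so any stage reruns in isolation.

## Problem sizes in the test suite

The acceptance checks run a single 7.5 s simulation at 500 neurons per
population for the rank-2 VAF target, the eight presets at 200 neurons for
the rate-range and trend properties, ten 1.5 s background-only runs at 100
neurons for the symmetry property, and the full 17-subject cohort (816
bursts) for rank selection; the statistical-recovery property uses five
cohort seeds and requires the full significance pattern in at least four.
These sizes are the package's chosen desk-scale defaults; the ensemble size
and durations are ordinary parameters.

## Known limitations

- The membrane-noise amplitude stands in for the original solver's
  unreported effective diffusion; absolute firing rates depend on it, and
  only the qualitative structure (baseline present, graded afferent
  response, 0–200 Hz range) constrains its value.
- The agonist-bias flip under senExtInt = 15 Hz is a small effect riding on
  a near-cancelled second synergy; its sign is stable at the default
  ensemble sizes but its magnitude is noise-limited.
- Welch tests treat positions as independent groups although the design is
  within-subject; this is the more conservative reading of "two-sided
  t test" and can be switched to pooled variance but not to a paired test
  without changing the published analysis.
- The burst detector assumes trapezoid-like bursts at a roughly regular
  cadence; irregular protocols would need the periodic-grid snap disabled.
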