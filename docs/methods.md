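# Methods

This note documents the estimators, the synthetic study conditions, and the
conventions behind every number the test suite and `scripts/acceptance.py`
compute. It states no result that those runs do not themselves produce.

## Estimators

**Memory-less streaming median (NM).** State is a sorted buffer of odd
length L = 2m + 1 plus one tie bit; the estimate is the element at index m.
For a full buffer and a new sample x:

* x < estimate: x is inserted after any equal values (the position of the
  first element exceeding x) and the last element (maximum) is dropped;
* x > estimate: symmetric — stable insertion on the right, the first
  element (minimum) is dropped;
* x = estimate (exact binary equality; no epsilon band, mirroring a
  hardware comparator): x takes the center, and the tie bit selects whether
  the first or the last element is dropped. The default is a single
  alternating bit; a seeded random bit (`tie_break="random"`) implements
  the alternative reading. Either choice balances the two branches, which
  is what keeps the estimator unbiased.

Dropping the extreme *opposite* to the insertion side means the buffer
population continuously migrates toward the center. The equilibrium
argument is a flux balance: if the central value sits below the true
median, more than half of incoming samples fall above it, the surplus
insertions on the right push the center up, and vice versa; the drift
vanishes exactly when half the probability mass lies on each side, i.e. at
the true median. The test suite checks this as a statistical property
(mean steady-state error = 0 within 3 standard errors over 5,000 runs, on
both a Gaussian and a skewed Beta input).

**Warm-up.** Before L samples have arrived the buffer is a sorted partial
list and the reported estimate is its lower middle element. All experiment
drivers treat the fill as part of the stream.

**Classical moving median (CMM).** The exact median of the last L samples;
eviction strictly by arrival age, stable insertion. Equal values are
interchangeable in a multiset, so any eviction among duplicates leaves the
window median exact; correctness is pinned by an exact equality test
against a brute-force re-sort-every-window oracle (10⁴ samples, several L).

**Non-finite samples** (NaN/Inf) are rejected with an error: the sorted
buffer needs a total order, and silently ordering NaNs would corrupt it.

**Hardware cell model.** `MedianCellArray` is a truth-table-level model of
the sorting register array used by hardware implementations: per-cell
comparators C_i = (R_i > X), a full three-way comparator at the central
cell, and a per-cell 4-input multiplexer (keep, take X, take left
neighbour, take right neighbour). The boundary cells see hard-wired
neighbour comparators (0 on the left end, 1 on the right end). The model
is asserted bit-identical to `NMEstimator` over 10⁴ lockstep steps with
shared tie decisions, on a discrete value grid so that ties actually occur.

**Quartile cascade.** Three NM estimators: the primary sees every sample;
each sample is also routed to the lower (upper) estimator when it falls
below (above) the primary's current estimate, read *before* the sample is
consumed. A sample exactly equal to the estimate follows the primary's tie
branch (to the lower cascade when the primary dropped its maximum). The
routing threshold is itself an estimate, so the sub-estimator inputs are
only asymptotically the conditional half-distributions; on uniform(0, 1)
input the cascade settles within Monte-Carlo tolerance of (0.25, 0.5,
0.75).

**Performance.** Per-sample updates are pure Python (bisect on a list); the
`stream()` path runs a numba kernel with identical semantics — the suite
asserts exact sample-by-sample agreement between the two, including tie
handling. Throughput is roughly 10⁷ updates/s at L = 63, which is what
makes 10⁸-update Monte-Carlo runs practical on one core.

## Noise sigma and detection

For Gaussian noise, median{|x|} = σ·Φ⁻¹(3/4) = 0.674490·σ (the constant
prints as 0.675 at three decimals). `streaming_threshold` feeds |x| through
the configured estimator and reports K·median/0.674490 per sample, K = 4 by
default. The folded signal is what the estimator consumes; for
negative-going detection the threshold magnitude is applied to −x.

Event extraction is deliberately simple: an event opens at the first
crossing, the event index/peak are the extremum before re-crossing, and an
excursion opening within `refractory` samples of the previous peak is
suppressed (default 30 samples ≈ 1 ms at 30 kHz). Detection is scale
equivariant: scaling the signal scales the thresholds and leaves event
indices unchanged.

## Synthetic study conditions

* **Step streams** — i.i.d. samples whose distribution switches once; true
  medians come from the families' quantile functions (Beta(1.5, 4) →
  0.2439, Beta(4, 1.5) → 0.7561, |N(0, 1)| → 0.6745), never from the
  realised samples.
* **Spike-embedded noise** — white Gaussian noise with biphasic templates
  (sharp sin² trough ~0.3 ms, shallow rebound, 1.2 ms total at a nominal
  30 kHz) scaled so the planted peak equals snr·σ; 2 events per 1,000
  samples by default, minimum gap one template width, planted positions
  returned as ground truth. This stands in for a real recording: it has no
  1/f background, electrode drift, or overlapping units, so detection
  results here bound the easy part of the problem (stationary noise,
  known waveform), not real-recording performance.
* **Contamination mixtures** — primary N(0, 1) plus an outlier component
  N(0, 10) at probability 0.05 (defaults chosen as a heavy but plausible
  artifact rate; all three parameters are configurable), labels retained.

Every generator is deterministic given its seed; per-repetition seeds are
spawned from one master seed via `numpy.random.SeedSequence`.

## Experiment conventions

* **Settling time**: first touch of μ_f − 0.05·(μ_f − μ_i) after the step,
  direction-aware, in samples; not-settled runs are NaN and excluded from
  means (run lengths are chosen so these are rare). First touch rather
  than sustained crossing because the trajectories are noisy; any
  sustained-crossing rule would need an arbitrary dwell parameter.
* **Initialization of step experiments**: the buffer is freshly filled
  with pre-step samples and the step follows immediately (`n_before = L`).
  The alternative — a long pre-step run — deepens the NM buffer's
  compression and lengthens its settling by ~10–15%; the fill-moment
  convention is the one used for the buffer-dynamics analysis and is
  applied uniformly to all settling comparisons. Sensitivity to this
  choice is the main caveat on settling-time ratios.
* **Steady state**: the first 10·L estimates of a run are discarded;
  `steady_state_variance` pools the remaining estimates across
  repetitions (a time-and-ensemble variance). The final-value error
  distribution (`error_distribution`, the step-experiment error) is a
  separate quantity: across-repetition variance of the last estimate,
  default run length 20·L.
* **ROC for small median changes**: the input median steps from m to
  m·(1 + δ) at unchanged spread (base N(8, 2)); one estimator reading is
  taken per repetition just before the step and again 20·L samples after
  re-convergence; sweeping a decision threshold over the two ensembles
  gives the curve, whose area equals P(post-change reading > pre-change
  reading). The decision statistic (a single estimator sample) is a
  design choice — it measures how well the estimator's output distribution
  separates, which is the quantity of interest.
* **Buffer density**: histograms of buffer contents at requested times
  (t = 0 is the moment the buffer fills), averaged over repetitions, with
  a common bin grid from the generating distribution's 0.05–99.95%
  range; the mean interquartile width of the buffer contents tracks the
  compression.
* **Repetition counts**: desk scale — 5,000 for the headline step
  experiment, 2,000 for variance ratios, hundreds for density/ROC — sized
  so the whole suite runs in minutes while keeping Monte-Carlo error well
  inside the asserted tolerances.

## Known limitations

* The NM estimator trades bias-free tracking for a *state-dependent*
  response time: settling after a change depends on how compressed the
  buffer has become, so settling times quoted here are tied to the
  fill-moment initialization above.
* Exact-equality tie handling means that on coarsely quantised inputs
  (e.g. raw int16 at low amplitude) the tie branch fires often; the
  alternating bit keeps this unbiased but the random mode may be
  preferable if the input is adversarially patterned.
* The quartile cascade's outer estimators converge more slowly than the
  primary (they only see ~half the samples, routed through a moving
  threshold).
* `sliding_median_oracle` is O(n·L log L) by construction; it is a test
  oracle, not a production path.
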