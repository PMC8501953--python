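# Methods

## The measurement being modelled

A droplet cytometer encapsulates single cells in ~500 pL aqueous
droplets together with an RT-LAMP amplification mix, incubates them, and
reinjects them past a laser at ~300 droplets per second. Each droplet
produces a plateau in the multi-channel photodetector trace; its
per-channel mean fluorescence reports cell presence (a live-cell stain)
and per-marker amplification. `dropgate` implements everything after the
photodetector: event extraction, the gating cascade, detection-power
statistics, molecular logic readouts, and qPCR-based enrichment
validation — with a synthetic-data generator that supplies ground truth
for all of it.

## Synthetic droplet generator (`dropgate.simulate`)

Cell loading is Poisson: dilution loading physically randomises cell
arrival, so the per-droplet cell count is Poisson(λ) with the default
λ = 0.105 chosen so that P(≥1 cell) = 1 − e^(−0.105) ≈ 0.0997 — about
one occupied droplet in ten, the regime the gating cascade assumes.
Doublets are generated and recorded; a multi-cell droplet's marker state
is the OR of its cells' states and its stain the sum of their stains.

Per-marker amplification is Bernoulli: probability `expression[marker]`
for an occupied droplet of a given class, `fpr_per_marker` (default
2×10⁻⁴) for an empty one. The false-positive mechanism is modelled at
event level; nucleus-like spike artifacts — short high-amplitude
transients inside a droplet, a known physical source of false positives —
are available separately (`spike_rate`, default 0; amplitude 5× the
amplification signal) so the two mechanisms are never double-counted and
the empty-droplet positive rate converges exactly to `fpr_per_marker`.

Fluorescence is `empty_baseline` (100 a.u.) plus `amp_signal`
(1000 a.u., i.e. 10× baseline) on amplified marker channels plus the
stain level on the stain channel, mixed through an optional spillover
matrix (observed = S·true, unit diagonal), plus per-channel Gaussian
noise (σ = 5 a.u.). The 10× amplification contrast makes the 2.8×-median
thresholds cleanly separating by default; both knobs are configurable to
study overlapping populations. Droplet durations are lognormal (mean
100 samples, CV 0.10) — strictly positive and right-skewed; no
distributional claim is attached beyond that. Traces interleave
plateaus with near-zero oil gaps sized from the 300 Hz droplet rate and
a 100 kHz sampling rate. Everything is reproducible from one seed.

What the generator does **not** emulate: amplification kinetics (marker
states are binary endpoints), baseline drift, droplet coalescence or
size–signal correlations, optical peak shapes, and autofluorescence
spectra. Tests passing on this generator show the *processing* is
correct under the stated statistical assumptions, not that real
instrument data satisfies those assumptions.

## Event detection (`dropgate.trace`)

Events are maximal runs of detection-channel samples **strictly above**
a fixed threshold (samples equal to the threshold are oil), half-open
`[start, end)`, 0-based, kept when at least `min_width` (default 3)
samples long — a debounce against single-sample noise crossings. There
is no hysteresis or dual threshold. Spikes inside a droplet are not
split into separate events; they raise the event mean, and an optional
per-event max/mean ratio (off by default) exposes them to downstream
filtering. Equivalence with a brute-force per-sample labelling is a
tested invariant.

## Gating cascade (`dropgate.gating`)

Fixed order: compensate → size gate → cell gate → amplification
thresholds from the empty population → down-sample cells → classify.
The empty population is defined as the stain-negative survivors of the
size gate, and thresholds are computed *before* down-sampling so they do
not depend on the random subset. Numerical conventions: trim count per
tail is `floor(trim·n)` with duration ties broken by droplet id; the
median of an even-sized set is the mean of the two central values;
compensated fluorescence may go negative and is not clipped (clipping
would bias the empty-droplet median upward). The cell gate is a
programmatic fold-over-median rule (default 2.8, the same constant as
the amplification rule) replacing manual gating for reproducibility.
The cascade is conservative by construction: every input event is
retained or attributable to exactly one removal step, and the report
logs each count.

The fold-over-median gates presuppose the mostly-empty loading regime;
at occupancies well above ~50% the all-event median migrates onto the
occupied population and the stain cutoff loses meaning. This is a
property of the median-anchored rule, not of the implementation.

## Rare-cell detectability (`dropgate.rarecell`)

For `n` cells at positive prevalence `q` with per-cell rates TPR/FPR,
the expected positive count is `n(1−q)·FPR + nq·TPR`. Detection tests
the rounded expected count against the pure-negative null
Binomial(n, FPR). Conventions: the test is one-sided upper-tail
(detection means an excess of positives; a two-sided variant is a flag);
non-integer expected counts round half-up; tails are exact binomial sums
(scipy), with the continuity-corrected normal approximation kept only as
a cross-checked invariant (agreement within 0.01 for null means ≥ 20).
The default limit-of-detection grid is one point per decade,
10⁻⁶ … 10⁻². With TPR 0.971 / FPR 2×10⁻⁴: 10,000 cells detect 10⁻³
(p ≈ 1.4×10⁻⁶) but not 10⁻⁴ (p ≈ 0.32); 100,000 cells detect 10⁻⁴
(expected 30 positives vs null mean 20, p ≈ 0.022).

`simulate_mixture_series` draws positives as
Binomial(n_pos, TPR) + Binomial(n_neg, FPR) per mixture point and fits
ordinary least squares of measured on true proportion; the expected
slope is TPR − FPR by linearity, and at 10,000 cells per point R²
rounds to 1.00.

## Molecular logic (`dropgate.logic`)

Gates: YES (transducer pass-through), NOT (transducer output displaces
an unquenched fluorophore), OR (two transducers, identical output
strand, levels add), AND (a stoichiometric threshold strand sequesters
output; only the excess past it reports), AND-NOT (asserted branch minus
inverting branch). AND-NOT is a primitive, not sugar for AND + NOT.

The signal model is an equilibrium *level* model — sums, threshold
subtraction, floors at zero — chosen to reproduce the described
mechanisms; it makes no kinetic claims. Each gate reads its inputs
through its own transducer stage, which restores the incoming level to
`on_level`/`leak` according to the upstream ON/OFF call. This mirrors
the molecular architecture (each layer releases a discrete output strand
that does or does not trigger the next stage) and is what makes
signal-level calls extensionally equal to Boolean evaluation at any
circuit depth under the default parameters — a purely additive cascade
would degrade: two stacked AND gates at ON level 0.8 would sum to 1.6,
fall below threshold + cutoff, and mis-report.

Defaults (`on_level` 1.0, `leak` 0.05, `and_threshold` 1.2,
`detect_cutoff` 0.5) are chosen so Boolean semantics hold with margin;
measured chemistry ON/OFF ratios are not fitting targets. A leak at or
above the cutoff is permitted (with a warning) precisely so the
false-ON failure mode can be constructed and studied. The expression
grammar gives unary NOT/YES highest precedence, then AND / AND-NOT
(left-associative), then OR.

## Enrichment (`dropgate.enrichment`)

Fold enrichment uses base (1 + E) with efficiencies on the 0–1 scale
(E = per-cycle fold increase − 1), reducing to the classical 2^(−ΔΔCt)
at E = 1. Callers pass replicate-averaged Cts (`dropgate.io.mean_ct` is
the reducer); no averaging happens inside the formula. Standard-curve
efficiency comes from the OLS slope s of Ct against log₂(relative
concentration): E = 2^(−1/s) − 1, clipped to [0, 1] with a warning —
robust regression is out of scope.

## Pipeline and problem sizes

All randomness flows from a single seed, split per stage with
`numpy.random.SeedSequence`. The test suite and acceptance script run
their simulations at 10⁴–3×10⁵ droplets and 10⁴ cells per mixture
point — sizes at which binomial standard errors are a few parts per
thousand, tight enough for 3-SD checks against closed forms while
keeping the whole suite in seconds on one core. Statistical assertions
use 3-SD binomial bounds (occasionally widened by a small deterministic
allowance where doublets bias the target rate); exact computations
(binomial tails, truth tables, compensation, enrichment) are asserted to
numerical precision.

## Known limitations

- The generator's amplitude parameters (baseline, 10× signal, stain
  levels, noise) are calibration knobs, not measured claims; only the
  rate structure (loading, TPR/FPR, occupancy) is anchored.
- The logic signal model is phenomenological; it cannot predict ON/OFF
  ratios, incubation-time leak growth, or crosstalk between gates.
- The binomial detectability model treats cells as i.i.d.; clumping,
  sorting losses, and droplet-level correlations are outside it.
- FCS export is not provided; event tables travel as CSV.
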