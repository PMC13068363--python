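# Methods

`protomorph` analyses the electrochemistry and morphology of
proteinoid–olivine hybrid systems: long galvanostatic potential logs with
spontaneous bursty oscillations, impedance time scans that are transduced
into Boolean logic, cyclic- and differential-pulse voltammetry during
electrode conditioning, and SEM-style images of dendritic self-assembled
structures.  This note records the models, conventions and numerical
choices behind each stage, what the synthetic generators do and do not
emulate, and the known limitations.

## Impedance model and conventions

Impedance is stored per record as (|Z|, φ, Z′, Z″, C_s, f) with
|Z| = √(Z′² + Z″²) and φ = atan2(Z″, Z′).  The package follows the
capacitive-system convention Z(ω) = Z′ − jZ″ = |Z|·e^{−jφ}: the record
keeps a *positive* Z″ for capacitive behaviour and exposes the displayed
phase as −φ (`neg_phase_deg`).  This is the only convention under which a
tabulated positive Z″ (≈0.38 Ω) and a displayed mean phase of ≈−1.17°
coexist, so both columns of a summary table are reproducible from one
record.  Series capacitance is C_s = 1/(2π f Z″); a negative Z″ yields a
negative C_s, which is reported as-is — negative-capacitance spikes are a
diagnostic of transient responses and are never silently filtered.

The equivalent circuit is a Randles cell, Z = R_s + R_ct/(1 + jωR_ct·C_dl),
used in forward evaluation only.  It traces a semicircle in the (Z′, −Z″)
plane whose apex −Z″ = R_ct/2 occurs at ω = 1/(R_ct·C_dl); this identity is
asserted to 1e−6 in the tests.  Fitting circuit parameters to measured
spectra is out of scope.

Units: ohms internally everywhere; readers accept kΩ columns behind an
explicit unit tag, and the logic threshold default of 0.14 kΩ is stored as
140 Ω.  Voltage channels carry mandatory unit tags; mV series are converted
to volts before any squaring (a silent mV/V mixup is a 10⁶ error in
energy).

Summary tables report count, mean, n−1 std, min, the quartiles and max per
channel, with quantiles by linear interpolation between order statistics;
the trailing "mod |Z|" column duplicates |Z| for layout compatibility.

## Threshold logic transduction

A |Z| trace is binarised with an *inclusive* threshold (bit = 1 iff
|Z| ≥ θ, default θ = 140 Ω), which makes binarisation monotone in θ.
Temporal gate inputs pair consecutive bits: A is the current sample, B the
previous one; the first sample is dropped rather than padded (padding B = 0
would fabricate an initial XOR spike).  All six channels (AND, OR, XOR,
NAND, NOR, NOT A) are evaluated elementwise; the number of XOR = 1 samples
equals the number of rising plus falling edges, and maximal constant runs
are reported as plateaus — the "memory" segments of the record.

`suggest_threshold` supports the analyst's choice: it finds the widest
empty-bin gap between the two dominant clusters of a 20-bin histogram and
returns the gap midpoint together with the median and the fraction of
samples above, so a "just below the median" heuristic can be applied
deliberately.  Effectively unimodal data (gap score below 5% of the range)
fall back to the median with a degenerate flag.

## Oscillation statistics

Default detrending is a centred rolling median over 2001 samples at 1 Hz
(long against the ≈176 s interevent scale, so burst pulses are preserved);
polynomial detrending up to degree 5 is available for records with smooth
drift.  Peaks and troughs come from topographic-prominence detection with a
minimum separation of 5 s; the default prominence is half the standard
deviation of the detrended signal, a rule for signals of unknown noise
level.  For recovery tests against planted events the prominence is set to
five times the generator's noise standard deviation (0.1 mV) — when the
noise floor is known by construction, tying the detection threshold to it
is the principled choice.

Alternation is enforced by keeping the extreme value inside any same-type
run.  Counting conventions: n peaks yield n−1 interpeak periods;
peak-to-trough amplitudes (peak value minus the mean of the two adjacent
trough values) are defined for interior peaks only, yielding n−2
amplitudes — the 511/510/509 counting structure of a long record holds on
every run.  Frequencies are elementwise reciprocals of periods.
Descriptive statistics use n−1 std, linear-interpolation quantiles, and
kurtosis in the Pearson convention (normal = 3), switchable to excess
kurtosis.

Two distributional null tests probe whether interevent timing is
memoryless:

- **Shifted-exponential K–S.**  loc = min(periods), scale = mean − loc
  (method of moments), one-sample K–S with the asymptotic p-value.  With
  parameters fitted from the same data the asymptotic p-value is
  conservative (the Lilliefors effect) — measured type-I error ≈ 0 — so
  calibration studies pass the known true (loc, scale), under which the
  test is exact and the measured type-I error sits at ≈4.5% for a nominal
  5%.  The analysis default remains the moment fit.
- **Poisson χ² on binned counts.**  Events are counted per 2 s bin; λ̂ is
  the mean count; count categories are pooled from the upper tail until all
  expected frequencies reach 5; df = categories − 2 (normalisation plus
  the estimated λ̂), floored at 1 for very sparse regimes that pool down to
  two categories.

The autocorrelation summary uses the biased normalisation (divide by n and
the lag-0 variance); the decay timescale is the first 1/e crossing located
by linear interpolation, and the dominant frequency is the argmax of the
squared real-FFT magnitude with DC included — a drifting record therefore
correctly reports a 0 Hz dominant component.

## Landauer accounting

E_L(T) = k_B·T·ln 2 with the CODATA value k_B = 1.380649×10⁻²³ J/K
(2.853×10⁻²¹ J/bit at 298.15 K; slope k_B ln 2 = 9.57×10⁻²⁴ J/(K·bit)).
Dissipated energy is the trapezoidal integral of V(t)²/R_eff; per-event
energy divides by the number of detected peaks, and the ratio to E_L is
reported per effective-resistance regime.  When one driving integral
∫V² dt is shared across regimes, E_total scales as 1/R and the report's
rows are mutually consistent under that scaling (asserted within 1%).
The temperature sweep is `landauer_limit` mapped over a range, not a
separate operation.

## CV conditioning and information metrics

Per-cycle CV metrics are the current extrema and the signed loop area
AUC = ∮I dE (trapezoid over the recorded sweep order, loop closed
explicitly); a transient negative AUC needs no special casing.  Sweeps
whose endpoints differ by more than 1% of the potential range are flagged
open, not rejected.  Conditioning of the peak magnitude is fitted by
nonlinear least squares to A·e^{−k·cycle} + c with initial guesses from the
value range, the minimum, and the log-slope between first- and
last-quartile means; the converged flag reflects the optimizer status
honestly.

Information metrics discretise each per-cycle series into 8 equal-width
bins over its range and use plug-in (histogram) entropies.  The entropy
rate is H(X_t | X_{t−1}, …, X_{t−k}) = H(k+1 joint) − H(k joint), default
k = 1.  Transfer entropy TE_{Y→X} is the corresponding conditional mutual
information (defaults k = l = 1).  Plug-in TE is biased upward in any
finite sample, so a bias floor is estimated from 20 circular rotations of
the source by random offsets — rotations break cross-channel alignment
while preserving the source's own serial structure, which matters for
strongly autocorrelated conditioning series.  The raw estimate is reported
only when it exceeds the largest surrogate by a conservative 25% margin;
otherwise the flow is indistinguishable from estimator bias and 0.0000 bits
is reported with the floor attached.  Genuine coupling (e.g. a copy
channel carrying 1 bit) sits orders of magnitude above the floor, so the
margin costs sensitivity only at the resolution limit.  Because the
absolute entropy-rate value depends on the binning choice, it is treated as
a relative diagnostic, not a reproduction target.

DPV analytics report the global peak current and its potential and the
trapezoid AUC over the full −4..+4 V window (the active-window-only
alternative is not taken; the choice is visible in the AUC magnitude).
The AUC–amplitude relation is fitted by OLS on (1, E, E²) with RSS, TSS
and R² = 1 − RSS/TSS reported.  The theoretical pulse peak current is
implemented as I_p = n·F·A·C·√(D/(π·t_p))·ΔE/2 — the standard
Cottrell-type form; the flat-text rendering of this expression elsewhere
omits the square root and is dimensionally inconsistent, so the standard
form is used.

## Synthetic generators

All generators are bit-reproducible for a fixed seed and return their
planted ground truth so downstream recovery is testable without any
external data.

**Burst potential log.**  93,000 s at 1 Hz: a linear drift
(5×10⁻⁴ mV/s) plus a gamma-renewal train of burst pulses plus white
Gaussian noise (sd 0.02 mV, a realistic figure for mV-scale data logging).
Interevent gaps are gamma with shape 3 and mean 176 s — over-dispersed yet
non-exponential, matching the non-memoryless timing the null tests are
built to detect.  Pulses are one-sided exponentials with a 10 s time
constant (the simplest shape preserving peak-to-trough structure);
amplitudes are lognormal (median 1 mV, log-sd 1) under an envelope decaying
with a 60,000 s constant, which damps typical excursions below 5 mV late in
the run.  One deterministic 60 mV burst is planted at t = 5000 s to emulate
the early activation transient.  The generator matches the statistical
structure of such records — drift, heavy tails, renewal clustering,
progressive damping — but not any particular measured trace: passing
recovery tests shows the pipeline recovers events of this structure, not
that it reproduces a specific experiment.

**Three-phase impedance scan.**  30 cycles at 699 s intervals, 1000 Hz:
|Z|(t) ramps linearly 0.072→0.082 kΩ over 2500 s, rises along an
endpoint-normalised logistic to 0.162 kΩ at t = 6291 s (cycle 9 exactly on
the sampling grid), then relaxes exponentially toward 0.139957 kΩ with time
constant (settle − peak)/10.  The settle asymptote is deliberately a hair
below the 0.14 kΩ logic threshold so the noise-free trajectory produces
exactly one rising and one falling transition — the single
activation/deactivation cycle the logic stage is designed around.  Phase
interpolates 11.4→17.0→14.2°; Z′/Z″ follow from |Z| and φ, with any |Z|
noise applied before the component split so |Z|² = Z′² + Z″² holds exactly
on every record.

**Voltammetry fixtures.**  CV: per-cycle peak magnitude follows
1531.22·e^{−0.1889·cycle} + 58.43 μA (optional multiplicative noise), with
full triangular sweeps carrying Gaussian cathodic/anodic features (anodic
fraction 812/1553) so cycle-metric extraction runs end to end.  DPV: AUC
follows 0.0725·E² + 0.5165·E + 0.0070 mA·V (optional additive noise); each
curve is a Gaussian feature near −0.3 V whose height is the planted peak
current (0.42 + 0.13·E mA, inside the observed 0.4–0.55 mA window) and
whose width is set so the trapezoid AUC matches the planted value.

**Dendrite generator.**  A stochastic recursive branching model: each of
k = 2 children turns by the ±25° base half-angle plus uniform jitter
(±12°) and shrinks by a factor drawn from U(0.68, 0.82); segment width
tapers at 0.3× segment length, rendered with round caps by thresholding a
Euclidean distance transform of the 1-px midpoint-stepped centrelines
(stroke widths quantised to powers of two).  The base angle, trunk length,
branching factor and taper are declared model choices.  At depth 8 the
rasterised canopies measure a box-counting dimension of ≈1.70 (mean over
10 seeds, 1024² images), inside the biological dendritic-arbor range
1.7–2.1, and the mean dimension increases monotonically with recursion
depth 6→10.  A line-segment tree cannot reach the ≈1.9–2.0 measured for
real mineral-templated structures at this depth without physically
implausible stroke widths; the generator is a topology/complexity testbed,
not a replica of any specific micrograph.

## Morphometrics

Segmentation is Otsu's between-class-variance threshold on a 256-bin
histogram (brighter class is foreground; `invert` flips).  No despeckling
is applied unless a minimum object size is requested.

Box counting anchors the grid at the origin and counts partial edge boxes;
default sizes are 12 powers of two from 2 px up to the image extent
(≤4096).  D_f is minus the slope of ln(count) vs ln(size) by least squares,
and the R² of that line always accompanies the estimate.  Analytic
benchmarks: filled square → 2, one-pixel line → 1, Sierpinski triangle →
log 3/log 2 = 1.585, each within ±0.05.

Branch analysis thins the mask to a 1-px 8-connected skeleton
(topology-preserving; idempotent on its own output).  Branch points are
skeleton pixels with ≥3 neighbours and end points have exactly 1; the
branching ratio is their quotient.  For node degrees, 8-connected clusters
of adjacent branch pixels are merged into single junction nodes first
(raw per-pixel counting inflates the degree of thick junctions); a merged
node's degree is the number of skeleton pixels adjacent to, but outside,
the cluster, clipped at 8, and the histogram pools junctions with degree-1
end points.

Lacunarity glides an r×r box at stride 1 (via an integral image) over
25 geometrically spaced sizes in [2, min(H,W)/2] and reports
Λ(r) = var(M)/mean(M)² per size plus their mean and range.  This
coefficient-of-variation² convention makes Λ = 0 for any uniform mask; the
Allain–Cloître normalisation E[M²]/E[M]² = 1 + var/mean² is available
behind a flag since published Λ values do not always disambiguate the
convention.  Whether a published Λ is a mean over sizes or a single-size
value is likewise often unstated; this package reports both the per-size
curve and the mean.

## Problem sizes and determinism

Default analyses run on the full 93,000-sample potential log, 30-cycle
impedance scans, 100-cycle CV records and 1024² images; calibration
studies use 200 seeds for type-I error and 50 for power, with sample sizes
of 500 events per replicate — sizes at which the binomial uncertainty of a
5% rejection rate is ≈1.5%.  Every stochastic routine takes an explicit
seed (CLI default 0) and is bit-reproducible given it; reports embed the
exact configuration used.

## Known limitations

- The morphometric pipeline is validated on analytic fixtures and the
  dendrite generator, not on original SEM micrographs, which are not
  machine-readable from a published manuscript; absolute morphometric
  values for real micrographs are therefore out of reach by construction.
- The entropy rate and transfer entropy depend on the discretisation
  (8 equal-width bins by default); absolute values should be compared only
  under an identical binning scheme.
- Equivalent-circuit parameters are never fitted to data; the circuit is a
  forward model for identities and sanity checks.
- The K–S test's default moment fit yields conservative p-values; decisions
  near the significance boundary should use the known-parameter form or a
  parametric bootstrap.
- The logic stage demonstrates threshold transduction of a fixed-excitation
  record; no claim of stimulus-programmable computation is made.
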