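# Methods

This note documents the models behind `isletchip`, the parameters that
matter, and what the synthetic data do and do not establish.

## Synthetic MEA recordings

**Signal model.**  Each electrode records µV-scale voltage at a configurable
rate (default 1 kHz; the container also supports native 10 kHz acquisition —
slow-potential content lives below ~3 Hz, so 1 kHz loses nothing relevant
while keeping desk-scale runs fast).  Occupied electrodes carry slow
potential (SP) waveforms superposed on white Gaussian noise; unoccupied
electrodes carry noise only, mirroring the no-islet control traces of a
real MEA.  Defaults: 60 electrodes (a standard 60-electrode array), half
occupied, SP amplitude 50 µV, noise 5 µV RMS (amplitude SNR 10, consistent
with the high signal-to-noise ratio of MEA islet recordings).

**Waveform.**  The SP waveshape is not constrained by published traces, so
we use a smooth, analytically convenient stand-in: one sine cycle under a
Hann window, width `sp_duration_s` (default 1 s).  It is exactly zero-mean,
biphasic, has smooth zero tails, and keeps >99.9% of its spectral power
below 3 Hz, so it passes the SP band filter essentially intact.

**Event process.**  Events on an electrode follow an inhomogeneous Poisson
process with a physical dead time of `1.1 × sp_duration_s` (waveforms must
not overlap; the 10% guard keeps detected separations strictly above the
detector's own 1 s dead time, so jitter cannot merge distinct events).
Dead time biases a naively thinned process low — by ~29% at 0.409 Hz — so
the generator compensates: after each event the intensity is
`λ' = λ/(1 − λτ)`, giving a mean interval of exactly `1/λ`.  The realized
mean rate therefore equals the ground-truth rate map, at the cost of a
hard ceiling `λ < 1/τ ≈ 0.9 Hz` (enforced with an explicit error).  The
compensated process is sub-Poisson (more regular than Poisson) at high
rates; rate-fidelity tests use the Poisson standard error, which is
conservative.

**Condition-dependent rates.**  A profile maps condition descriptors
(`"G15"`, `"G15+GLP1"`, …) to rates; Ca²⁺-free segments are silenced
unconditionally; rate switches at segment boundaries are instantaneous
except for the biphasic archetype, whose low→high glucose steps follow a
kinetic template: linear rise to the first-phase peak (default 0.409 Hz at
5 min), decline to 45% of peak over 3 min, recovery to a 65% plateau, then
sinusoidal oscillation (±15% of peak, 7.5 min period, inside the
characteristic 5–10 min band).  The last event of a recording is placed so
its waveform completes before the recording ends — a pulse truncated at
the boundary is an acquisition artifact, not an event.

**Archetypes.**  Eight profiles realize the phenotypes the decision tree
separates (intended outcome in parentheses): `unresponsive` (1),
`secretagogue_only` (2, glibenclamide only), `incretin_competent` (3),
`high_glucose_only` (4), `dose_dependent` (5), `biphasic` (6),
`alpha_dominant` (disqualified) and `hyperactive` (1: constitutively
active, epinephrine-silenceable, insensitive to everything else — the tree
continues past the silencing but nothing downstream responds).  Rates were
chosen to clear the decision thresholds with ≥3 SE margins at desk-scale
problem sizes; the α-dominant pair (G1 0.56 Hz, +EPI 0.89 Hz) sits near
the dead-time ceiling because the 1.5× enhancement cut-off must be
exceeded from an already-active baseline.

## Detection pipeline

**Filtering.**  All filters are zero-phase (forward–backward Butterworth in
second-order sections), so event timing feeds latency estimates without
phase shift.  `acquisition_filter` reproduces the amplifier band (0.1 Hz –
min(3000, 0.45·fs) Hz).  For detection, `sp_band_filter` extracts
0.1–3 Hz directly from the raw trace: it first block-averages to 50 Hz
(the 0.1 Hz corner is numerically ill-conditioned at 1 kHz, Wn ≈ 2·10⁻⁴,
and well-conditioned at 50 Hz; block-mean aliasing into the 3 Hz band is
<1% of the noise power), then applies an order-2 low-pass at 3 Hz — steep
enough to isolate the band while keeping post-pulse ringing below the
detection threshold — and an order-2 high-pass at 0.1 Hz with padding
extended to the filter settle time, so boundary transients cannot
masquerade as events.  Cascading the acquisition filter before the SP
filter is mathematically redundant for a 3 Hz detection band and is
therefore not part of the default pipeline.

**Threshold.**  Detection uses `k = 5` robust noise standard deviations.
The noise scale is *not* taken from the SP-band signal itself: SPs are ~1 s
wide, so above ~0.5 Hz they occupy most of the trace and a direct MAD
measures the events rather than the noise — precisely on the hyperactive
and epinephrine-enhanced preparations the tree must flag.  Instead the MAD
is measured in an SP-free high band (25–450 Hz) of the raw trace and
rescaled to the SP bandwidth assuming a flat noise spectrum
(`estimate_noise_sigma`).  The flat-spectrum assumption holds exactly for
the generator and approximately for real MEA noise; with strongly colored
noise the threshold should be set via the `fixed_uV` mode instead.

**Events.**  One event per local maximum of the rectified SP-band signal
above threshold, pruned greedily in time order to a 1 s refractory
spacing.  For isolated excursions this is the classic
one-event-per-excursion rule; at high rates, where consecutive pulses blur
into a single excursion, each pulse still contributes its own extremum.
Detections within one refractory interval of either recording boundary are
discarded (filter settle margin).  At SNR 10 the pipeline achieves recall
and precision ≥ 0.99 against generator ground truth, with a false-positive
rate ~3·10⁻⁴ Hz on pure-noise electrodes (Gaussian 5σ up-crossings of a
3 Hz-band process are rare events).

**Frequency profiles and segment statistics.**  Per-electrode frequency is
the event count in consecutive 60 s windows divided by the window length;
the aggregate is the mean across occupied electrodes with SEM = sample
SD/√n (noise electrodes are reported but excluded).  Segment statistics
average windows fully inside a segment after discarding the first 60 s
(solution-exchange transient); segments too short for one full window
after the discard are excluded with a warning.

## Decision tree

**Responses (③⑥⑧).**  "Significant increase" is operationalized as a
paired one-sided Wilcoxon signed-rank test across electrodes (electrodes
are the natural replicates) at α = 0.05, *and* an effect floor: a ≥2-fold
rise or an absolute rise ≥0.1 Hz.  The fold branch additionally requires
the stimulated mean to reach 0.05 Hz — without that, a "2-fold" rise
between near-zero rates (e.g. 0.01 → 0.03 Hz of counting noise) passes the
floor it was designed to enforce.  With fewer than 5 shared electrodes the
test is skipped and the flag comes from the effect floor alone, marked
low-confidence.  Baselines: ③ compares G15 against the G1 baseline; ⑥ and
⑧ compare the drug condition against plain G15 (the incremental drug
effect).

**Epinephrine disambiguation (②⑦).**  Silencing: EPI mean < 50% of the
reference mean; enhancement: > 150%.  The published criterion specifies
directions only; the cut-offs are configurable.  Enhancement at low
glucose marks an α-cell-dominated preparation, which is disqualified and
excluded from cohort correlation.

**Dose dependence (④).**  Per-electrode Spearman correlation between
concentration (1/3/5.5/8.2/11 mmol/L) and segment frequency, tested across
electrodes (one-sided Wilcoxon against zero) at α = 0.05, plus a
top-vs-bottom ratio ≥ 2 *and* an absolute top−bottom floor of 0.05 Hz —
the ratio alone is meaningless between near-zero rates.  GLP-1/EPI applied
within this branch are recorded as evidence but do not move the score
(the scoring sentences attach them to the glucose-unresponsive branch).

**Biphasic check (⑤).**  On the aggregate profile after the step
(3-window moving average, baseline from the preceding washout): a
first-phase peak of ≥0.1 Hz above baseline within 2–10 min of onset
(latency refined by parabolic interpolation of the peak window), a decline
to ≤70% of the peak within 8 min after it, and a post-nadir mean ≥40% of
the peak.  The acceptance windows were chosen to admit the published
phenotype — 5-min first-phase peak, 5–10 min second-phase oscillation —
with margin; all are configurable.  The check requires ≥20 min of
post-onset observation.

**Score assembly.**  The score is the highest rank attained (1…6 as in the
README table); flags for decision points not reached on the path are left
unevaluated, and internally contradictory flag combinations (unreachable
in the tree) are rejected.  A brute-force enumeration of all reachable
flag vectors against an independently hand-coded tree, and a monotonicity
property (passing an additional decision point never lowers the score),
are part of the test suite.

## β-score

Components follow the printed rubric; two gaps are filled explicitly and
configurably: the "diabetic range" fasting glucose zero cut is ≥7.0 mmol/L
(the standard fasting diagnostic threshold), and "absent on stimulation"
C-peptide, when no stimulation result is recorded, is a basal value
<0.1 nmol/L.  C-peptide in ng/mL is converted via the molar mass
3020.3 g/mol; HbA1c in mmol/mol via the standard NGSP/IFCC linear
relation.  Oral agents without insulin score the intermediate point (the
zero cut is printed only for insulin dose).  Range, monotonicity and the
category partition (7–8 / 4–6 / ≤3) are property-tested.

## Cohort statistics

Spearman ρ uses tie-corrected mid-ranks.  For n ≤ 10 the two-sided p-value
is exact, by complete enumeration of all n! pairings of the observed ranks
(asymptotic approximations are unreliable at the cohort sizes this
pipeline targets, n ≈ 8); larger samples use the asymptotic approximation,
and the method used is flagged in the report.  Disqualified preparations
carry no numeric score and are dropped pairwise with a logged count.

## Problem sizes and reproducibility

Every stochastic component consumes a single seeded generator; identical
inputs and seed give bit-identical recordings and hence bit-identical
pipeline output.  Desk-scale runs — the test suite and the acceptance
script — use 1 kHz simulation, 8 electrodes (6 occupied), 3-min evaluated
segments and a 23-min biphasic observation (the per-segment duration is a
free protocol parameter; 15 min is the field-realistic default).  The
exemplar maximum-frequency measurements use 30 occupied electrodes and a
10-min stimulated observation whose ground-truth rate activates to its
peak over 8 min and holds it for the final 2 min — a first-phase-like
activation, so the max-over-windows statistic measures the peak plateau
rather than the upper tail of window noise.  End-to-end archetype fidelity
is assessed over 50 seeds per archetype with a ≥95% recovery requirement.

## Limitations

The generator's noise is white and stationary; real MEA recordings show
1/f components, line interference, solution-exchange artifacts and
electrode drift, none of which are modeled (drift/artifact simulation is
out of scope).  Electrodes are independent — no spatial correlation or
propagation between sites — and fast action-potential spikes are not
synthesized, so spike/SP separation is untested.  The SP waveshape is a
plausible stand-in, not a fit to recorded pulses.  Passing the end-to-end
suite therefore demonstrates internal consistency of the
generator–detector–scorer chain under these idealizations, not equivalence
with the original real-time hardware, whose exact detection algorithm is
not reprinted.  The dead-time-compensated event process cannot realize
rates above ~0.9 Hz per electrode, which bounds the α-dominant archetype's
enhancement contrast.
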