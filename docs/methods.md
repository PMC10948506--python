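# Methods

This package re-implements, end to end and against synthetic ground truth,
an EEG analysis of temporal numerosity adaptation: how exposure to a rapid
(~8 Hz) or slow (~2 Hz) sequence of flashes biases the perceived
numerosity of a subsequent test sequence, and how that bias manifests in
frequency-tagged steady-state visual evoked potentials (ssVEPs) and in
phase-based functional connectivity.

## The paradigm

Each trial presents an 8-s adaptor (64 flashes in the High condition, 16
in the Low condition), a 1-s gap, and a 4-s test sequence of 14, 16, 18,
20 or 22 flashes; the participant reports the perceived number. 350 trials
are run in 10 blocks of 35; the adaptation condition is constant within a
block and counterbalanced across participants (even participant indices
start with five High blocks). Flashes are nominally evenly spaced with a
uniform jitter bounded by ±15% of the nominal inter-flash interval; the
generator draws each onset within ±jitter/2 of its nominal position so the
interval bound and the sequence duration hold simultaneously.

Because the test sequence lasts exactly 4 s, each numerosity defines a
tagging frequency of numerosity/4 Hz (3.5 … 5.5 Hz), and an FFT over
exactly the 4-s window (2000 samples at 500 Hz, Δf = 0.25 Hz) places every
tagging frequency on an exact bin — the window choice removes all spectral
leakage ambiguity.

## Synthetic data

The generator produces data with the statistical structure the analysis
assumes, so parameter recovery is meaningful. What it emulates, and what
it does not, bounds what passing tests say about real recordings.

**Behavior.** Estimates are multiplicative with additive report noise:
estimate = round(max(0, true × gain_cond × s_p + ε)), with condition gains
0.925 (High) and 1.075 (Low) — their difference of 0.15 sets the expected
adaptation percentage at 15% — a per-participant gain s_p ~ N(1, 0.05),
and trial noise ε ~ N(0, 1.2 flashes). Rounding is half-away-from-zero
(verbal integer reports). The adaptation percentage of participant p is
15%·s_p, so participants vary realistically in adaptation strength.

**EEG.** Epochs span −500…4500 ms around test onset at 500 Hz (2500
samples). Each trial is the sum of:

1. *Background noise*: 1/f (exponent 1, flattened below 1 Hz) at 10 µV
   RMS per channel, built from 4 latent sources mixed through smooth scalp
   patterns (92% of variance) plus channel-independent 1/f noise (8%).
   The low-rank shared part mimics volume conduction — it is what the
   surface Laplacian is supposed to attenuate, and what makes nearby
   channels (and their test statistics) correlated, as in real EEG.
2. *ssVEP*: a pure sinusoid at the trial's tagging frequency, phase-locked
   to test onset and active only during the 4-s test window, with
   amplitude 1.0 µV (Low) or 1.3 µV (High) at the effect sensors POz, O2,
   C3, Cz, falling off as a Gaussian in great-circle distance with σ =
   0.07 rad. The σ keeps the effect confined to the named sensors: the
   closest neighboring sensor (PO4, 0.179 rad from O2) receives under 4%
   of the effect. A pure sinusoid is used although flash onsets jitter,
   reflecting the empirical observation that the evoked response locks to
   the prevailing stimulation frequency.
3. *Phase coupling*: every node of the coupling graph (C3–CP5, CP5–CP6,
   CP5–POz, C3–PO7; nodes C3, CP5, CP6, POz, PO7) carries a narrowband
   component at the tagging frequency (±0.5 Hz), phase-locked across the
   trials of a condition × numerosity cell. The components are Gaussian
   mixtures with unit variance and a target correlation matrix holding
   min(0.95, 1.55 × strength) on directly coupled pairs (strength: High
   0.6, Low 0.2) and a condition-independent 0.7 on the remaining node
   pairs, projected to the nearest correlation matrix. Each component
   enters the scalp with the potential pattern of a focal current source
   under its electrode (the pseudoinverse column of the spherical-spline
   Laplacian operator, source strength 15): smooth on the raw scalp, a
   delta at the member electrode after the analysis' Laplacian stage.

Three structural choices in (3) deserve explanation, because naive
alternatives fail in instructive ways:

- *Focal-source topographies.* Injecting a component only at the member
  electrode (a spatial delta) leaks through the global spline fit of the
  surface Laplacian — up to 43% of a delta at CP5 reappears at P7 — so any
  condition-dependent component would light up pairs all over the scalp.
  Giving the component the scalp pattern whose Laplacian *is* a delta
  confines it, after the Laplacian, to its member electrode.
- *Network mixing rather than per-pair shared components.* The coupling
  graph has a hub (CP5 joins three pairs) and open triangles (C3–CP5 and
  CP5–CP6 are coupled, C3–CP6 is not). Adding an independent shared
  component per pair makes the hub's signal a three-way mixture whose
  phase locks to none of its partners, destroying the pair contrast.
  Mixing all node components toward a target correlation matrix puts the
  contrast where it belongs.
- *Condition-independent background correlation and amplitude.* Positive
  semi-definiteness forces correlations among a hub's partners: direct
  correlations of d on the spokes imply spoke–spoke correlations of at
  least 2d²−1 (≈0.6 at d≈0.9). Making that background identical in High
  and Low — and keeping component amplitude condition-independent —
  means only directly coupled pairs carry an expected condition
  difference; adaptation modulates synchronization, not power.

The generator can couple each participant's ssVEP amplitude ratio to
their behavioral gain (`behavior_link`, default 0.5), linearly scaling
(ratio − 1) by the participant's standardized gain; this is what makes
the brain–behavior Spearman correlation recover a positive sign.

What the generator does **not** emulate: eye/muscle artifacts and their
removal, biophysical forward models (sources are phenomenological scalp
patterns), non-stationarity within a session, realistic ERP components
(the ERP comparison is validated as a correctly calibrated null), or the
true single-trial ssVEP signal-to-noise ratio of the recordings — the
noise RMS is a documented free knob. Passing recovery tests therefore
demonstrate that the *pipeline* is correct and well-calibrated, not that
the real effects are of the simulated size.

## Preprocessing

Band-pass: linear-phase windowed-sinc FIR (Hamming), −6 dB at 0.5 and
40.5 Hz (1–40 Hz passband, 1 Hz transitions), 1651 taps at 500 Hz,
applied as a centered convolution so the net group delay is zero — phase
integrity matters downstream. Epochs shorter than three group delays are
rejected. Average reference over the cephalic electrodes. Bad channels
are replaced by spherical-spline interpolation. Epochs whose peak-to-peak
amplitude exceeds 150 µV on any channel are dropped deterministically —
a documented stand-in for manual artifact inspection (and for the
independent-component step of the original chain), chosen for
reproducibility; the original study's removed fractions are not targets.

Spherical splines (interpolation and the surface Laplacian share one
basis): Perrin parameterization with m = 4, regularization λ = 1e-5, 50
Legendre terms, fitted with the zero-sum constraint so constant fields
map to exactly zero Laplacian. The montage ships with idealized 10-10
positions built from the standard arc construction (outer ring at 72°
inclination, midline at 18° steps, great-circle subdivision); no digitized
positions exist for the recordings, and only inter-electrode angles enter
the analysis.

## ssVEP quantification

Per participant and condition × numerosity cell: selective trial
averaging, FFT amplitude over [0, 4000) ms (single-sided, 2|X|/N, µV),
amplitude at the tagging bin, then the numerosity average (conditions kept
separate). "Power" is operationalized as single-sided amplitude in µV,
matching the magnitude output of frequency-tagging toolboxes. The
condition comparison is a per-channel paired sign-flip permutation test
(15,000 permutations, paired t statistic, two-sided, p = (1+count)/(n+1),
exhaustive enumeration when 2^participants fits the budget) with BH-FDR
over the 30 channels at q = 0.05.

## Connectivity (ISPC)

Per numerosity: condition average → surface Laplacian → zero-phase
2nd-order Butterworth band-pass at the tagging frequency ±0.5 Hz
(forward–backward, so effectively 4th-order magnitude and zero phase) →
Hilbert transform → inter-site phase clustering
|mean_t exp(i(φ_a − φ_b))| over all 435 electrode pairs → unweighted
average over the five numerosities. ISPC is computed over time within
condition-averaged signals (trials are averaged before the Hilbert step),
not across trials — both conventions exist; this one follows the original
chain. The first and last 500 ms of the test window are excluded (valid
window 500–3500 ms): the 1-Hz-wide filter's transients are seconds long,
and the exclusion only partially clears them — instantaneous-frequency
fidelity for a window-gated tone is ±0.1 Hz rather than the ±0.05 Hz an
unbounded tone achieves. The half-bandwidth of 0.5 Hz is the largest that
still separates adjacent tagging frequencies (0.5 Hz apart). Comparison:
paired permutation test per pair, BH-FDR over pairs.

A consequence worth stating: a 1-Hz-wide band observed for 3 s carries
roughly 2·B·T ≈ 3 effective phase samples per numerosity, so the ISPC of
*independent* channels has mean ≈ 0.48 (not near 0) and a per-pair
standard deviation ≈ 0.12 after numerosity averaging. This estimator
floor, fixed by the analysis parameters, is what sizes the coupling
calibration above, and it caps the achievable contrast.

## Statistics

- Paired sign-flip permutation tests, statcond-style: participant-level
  sign flips of difference vectors, paired t statistic, two-sided
  (1+count)/(n+1) p-values, exhaustive when 2^n ≤ budget.
- BH-FDR step-up with monotonicity enforcement.
- Two-way repeated-measures ANOVA (Adaptation × Numerosity) on
  per-participant cell means, Greenhouse–Geisser ε̂ from the covariance of
  orthonormalized contrast scores (ε̂ ≡ 1 for two-level effects),
  GG-corrected p on uncorrected df, partial η². Verified against an
  independent established implementation to 1e-6.
- Bonferroni post-hocs (paired t × number of comparisons, capped at 1).
- Adaptation percentage: 100 × (mean Low − mean High estimate)/true, per
  participant and numerosity, averaged over numerosities, then over
  participants (the per-numerosity division is applied before averaging).
- Spearman correlation (mid-ranks, two-sided t approximation) between
  adaptation percentage and the High−Low numerosity-averaged ssVEP
  difference averaged over the FDR-significant sensors.

## Validation design and known limitations

The two parameter-recovery studies isolate their manipulation: the
sensor-recovery study injects the amplitude effect with coupling disabled,
and the pair-recovery study injects coupling with the ssVEP tone disabled
and amplitude ratio 1. The reason is structural, not cosmetic: ISPC on
condition-averaged signals is sensitive to *any* phase-locked component,
so an amplitude ratio at the effect sensors itself shifts ISPC at
effect-sensor pairs (the original study indeed reports overlap between its
significant sensors and its significant pairs). With both effects active,
"exactly the injected pairs" is not a well-posed recovery target.

A second, quantitative limitation: demanding that the FDR-significant set
*equal* the injected set in ≥90% of runs asks for family-wise error
control from a false-discovery-rate procedure. With 4 true discoveries
among 435 pairs at q = 0.05, the BH threshold for a fifth discovery is
p ≤ 5q/435, so the chance that at least one of the 431 null pairs crosses
it is ≈20% regardless of effect strength — exactly the false-discovery
allowance FDR promises (realized FDP 1/5 in a quarter of runs averages to
q). In the pair-recovery study all four injected pairs are recovered in
every run, and failures of exactness are always a single random extra
pair; the channel-level study escapes the cap because its null statistics
are strongly correlated through the shared noise. Under the global null
(no condition difference anywhere) BH does control the family error at q,
and the null study confirms it.

Problem sizes were chosen for desk-scale runtime: EEG studies simulate 16
participants at 8 trials per condition × numerosity cell (the full design
is 35), which is also the profile the recovery studies and the test suite
use; behavioral simulations always use the full 350-trial design.
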