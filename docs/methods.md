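# Methods

This note documents the models, default parameters and design choices
behind `loudsum`. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Categorical loudness functions

Categorical loudness scaling rates loudness on an 11-category scale of
categorical units (CU) from 0 ("not heard") to 50 ("too loud"); 40 CU
lies between "loud" and "very loud". `LoudnessFunction` is the standard
two-branch linear model of this relationship:

    CU(L) = clip( 25 + m_lo · (L − l_cut),  0, 50 )   for L < l_cut
    CU(L) = clip( 25 + m_hi · (L − l_cut),  0, 50 )   for L ≥ l_cut

with `l_cut` the level (dB) at the 25-CU pivot and `m_lo`, `m_hi` the
branch slopes in CU/dB. An optional quadratic-Bezier transition over
`l_cut ± smoothing_halfwidth` removes the kink; because the Bezier's
level coordinate is linear in the curve parameter, both evaluation and
inversion stay closed-form (the inversion solves one quadratic).
Defaults: smoothing off in unit-level work, 10 dB in pipeline runs,
where virtual listeners should not have an implausible hard corner.
`level_at_cu` is the exact inverse on CU ∈ (0, 50) and raises
`SaturatedCategoryError` at the plateaus. The level at 40 CU, written
L40, is the summary statistic used throughout.

### Normal-hearing references

The packaged normal-hearing (NH) binaural broadband reference for the
female speech-shaped noise (IFnoise) is `l_cut = 67.3`, `m_lo = 0.40`,
`m_hi = 1.00`, so it reaches 40 CU at exactly 82.3 dB SPL — the NH
group-average anchor (L40ref) that defines ΔL40 = 0. References for the
5-band and 17-band uniformly exciting noises are packaged alongside but
are not used by the default pipeline, which evaluates only the most
speech-like stimulus.

Narrowband NH references per audiometric frequency are generated by the
same two-anchor construction used for impaired functions, evaluated at a
0 dB HL threshold (see next section), from a per-frequency "too loud"
anchor near 100 dB HL stored in `data/nh_references.yaml`. A single
RETSPL-style transducer table (`data/transducer_retspl.yaml`,
supra-aural dialect) converts dB HL to dB SPL; exact per-site headphone
calibration is out of scope and the dialect is declared in the data
file.

## Audiogram-based estimation of impaired narrowband functions

Published audiogram-to-loudness-function coefficient tables are not
reproduced here; instead the package uses a transparent two-anchor
construction that captures the behaviour the prescription needs —
loudness recruitment:

- anchor A ("very soft", 2.5 CU) at `threshold + 2` dB HL (the just-
  audible region tracks the threshold),
- anchor B ("too loud", 50 CU) at the NH 50-CU level plus
  `0.25 · threshold` (the top of the scale rises only partially),
- the 25-CU pivot at fraction 0.55 of the way from A to B, with branch
  slopes following from the anchors.

All three coefficients live in `EstimationCoefficients` and are
overridable. The construction is exactly the NH reference at 0 dB HL,
steepens monotonically with threshold (larger loss never lowers the
level needed for a fixed loudness ≥ 2.5 CU), and pins the reduced
dynamic range between the two anchors. With the default pivot fraction
the upper branch is steeper than the lower one, as is typical of
measured curves.

## Simulated adaptive scaling

A `VirtualListener` holds true aided loudness functions per stimulus and
answers with `quantize(CU_true + N(0, σ))`, σ = 5 CU by default,
rounded half-up to the nearest of the 11 categories. The adaptive
procedure is a simplified two-phase stand-in for clinical adaptive
scaling, whose exact level-placement rules are proprietary to the
measurement device: phase 1 ascends from 65 dB SPL in 10 dB steps until
a rating ≥ 45 CU (cap 120 dB SPL), then descends until ≤ 5 CU (floor
0 dB SPL); phase 2 spreads the remaining budget evenly over the
bracketed range in pseudo-random order. The total budget is 22 trials
per stimulus, reflecting a shortened clinical run. A listener saturated
across the whole range raises an error rather than returning junk.

Fitting is weighted least squares of the two-branch model (smoothing
off), saturated categories (0/50 CU) down-weighted to 0.5 as censored
observations, slopes bounded to [0.05, 5] CU/dB, initialized from a line
through the soft-side and loud-side response clouds. Noise-free data at
informative levels are recovered exactly.

Recovery quality at the default settings, measured by the seeded
Monte-Carlo tests: RMSE(L40) ≤ 3 dB, and a small systematic
overestimate of L40 of about +0.7 to +0.9 dB (within the ±1 dB
unbiasedness band asserted by the tests). The bias is a property of the
response process, not the optimizer: the 0–50 scale censors the
quantized responses at its edges, compressing extreme ratings inward.
A Tobit-style one-sided treatment of saturated responses was evaluated
and increased the bias; the simple down-weighting is kept.

## Gain prescription

### Step 1 — narrowband loudness normalization

For each ear, audiometric frequency f and broadband input level
L ∈ {50, 65, 80} dB SPL, the band level `Lb(f, L)` of the test signal is
read from a packaged third-octave spectrum fixture
(`data/ifnoise_spectrum.yaml`, a female-speech LTASS-like shape,
renormalized at run time so its power sum equals the overall level; the
same shape is used at all levels). The target CU is the NH narrowband
loudness of that band, and the gain is

    g(f, L) = level_at_cu(HI_f, CU_target) − Lb(f, L),

interpolated onto the third-octave grid on a log-frequency axis.
Target CUs are computed on the *unclipped linear extension* of the NH
curve: gains are level differences between two curves at equal loudness,
and using the extension keeps the mapping well-defined when a band falls
below "very soft" — in particular a normal audiogram then yields exactly
0 dB gain at every cell. Targets outside [2.5, 47.5] CU are inverted at
the clamped value, extrapolated linearly, and flagged in the table
metadata.

### Step 2/3 — broadband binaural correction

The aided broadband binaural loudness function (measured in the scaling
simulation and fitted from the trial log) is compared with the NH
broadband reference: at each input level the reference loudness is
looked up and the fitted curve inverted at that CU; the resulting offset
is added uniformly across frequency (full bandwidth, no binaural
difference). A listener with excess summation (curve shifted toward
lower levels, positive ΔL40) receives negative offsets — a gain
reduction; the offsets are exactly −ΔL40 at all levels when the measured
curve is a pure translation of the reference. Offsets are computed at
exactly 50/65/80 dB SPL from the fitted parametric curve; no
interpolation between levels is defined or needed.

### Compression ratio and comparison metrics

The compression ratio between a low and high broadband input level is

    CR = ΔLin / (ΔLin + G(L_high) − G(L_low)),    ΔLin = L_high − L_low,

reported as 1 for level-independent gain, > 1 compressive, < 1
expansive; non-positive or non-finite values are returned flagged
invalid instead of raising. Prescription rules are compared by the mean
unsigned gain difference over 0.5/1/2/4 kHz × 50/65/80 dB SPL × both
ears (24 cells), with a strict 5 dB criterion for a meaningful
difference.

Established threshold-based prescription procedures are external tools;
their tables are ingested from CSV (`import_gain_table`, bit-exact
round-trip). For pipeline testing the package ships a clearly labelled
*synthetic* stand-in rule (`standin-halfgain`): half-gain with a linear
level rolloff, `clip(0.5·T − 10·(L−65)/15, 0, T)`. The upper clip at the
threshold itself makes a normal audiogram map to zero gain at every
level. It is not a reimplementation of any published rule.

## Synthetic cohort generator

The generator emulates the study conditions: 88 New + 72 Experienced
hearing-aid users from hearing-aid professionals' facilities, 20
Experimenter users from a research database, 20 young NH listeners.

**ΔL40 distributions.** Hearing-impaired groups are skew-normal (three
parameters match a mean plus percentile constraints); NH is mean-zero
Gaussian with σ = 17.2/z(0.95) so its analytic 95th percentile is
exactly the 17.2 dB boundary. The two HAPF groups share one law with
mean 13.2 dB; the Experimenter law has mean 8.1 dB and, as a design
choice, 0.8× the HAPF scale (that group's narrower spread is otherwise
unconstrained by the published summary statistics). The remaining two
free parameters (HAPF scale ω and shared shape α) are solved
deterministically at run time so the pooled 88:72:20 mixture hits
2.5th/97.5th percentiles of −12.4/36.1 dB; the solution is
ω ≈ 15.60, α ≈ −1.14 (a mild left skew — the printed lower percentile
sits farther from the mean than the upper one). Calibration closure is
therefore analytic, verified by tests on the distribution objects before
any sampling.

**Listeners.** Excess summation is injected as a pure leftward
translation of the NH broadband reference by the latent ΔL40 (slope
jitter off by default), so listener L40 = 82.3 − ΔL40 by construction.

**Audiograms.** Sloping losses around a packaged N3-like anchor
(`data/n3_anchor.yaml`), perturbed by a common level shift (SD 10 dB),
a tilt over log-frequency (SD 4 dB), small local deviations (SD 3 dB)
and per-ear deviations (SD 3 dB), rounded to 5 dB steps, and
rejection-sampled against the inclusion criteria (better-ear PTA
≥ 30 dB HL, interaural PTA difference ≤ 15 dB). New users carry a −5 dB
profile offset, reproducing their better thresholds. NH audiograms sit
near 5 dB HL under the NH admission rule (≤ 15 dB HL at all but ≤ 2
frequencies).

**Covariates.** Tone UCLs are Gaussian around 100 dB HL clipped to
[80, 120]; ages are group-wise Gaussian (70.9 ± 11.4, 72.7 ± 11.3,
75.9 ± 12.3 years; NH uniform 18–25). Speech UCLs, tone UCLs and the
hyperacusis (IHS) total score carry linear couplings to the centred
latent ΔL40, with slopes solved from the target variance-explained
values given the residual SDs and the generator's pooled HI ΔL40 SD of
12.5 dB: minimum monaural speech UCL R² ≈ 0.18 (the strongest
predictor), binaural speech UCL ≈ 0.10, binaurally averaged PTA UCL
≈ 0.06 (the slope targets the 8-draw average, whose residual variance is
SD²/8), IHS ≈ 0.03. Each coupling is calibrated marginally; the full
joint correlation structure of real data is not modelled.

**What the generator does not emulate.** Site effects, recruitment/
sampling-bias mechanisms, hearing-aid usage history, per-participant NH
reference variability (ΔL40 is defined against the single scalar
82.3 dB SPL), and any dependence of excess summation on the audiogram.
Passing tests therefore demonstrate that the machinery is correct and
calibrated to the stated summary statistics — not that it would
reproduce individual-level structure of a real cohort.

## Pipeline and numerical choices

`run_pipeline` chains simulate → scale → fit → prescribe → analyze and
writes the cohort CSV bundle, trial logs, fits, per-rule gain tables,
per-participant results and a summary JSON. Scaling seeds are spawned
per participant from `SeedSequence([seed, 1])`, so results do not depend
on processing order; a fixed seed gives byte-identical outputs (floats
are written with `repr` and read back with exact round-trip parsing;
the summary JSON is key-sorted and rounded to 6 decimals). Participants
whose simulated run brackets no usable dynamic range are recorded with
missing fits and excluded from the affected statistics; an empty group
is reported as absent rather than crashing. Group comparisons use
Welch's unequal-variance t-test with Bonferroni correction; boundary
prevalence uses a strict ">".

Default problem sizes — 200 participants, 22 trials each, and 200-run /
500-run Monte-Carlo batches in the recovery tests — keep the whole suite
at a few minutes on one CPU while leaving Monte-Carlo standard errors
well inside the asserted tolerances.

## Known limitations

- The audiogram-to-loudness-function coefficients are this package's
  own documented construction, not transcribed published tables; gain
  targets at the narrowband stage are therefore comparable in shape but
  not numerically to any clinical device output.
- The adaptive procedure is a simplified stand-in; trial-placement
  details of clinical implementations differ.
- The test-signal spectrum fixture is LTASS-like, not derived from the
  actual signal recordings; it is versioned and overridable.
- The small positive L40 recovery bias described above propagates into
  measured ΔL40 (≈ −0.8 dB on average relative to latent values); it is
  visible in the pipeline's group means and documented rather than
  corrected.
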