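# Methods

This note documents the models and numerical conventions implemented in
`tinassay`, the parameters that matter, and the design decisions taken
where the underlying assay description leaves the design open. It states
no empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## The suppression-ratio statistic and epoching

Sessions are tiled by half-open 1-minute epochs `[start, end)`; press
timestamps are seconds from session start, and a press at an epoch
boundary belongs to the later epoch. The running suppression ratio at
minute *k* is `R = B/(A+B)` with `A = count(k−1)`, `B = count(k)`.
Conventions:

- **Minute 0** has no preceding segment; its R is undefined and excluded.
- **A + B = 0** leaves R undefined. It is carried as a NaN sentinel and
  excluded from every average rather than imputed — any imputation (0,
  0.5, or 1) would bias exactly the epochs where behaviour is weakest.
- R is NaN-free elsewhere and always in [0, 1]; `R(A,B) + R(B,A) = 1`
  whenever defined. These invariants are property-tested.

## Session quality control

A session enters analysis iff **both** criteria hold, with inclusive
boundaries ("minimum of 200", "at least 0.4"):

1. total lever presses ≥ 200 (config `qc_min_presses`);
2. mean of defined R over *eligible background minutes* ≥ 0.4
   (config `qc_min_background_r`).

"Eligible background" is read conservatively: background-noise minutes
excluding minute 0, probe minutes, and the minute immediately following a
probe (whose *A* comes from the probe minute and is contaminated by the
test stimulus). Sessions with no defined background epoch fail with an
explicit reason.

For boundary verification, `behavior.make_controlled_session` constructs
a 60-minute session whose mean background R equals a requested exact
fraction bit-for-bit: probe minutes tile the odd minutes so that all even
background minutes are post-probe (excluded), leaving exactly two
engineered eligible minutes whose counts are the numerator/denominator of
the requested fraction; the mean of two identical floats is that float.
Remaining presses are parked on minute 0 so any total press count is
reachable without touching the background mean.

## Generative model of test sessions

The simulator stands in for the study animals; no public operant logs
exist for this assay, so the generator's role is to realise the assay's
*design* exactly (session structure, probe placement) while providing a
latent severity parameter whose recovery can be tested.

**Protocol.** 60 one-minute epochs; 10 probe minutes drawn uniformly
among interior (minutes 1–58), pairwise non-adjacent slots via the
standard combinatorial bijection (so all valid placements are
equiprobable); 2 probes are always speaker-off; the remaining 8 draw from
a probe catalog — by default 20 kHz tones at 30–90 dB SPL in 10 dB steps
— in a balanced shuffled rotation, so every level is presented before any
repeats within a session. Infeasible placements (too many probes for
non-contiguity) raise immediately.

**Perceived similarity.** Each animal carries a latent tinnitus severity
τ ∈ [0, 1] (0 for unexposed animals), a tinnitus pitch (20 kHz), a
baseline press rate λ_bg, and a trained suppression depth c_off. A probe
stimulus maps to a similarity S ∈ [0, 1] with the animal's conditioned
danger percept:

- speaker-off: S = 1 always (for τ = 0 the percept is silence; for τ > 0
  it is the tinnitus itself — either way it is the danger percept);
- tones: `S = (1−τ)·S_sil(L) + τ·G(f)·w(L)`, where `S_sil` is a
  decreasing logistic in level (midpoint 45 dB, slope 6 dB), `G` a
  Gaussian in log2-frequency around the tinnitus pitch (σ = 0.5 octaves),
  and `w` a gently decaying level-admission window (−0.01/dB above
  30 dB, floored at 0.35) — a faint phantom percept is resembled more by
  soft tones, but loud tones at the pitch still partly match, so group
  separation persists at high levels;
- broad-band noise: `S = S_sil(L)` independent of τ. A tonal phantom
  percept blends with faint noise exactly as silence does; this is the
  modelling choice that reproduces the assay's key control result
  (BBN discrimination does not differentiate exposed from unexposed).

Similarities below 0.05 are clamped to zero. All kernel parameters are
configurable (`SimilarityParams`).

**Press process.** Per-minute press counts are Poisson with rate
`λ_bg · (1 − c_off · S)` (S = 0 in background minutes); press times are
uniform within the minute. Defaults: c_off = 0.9; λ_bg per animal from a
log-normal with median 15 presses/min and log-sd 0.8, wide enough that a
small fraction of animals genuinely fails the 200-press criterion — QC
has non-trivial action, as in real cohorts where low pressers are
dropped. The assay description states neither base rates nor suppression
depth; both are configuration, not claims about real animals. All
randomness flows from seeds through `numpy.random.SeedSequence` spawning,
so identical inputs and seed give byte-identical logs.

**What the generator does not emulate.** Acquisition/learning dynamics
(c_off is a fixed steady-state depth — the analysis targets steady-state
discrimination), motivational drift within sessions, serial dependence
between minutes beyond the shared schedule, and any auditory-periphery or
ABR model. Passing recovery tests therefore shows the *pipeline* is
correct and the *design* is detectable under Poisson-like behaviour; it
does not validate the physiological model of tinnitus itself.

## Discrimination functions and group inference

Per-animal mean R is computed per stimulus and level across all
QC-passing probe minutes; group functions average the animal means with
equal weight per animal (animals first, then group), and SEM is across
animals (flagged NaN for a single animal). Speaker-off forms a separate
leftmost point.

The group comparison is a classical two-way **mixed-design (split-plot)
ANOVA** computed from sums of squares: group (between subjects) tested
against subjects-within-groups; level and group × level (within subjects)
tested against the within-subject residual. This matches the F/df
reporting style of repeated-measures analyses in this literature; it is
deliberately not a modern mixed-effects likelihood fit. No sphericity
correction is applied, and the output records that. Speaker-off rows are
excluded from the ANOVA by construction. Empty subject × level cells are
an error listing the offending cells. The implementation is verified
against a frozen hand computation (all five sums of squares on a
4-animal toy, at 1e-10) and against pingouin's `mixed_anova` on every
balanced design up to 3 groups × 4 levels × 5 subjects.

**Subgroup rule.** Exposed animals are ranked ascending by mean 20 kHz
probe R (ties broken by animal id, so the assignment is invariant to
input order); the lowest 16 are prominent tinnitus, randomly halved by a
seeded permutation into antagonist/no-drug subgroups of 8; the next 8 are
weak tinnitus. Fewer than 24 animals is an error naming the shortfall;
animals beyond the 16 + 8 design are labelled unassigned.

**IHC group tests** are uncorrected equal-variance two-sample t-tests
(two-sided), by design — no multiple-testing machinery. The degenerate
all-constant case returns t = 0, p = 1.

## Micrograph quantification

Images are single-channel float rasters (8/16-bit grayscale PNG/TIFF on
disk; RGB inputs are collapsed with Rec. 709 luminance weights applied
without rescaling). The AOI is a boolean mask; pixel coordinates are
0-based, and `pixel_area` calibrates physical area. Per image:

1. **Threshold** computed from AOI pixels only (per-image adaptation, the
   reproducible analogue of per-micrograph visual adjustment): Otsu by
   default, with percentile and fixed overrides; the threshold used is
   reported for audit. The stain mask is `image < t` (stain is dark on a
   bright background). A constant AOI under Otsu is an error advising the
   alternatives.
2. **Particle analysis**: 8-connected components of the stain mask within
   the AOI (8-connectivity matches common particle-analysis defaults);
   components touching the raster border (section edges, blemishes) or
   smaller than `min_size_px` (default 4 px, unstated in the original
   workflow and therefore config) are excluded. Outputs: particle count,
   stained area, AOI area, percent area. Percent area is
   calibration-invariant; stained area scales with `pixel_area`. Both
   count and area are reported, but area fraction is the headline
   readout: stained somata overlap, which biases counts downward while
   leaving area unbiased.

The synthetic generator paints dark hard-edged disks (uniform radius 3–6
px by default) fully inside the AOI on a noisy bright background
(mean 200, σ 8, contrast 130), with optional border-straddling blemishes
and a high-contrast frame outside the AOI; ground truth is the exact
pixel count of the stained union. Hard edges keep the truth exact; real
DAB staining has soft particle edges, partial-intensity staining, and
uneven illumination, so recovery within ±1 percentage point on synthetic
images bounds algorithmic error only, not biological measurement error.
The cohort generator adds per-animal log-normal scatter (log-sd 0.2)
around a baseline expected blob count (18), doubled for exposed animals —
a staining effect size in line with a clearly visible group difference at
small group sizes (4 vs 3).

## Diffusion helper

`relative_diffusion` scales diffusion coefficients as `D ∝ MW^(−e)` with
e = 1/3 by default (Stokes–Einstein: D ∝ 1/radius, radius ∝ MW^(1/3) at
roughly constant density); a cocktail's coefficient is the mean of its
members'. For methylene blue (MW 374) against a cocktail of mean MW 201
this gives a ratio of (201/374)^(1/3) ≈ 0.813. The exponent is exposed
because the "classic diffusion equations" convention varies (e = 1/2
would give ≈ 0.73); the module documents the convention in use rather
than asserting any particular published percentage.

## Problem sizes and tolerances

Stochastic validation uses sizes chosen to make the checks sharp yet
cheap: severity recovery uses 24 animals × 10 sessions (Spearman ρ
threshold −0.5); ANOVA power uses 200 replicates of 8 τ=0.8 vs 8 τ=0
animals at 3 sessions each (threshold 80% at α = 0.05); IHC power uses
200 replicates at 4 vs 3 animals with the 2× effect (threshold 80%).
Oracle equivalences are exact (running R vs direct formula on 1000
sessions; connected components vs flood fill on 1000 rasters ≤ 12×12) or
at 1e-10/1e-8 (ANOVA sums of squares vs hand computation and pingouin).
Seeds are fixed in tests; the acceptance script takes `--seed` and
threads it through every stochastic step.

## Known limitations

- The similarity kernel is a minimal phenomenological stand-in; its
  parameters are not fitted to animal data.
- The mixed ANOVA assumes complete within-subject data; animals losing a
  level entirely (all sessions failing QC) must be dropped upstream.
- Particle counting on overlapping blobs undercounts by construction
  (as in real micrographs); only percent area is validated against truth.
- CSV float round-tripping relies on `repr`; files edited by spreadsheet
  software may lose exactness (the values remain correct to double
  precision).
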