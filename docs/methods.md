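# Methods

This note documents the scientific and numerical choices behind the package:
what is modelled, what the synthetic-data generator does and does not
emulate, how the inference is computed, and what the simulation studies can
and cannot show about real data.

## Morphometry

The sperm head is treated as a prolate spheroid (polar radius
r_p = L_H/2 strictly greater than equatorial radius r_e = W_H/2). Ellipticity
is the eccentricity of the meridional ellipse, e = sqrt(1 − r_e²/r_p²), and
head surface area uses the closed form

    A_H = 2π r_e² + 2π r_e r_p · arcsin(e)/e .

Equivalent algebraic forms of the prolate-spheroid area exist; the
implementation is anchored operationally by an independent oracle — adaptive
quadrature of the surface of revolution of the meridional ellipse — with
which it agrees to relative error < 1e-9 across aspect ratios 1+1e-6 to 20.
At the sphere limit, arcsin(e)/e → 0/0; below e = 1e-9 the exact sphere area
4πr² is substituted (the substitution error there is O(e²)/6 ≈ 1e-19, far
below measurement precision). Cells with W_H > L_H violate the prolate
assumption and are *rejected*, never silently axis-swapped, because swapping
would corrupt e; a strict-validation helper lists offenders. Deformed cells
are excluded from all derivations. The mid-piece is not modelled: it cannot
be distinguished from the head under light microscopy in most fishes.

## Hydrodynamics

Drag on the head is Stokes' law, D = 6πµaU, appropriate at the low Reynolds
numbers (≈1e-3) at which sperm swim. Three deliberate conventions:

* **a = W_H/2**, the equatorial half-width — not an equivalent-volume-sphere
  radius. This treats the head as a sphere of the measured width, the
  convention used in sperm-drag comparisons of this kind.
* **U is the male-level V_AP** at the matching activation temperature,
  applied to all of that male's cells: speed was recorded per sample (an
  average over cells in view), not per cell. Each drag record stores its own
  U, so per-cell speeds could be substituted without schema changes.
* **Viscosity lookup** defaults to the bracketing-average rule: µ at 8 °C is
  the mean of the 5 and 10 °C table entries, µ at 13 °C the mean of the 10
  and 15 °C entries — even though 8 and 13 °C are not midpoints. This matches
  the protocol the pipeline reproduces; linear interpolation is provided as a
  sensitivity option. The shipped default table contains standard
  pure-water dynamic viscosities at 5 °C steps (CRC-handbook-style values);
  it is a configurable input and no test depends on it numerically.

Units: lengths in µm convert to m (×1e-6) before Stokes' law; D converts to
pN (×1e12). Column names encode units (`_um`, `_Pa_s`, `_pN`).

## Deformity counting

Scans are ordered fields of view scored over {normal, kink, coil, short,
tailless}. Counting consumes whole fields until the cumulative total reaches
the target (default 100); the crossing field is always counted in full, so
totals overshoot — the "~100 cells" convention implemented literally.
Indiscernible aggregations are tracked separately and never enter a
denominator. Proportions are therefore invariant to how the same cells are
partitioned into fields.

## Synthetic-data generator

The generator emulates the study design: 2 acclimation groups × 8 males × 40
measured normal cells, V_AP at activation temperatures 8 and 13 °C, and a
~100-cell deformity scan per male with ≈30% flagellar abnormalities
(defaults: kink 0.12, coil 0.08, short 0.04, tailless 0.06 — bending made
most common, consistent with flagellar abnormality spectra in fish sperm).

Cell dimensions are lognormal with a **shared per-male size factor** on the
log scale (SD 0.06) plus small per-dimension male effects (SD 0.02), cell
CVs of 8% (head length), 6% (width fraction) and 5% (flagellum). Head width
is generated as a lognormal *fraction* (median 0.65) of head length, which
guarantees prolate heads by construction; draws with fraction ≥ 1
(probability ~1e-11 at defaults) are redrawn. Baseline medians — head 3.2 µm,
flagellum 32 µm, V_AP 95 µm s⁻¹ — are typical salmonid values; no raw data
accompany studies of this design, so these defaults are assumptions, not
calibrations, and every distributional choice is configurable. V_AP is
lognormal with between-male CV 0.15 and within-male, per-activation
-temperature CV 0.11 (CASA repeat-measurement variability of roughly 10–15%
is typical).

**What passing tests do not show:** the generator draws clean lognormal
cells with a single shared male factor; real micrograph data carry
measurement error, within-ejaculate heterogeneity beyond a common size
factor, occasional mis-scored categories and possible mean–variance
relationships not captured here. Calibration results (type-I ≈ 0.05,
coverage ≈ 0.95) certify the inference machinery under the generative
assumptions, not robustness to their violation.

### The warm-acclimation scenario preset

The qualitative scenario gives warm males a head multiplier of 0.95 on both
head dimensions (so A_H shrinks ~10% and L_F/A_H rises ~11% while flagellum
and total length barely move), and leaves group V_AP medians equal at 8 °C.
Because both the within-group activation drag contrast (∝ group mean head
radius) and the pooled residual SD scale with head size, *equal speeds at
both temperatures would always make the larger-headed cold group's contrast
the more significant one*. The scenario therefore encodes the physiological
interpretation that the smaller warm-male cells carry a smaller power unit:
cold-group sperm respond to 13 °C activation water with a +5.6% V_AP
increase that warm-group sperm fail to produce. That partially offsets the
viscosity-driven drag drop in the cold group, making the within-warm
contrast the stronger rejection (expected t ≈ 2.5 vs ≈ 1.7 at the study n
with the default dispersions). The 5.6% figure was derived analytically from
that target contrast ratio before any simulation was run, and is a preset
like any other — edit `EffectConfig` to explore alternatives.

## Inference

* **Deformity**: binomial GLM (logit) of per-male deformed/total on group;
  per-male rows, not pooled counts. Complete separation is flagged, not
  fatal.
* **Morphology**: random-intercept mixed model per measure. The absolute
  sizes (A_H, L_F, L_T) are right-skewed and fitted on the log scale — a
  linear mixed model on log response is used as the lognormal-family fit
  because it has the same estimand (multiplicative group effect) while being
  exactly reproducible and testable, whereas penalised quasi-likelihood is
  implementation-specific. The ratios are fitted on the identity scale.
* **Speed**: per-male OLS of V_AP on the mean morphology ratio; acclimation
  group enters the L_F/A_H models because that ratio differs between groups.
  The 8 °C models use an identity response; the 13 °C models a log response
  (speeds there fail normality checks in this design's data class), chosen
  for consistency with the morphology stage.
* **Drag**: mixed model of per-male mean drag with acclimation, activation
  and their interaction; male nested within acclimation as random intercept
  (with unique male IDs this equals a male intercept). Post-hoc
  least-squares-means activation contrasts within each acclimation level,
  without multiplicity adjustment (none is applied anywhere; significance is
  P < 0.05 throughout).

### The mixed-model engine

All mixed models are random-intercept LMMs fitted by REML in
`troutsperm.lmm`: the variance ratio λ = σ²_b/σ²_e is profiled out and
minimised by bounded scalar search on log λ over [−20, 12] (xatol 1e-10,
deterministic); everything reduces to per-group sufficient statistics via
Sherman–Morrison, so one fit costs ~1 ms and the 1000-replicate simulation
studies stay cheap. Degenerate data are flagged rather than fatal: λ at the
lower bound ⇒ boundary (zero male variance, inference falls back to residual
df); λ at the upper bound or zero GLS residual ⇒ degenerate (vanishing
residual variance).

Per-term and per-contrast t tests use **Satterthwaite denominator df**:
df = 2·(L'CL)² / (g'Ag), with C(θ) the fixed-effects covariance as a function
of θ = (σ²_b, σ²_e), g its finite-difference gradient, and A the inverse
negative Hessian of the REML log-likelihood (central differences, relative
steps 1e-6 and 1e-4 chosen to balance truncation against round-off). For the
balanced 16-male × 2-temperature drag design this reproduces df = 14 for
within-male terms to ~1e-3, matching lmerTest; a `residual` df method
(n − p) is available as a config option. The engine agrees with statsmodels
MixedLM (estimates, SEs, variance components) and with R lmerTest (df,
p-values) in the test suite; those packages serve as oracles only.

## Simulation studies and problem sizes

`troutsperm.calibration` runs three studies at the emulated study scale
(8 males/group, 40 cells/male): type-I error of each stage's null term over
1000 null replicates (accepted band 0.03–0.07 at α = 0.05, the 3-SE binomial
band around 0.05); 95%-CI coverage of an injected +20% warm-group L_F/A_H
shift over 500 replicates (the true effect is computed by Monte-Carlo at
200 000 cells, since E[L_F/A_H] has no closed form under the lognormal
model); and rejection rates under the scenario preset over 500 replicates.
These replicate counts keep the whole verification suite at a few minutes on
one CPU while leaving Monte-Carlo noise (±0.7 percentage points on a 5%
rate) well inside the accepted bands. Replicate seeds are spawned
deterministically from one base seed.

## Known limitations

* Only a single random intercept is supported (all the study's models need);
  no random slopes or crossed designs.
* The Stokes model covers head drag only — no flagellar propulsion,
  resistive-force theory or Reynolds-number computation.
* Deformity classification itself (from images) is out of scope; the package
  starts from scored categories.
* The generator's defaults are field-plausible assumptions, not fits to a
  published dataset; conclusions about real data require re-running the
  pipeline on real tables.
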