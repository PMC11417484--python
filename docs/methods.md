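# Methods

## Measurement model

A segmentation stack is a 3-D integer label volume indexed (slice, row, col)
with labels 0 = background, 1 = LV cavity, 2 = LV myocardium, 3 = RV cavity
(remappable at read time), plus geometry: in-plane pixel spacing (mm),
slice thickness `t` and inter-slice gap `g`. Slices are normalised to
base→apex order internally; apex-to-base inputs are reversed on read.

Mass is pixel-sum based: a slice with `n` myocardial pixels of area `a` mm²
contributes `n·a·(t+g)·ρ` grams with ρ = 1.055 g/cm³. The `(t+g)` factor is
the contiguous-coverage convention (each slice represents its thickness plus
the following gap); a `thickness_only` switch exists for the alternative
reading. Total LV mass sums all slices. Apical mass sums the four most
apex-ward slices *containing myocardium* (not the raw array tail, which may
be empty); `n_apical` is configurable.

### Septum

Per slice: the LV centroid is the mean pixel position of cavity ∪ myocardium
(using both keeps it stable on thin-wall slices). The contact set is every
myocardial pixel 8-adjacent to an RV pixel. The RV insertion points are the
endpoints of the smallest circular angular interval containing all
contact-pixel angles about the centroid (computed by the largest-gap rule on
sorted angles); pixel-centre angles are used with no subpixel fitting, so
angular resolution is ≈ atan(spacing / epicardial radius) ≈ 1° at 0.5 mm
and r = 28 mm. Septal pixels are myocardial pixels whose angle lies in the
closed interval; septal mass applies the slice-mass formula to their count.
Slices without RV contact contribute zero by default
(`--septum-fallback nearest` reuses the nearest contact slice's angles);
contact arcs spanning ≥ 180° are flagged degenerate and excluded. A stack
with no RV contact anywhere has no defined septum and raises.

Consequences worth knowing:

- Septal + non-septal pixel counts conserve the myocardial total exactly
  (the septal set is a subset by construction).
- Rotating the anatomy by 90° permutes pixels, so masses are unchanged
  exactly and insertion angles shift by exactly 90°; whole-pixel
  translations change nothing.
- The covering interval overshoots the true contact arc by up to one pixel
  angle per end, a small *positive* bias on septal mass of order
  2·atan(spacing/r_out)/span — ~1–3% for a 90° arc at 0.5 mm and
  r_out 21–35 mm. This is intrinsic to pixel-resolution insertion points,
  dominates septal error at fine grids, and is why septal mass converges
  more slowly than total or apical mass.

### Quality control

Configurable rules, reported (never raised): at least 6 myocardium-bearing
slices; RV present in the middle third; in each mid-third slice the
myocardium must form a single 8-connected ring that topologically encloses
the cavity (checked by 4-connected flood fill of the complement from the
border — component counting alone cannot detect a single radial gap, which
leaves a connected "C"); and the most apical myocardial slice's cavity area
must be below 0.95 of the mid-ventricular maximum (an apex that never
tapers, or a truncated stack, fails this cap). QC decisions depend only on
relative geometry, hence are translation invariant. Failed stacks yield
records with QC reasons and no masses.

## Synthetic ground truth

**Phantoms.** Each slice is a circular annulus (cavity disc inside) with the
RV realised as a half-annulus segment hugging the epicardium over exactly
the configured arc, so insertion angles are known by construction; radii
taper linearly toward the apex (default batches use 1–4%/slice). Truth
masses are closed-form: per-slice annulus area π(R_out² − R_in²) × (t+g) × ρ;
septal truth is the arc fraction of the (uniform) annulus. Injectable
defects — missing apex slices, a carved radial gap, absent RV — exercise the
QC rules. Rasterisation uses pixel-centre membership; its area error is
oscillatory in spacing for a single geometry, so convergence is assessed on
batch-mean error over a fixed geometry ensemble (monotone across
2 → 1 → 0.5 mm).

**Cohorts.** Per-sex (total, apical, septal) masses are multivariate normal
with defaults male (103, 16, 38) ± (20, 5, 9) g, female (71, 11, 27) ±
(15, 4, 7) g and within-sex correlations (total–apical 0.66, total–septal
0.86, apical–septal 0.60); covariates: age ~ N(64, 7.5²) yr, pulse
~ N(69, 11²) bpm, hypertension prevalence 0.30, BMI ~ N(27, 4.5²). Pooling
sexes inflates marginal correlations above the within-sex targets (a mixture
effect), so correlation-recovery checks use single-sex cohorts. Event times
are exponential with subject hazard λ·exp(βᵀx) — the simplest model under
which Cox estimates have closed-form targets; censoring is an independent
exponential race plus an administrative cut-off (default 10 y). Outcome
dates derive from baseline + time, with an optional injected prevalent
fraction whose first event predates baseline.

**Genotypes.** Dosages are sums of two haplotypes. Within a declared LD
block every haplotype copies a latent founder allele with probability √r
(else a fresh Bernoulli at the block's allele frequency), which makes *all*
pairwise dosage correlations equal r in expectation while preserving
marginals; variants outside blocks are independent. Phenotypes add Gaussian
noise to the causal dosage combination. The panels carry no relatedness or
population structure, so an OLS scan is calibrated under the null by
construction — which is exactly what makes it an honest stand-in for a
mixed-model scan here, and what passing tests do *not* demonstrate about
structured real cohorts.

## Statistical procedures

**Hypertrophy flags.** Within each sex, flag = mass strictly greater than
the sex's empirical percentile (linear-interpolation quantile, default
90th). Strict ">" makes ties deterministic (all-equal values flag nobody)
and raising the percentile never adds flags. For n distinct values with n a
multiple of 10 this marks exactly n/10; for other n the linear-interpolation
definition can differ from ⌊n/10⌋ by one. Thresholds are computed on the
post-QC cohort before prevalent-case removal (they describe anatomy, not
outcomes). The three flags give an eight-cell partition; modelling uses the
disjoint five groups control / global (any global flag) / isolated apical /
isolated septal / combined (both regional flags, no global).

**Cox families.** Fitting delegates to lifelines' `CoxPHFitter` (Efron tie
handling, Newton iteration, Wald 95% CIs); the package adds design
encoding, per-SD standardisation (sample SD over the fitted subset,
recorded for reporting), complete-case handling with logged counts, a
condition-number gate (> 1e8 → collinearity diagnostic), and a decreasing
step-size retry (0.95 → 0.5 → 0.25 → 0.1) because the default Newton step
can overshoot a finite MLE when strong effects meet heavy
administrative-censoring ties. Categorical fits use the no-hypertrophy
control as reference; groups with no members or no events get n-only rows
rather than distorting the fit, dropped smallest-first if the likelihood
still degenerates. Covariates default to sex, age, pulse rate and
hypertension (+BMI for PRS models). Death is treated as censoring, not a
competing risk. Note the weights-vs-replication nuance: integer case
weights reproduce an untied fit exactly, whereas physically replicating
rows creates ties whose Efron adjustment shifts estimates at ~1e-4 relative.

**Scan.** Per variant, OLS of phenotype on dosage plus covariates, computed
by residualising both against the covariates once (Frisch–Waugh) and
vectorising over variants; betas, SEs and p-values are identical to
per-variant OLS to 1e-10. Constant-dosage variants are reported with
undefined statistics, not dropped. Variant filters are inclusive:
MAF ≥ 0.01, INFO ≥ 0.3. λ_GC is the median χ² over its null median. The
median-based λ of a single 2000-variant scan has Monte-Carlo SE ≈ 0.05, so
calibration checks average λ and type-I error over 10 independent
null-phenotype replicates of the same panel (SE ≈ 0.016).

**Clumping.** Greedy: significant variants (p < 5e-8) visited in ascending
(p, chr, pos); a variant leads unless it lies within ±500 kb of an accepted
lead on the same chromosome *and* has r² > 0.6 with it (conjunctive reading;
"independent SNPs with r² > 0.6" is internally inconsistent as stated, and
the conventional clumping semantics — absorb into a lead when r² exceeds
the threshold inside the window — is implemented). LD is supplied as an
explicit pairwise lookup, by default computed from the panel's dosages; a
missing pair inside a window is a configuration error. Output is
independent of input row order; the deterministic tie-break is (p, chr, pos).

**PRS.** Additive: score = Σ w·dosage of the effect allele, with the weight
sign flipped when the effect allele is the panel's ref — under this
convention flipping ref/alt and negating weights leaves scores bitwise
identical (the 2−dosage convention would shift them by a constant).
Unmatched weight variants are logged and skipped; an effect allele matching
neither allele raises. Outcome models fit the standardised score per SD plus
binary top-decile and top-5% indicators (same strict-">" quantile rule).

## Pipeline and determinism

A validated YAML config (unknown keys rejected) drives
simulate → quantify → cohort → cox → scan → clump → prs. Per-stage seeds
derive from the global seed by stable hashing so stages can rerun
independently; tables are written with a fixed float format, making reruns
byte-identical (the manifest's wall timestamps are the one exception). The
manifest records per-stage counts, thresholds and output hashes.

## Problem sizes and defaults used in validation

Phantom batches: 8–10 geometries, inner radius 15–25 mm, wall 6–10 mm,
90° arcs, 10 slices, spacings 2 / 1 / 0.5 mm. Coverage battery: 200
replicate cohorts of n = 5000 (~650 events each at the default hazards);
categorical truths HR 9.28 / 2.69 / 4.41 / 5.0 over a 0.008 /yr control
baseline; per-SD truth HR 2.0 over 0.012 /yr. Scan calibration: 2000
variants × 2000 subjects × 10 phenotype replicates. Clump verification: 20
random instances of ≤ 200 variants against an independently coded naive
verifier plus a post-hoc absorption check. Demo pipeline: 200 phantoms,
n = 5000 cohort, 500 variants. One full validation pass takes a few minutes
on one CPU.

## Limitations

- Inputs are label masks; no greyscale images, segmentation, DICOM, cine
  timing or papillary-muscle handling beyond what labels encode.
- Circular-annulus phantoms cannot probe errors from non-circular LV
  shapes, wall-thickness asymmetry or segmentation noise; passing tests
  validate the arithmetic and geometry of the measurement, not robustness
  to realistic segmentation artefacts.
- The OLS scan omits mixed-model machinery; its calibration on
  structure-free synthetic panels says nothing about confounded cohorts.
- PRS weights are consumed, never inferred; no shrinkage estimation.
- Proportional hazards are assumed, with exponential (constant-baseline)
  generative times; no competing risks or time-varying covariates.
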