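# Methods

This note documents the models behind `gpqa`, the defaults and why they
were chosen, what the synthetic data emulate (and what they do not), and
the numerical conventions. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate frame and geometry

The stereotactic frame is defined by the immobilization cup: `y` runs
along the cup axis with the chest wall at `y = 0` and the apex at
`y = apex_y > 0`; `x, z` span the transverse plane; the machine radial
coordinate is `r = √(x² + z²)`. The cup interior is modeled as a
half-ellipsoid of revolution: base radius `base_diameter/2` at the chest
wall (93.7 / 121.7 / 153.7 mm for the three outer sizes) tapering to the
apex. Inner cups come in ten chest-to-apex depth classes per outer size;
the default depth model is `apex_y = 40 + 8·index + {0, 6, 12}` mm. The
default kernel library covers 19 (size, index) combinations, with shallow
indices for small cups and deep ones for large cups, matching how the
plan generator assigns cups from breast volume.

The chamber-jig cylindrical coordinates are `(r, θ, y)` with
`θ = atan2(z, x)` in `[0, 360)` and `θ ≡ 0` on the axis.

## Kernel library

The secondary dose check consumes two table families per
(collimator, cup) pair, in reality exported from a Monte-Carlo beam
model:

* **Off-center ratios** `OCR(Δy, Δr)` on a regular lattice (default 1 mm
  spacing, ±50 mm), bilinear interpolation, exactly 1 at the origin node,
  0 outside the lattice (the beam is fully blocked far off-axis; no
  extrapolation).
* **Isocenter dose rates** (Gy/min) on a `(y, r)` lattice spanning the
  cup; queries outside the lattice are errors by design — a focal spot
  outside the cup is not a deliverable state.

The synthetic generator uses separable error-function-smoothed top-hats,

    OCR(Δ) = ½[erf((w/2−Δ)/σ√2) + erf((w/2+Δ)/σ√2)],

with measured width `w = 22.0 mm` for the 15 mm collimator (a
commissioning value), `w = 35 mm` for the 25 mm collimator and penumbra
`σ = 3 mm` (both configurable stand-ins — the device's true 25 mm-profile
width and penumbra are not asserted here). Dose rates decay exponentially
with depth below the apex, `rate = R₀·exp(−μ·(apex_y − y))·(1 − β(r/R)²)`
with `R₀ = 3 Gy/min`, `μ = 0.008 /mm`, `β = 0.05`: deep positions near
the chest wall of a large cup read lower than shallow positions in a
small cup, which is the qualitative behavior the check's rate tables
encode.

## Forward engine and the distortion model

The engine superposes, for every control point i,

    dose(p) += rate(Cᵢ, cup, yᵢ, rᵢ) · tᵢ · OCR(Δy/bᵢ, ρ/bᵢ) / bᵢ³,

where `Δy` is the axial offset, `ρ = hypot(x−xᵢ, z−zᵢ)` the transverse
distance (a cylindrically symmetric dose blob around each focal spot) and
`bᵢ = 1 + α·rᵢ/R` the distortion broadening, with `R = 50 mm` and
`α = 0.7` by default. The `1/b³` factor conserves each kernel's volume
integral: a distorted beam redistributes dose rather than creating it.
Off-center position is measured by the radial distance from the cup axis
— the same `r` that indexes the rate tables — so a shot on the axis is
undistorted and `α = 0` reduces the engine exactly to the
position-invariant central kernel. That exact reduction is the oracle
lever of the whole validation: at an on-axis reference point the
first-order kernel sum and the engine agree to machine precision when
`α = 0` (the acceptance script reports the worst deviation over 20
centered single-shot plans).

`α = 0.7` is deliberately strong. The volume factor is a one-variable
correction; for it to be meaningful in a synthetic study the systematic,
volume-driven part of the kernel-sum error must dominate the
plan-to-plan variability of the optimizer's dwell solutions (~2 % in the
calibration ratio). At `α ≈ 0.3` the two are comparable and the
volume-monotonicity of the error degrades (Spearman ρ ≈ 0.7 rather than
≈ 0.86 over the 50-plan default suite); the reported ρ also varies by a
similar margin between random 50-plan cohorts. The magnitude of the
resulting correction (ratios ≈ 1.04–1.23) is therefore larger than the
sub-percent discrepancies a clinical secondary check shows; the geometry
of the effect, not its scale, is what the synthetic study reproduces.

**Transit dose** (off by default): when enabled, the dose delivered while
the table moves between consecutive control points is integrated along
straight segments at constant speed (default 5 mm/s) by the trapezoidal
rule at ≤0.5 mm steps, using the departing point's collimator. The
default is off so the engine matches the static-shot assumptions of the
point-dose check; the infinite-speed limit reproduces transit-off to
1e−9.

**Grids**: default 1 mm voxels (0.001 cc, the planning system's
single-pixel readout). `neighborhood_mean` averages the 5×5×5 block
(0.125 cc at 1 mm), approximating a small thimble chamber's sensitive
volume; `point_dose` is trilinear. The orchestration loop uses 2 mm
voxels to keep a cohort run at a few seconds per plan; grid-refinement
convergence is covered by the test suite.

**Medium correction**: the 1.6 % water-vs-breast-density factor is
applied only explicitly, with a signed direction recorded in the result —
which side of the comparison it belongs to is deployment-specific and is
never guessed.

## Synthetic cohort generator

Plan attributes are drawn from Beta distributions rescaled to the
published 15-patient envelopes with the mean pinned at the cohort
average (GTV 2.9–29.1 cc, mean 11.1; PTV 21.7–153.9 cc, mean 66.9;
breast 722–1994 cc, mean 1264; control points 361–813, mean 491;
concentration 6 — a modest pseudo-sample size giving realistic spread
without edge-piling). The prescription is the cohort's single-fraction
8 Gy.

Shot placement emulates a planning optimizer rather than noise:

* positions are a quasi-random (Halton) Gaussian cloud around the target
  centroid, SD = r_PTV/1.5, with 0.5 mm per-shot jitter — quasi-random
  placement makes the cloud's radial profile essentially deterministic at
  a given count, as a real optimizer's pattern would be;
* the two collimators are interleaved deterministically through the
  delivery sequence (30 % at 25 mm);
* beam-on times are set by bounded linear least squares so the dose at
  128 low-discrepancy points inside the target equals the prescription
  (a nominal-kernel flattening; bounds 0.02–20 s). Uniform random dwell
  times were rejected during design: they produce a peaked in-target
  dose with no <0.5 %/mm plateau anywhere, which no clinical plan would
  exhibit and which breaks the film-normalization workflow;
* the target centroid sits at 40–60 % of the cup depth with a lateral
  offset up to 0.3·R_base (wall-limited), and shots are constrained to
  remain inside the cup after the lateral QA shift onto the axis.

What the generator does **not** emulate: realistic optimizer objectives
(coverage/conformity trade-offs), chest-wall and skin proximity
constraints, non-spherical targets, couch-path ordering, or any
correlation between target size and shot count (the published cohort
shows none). Passing tests therefore demonstrate the QA machinery on
idealized spherical-target plans, not performance on clinical anatomies.

## Independent point-dose check and the volume factor

`dose_ref_no_volume` implements the first-order overlay sum with the
*central* kernel only. It is azimuthally exact at an on-axis reference
point; at off-axis reference points its radius-difference argument
`rᵢ − r_ref` additionally approximates the true transverse distance, so
quantitative validation is done in the QA geometry (plan shifted so the
target centroid lies on the chamber, chamber on the cup axis at the
target's depth — also the geometry in which the empirical volume factor
is determined, since that is where phantom measurements are made).

`calibrate_vf` fits ground-truth/kernel-sum ratios against target volume
by ordinary least squares and reports the residual SD; corrected doses
multiply by the fitted line. A published preset (0.028 /cc, 2.7) is
available under `VfModel.paper_preset()`; its magnitude cannot be a
direct multiplier of a dose that already agrees to a few percent, so the
application convention (`multiply` / `divide` / `percent`) is an explicit
parameter of `dose_ref` and the calibrated ratio pathway defines the
default semantics. Percent differences use the planning-system value as
denominator: negative means the check or measurement reads below the
plan.

## Film and gamma analytics

Film enters as a response-valued plane (red-channel netOD). The
calibration model `netOD = a·D/(b+D) + c·D` (saturating plus linear term,
strictly monotone for non-negative coefficients) is fitted to 12 points
spanning 0.01–10 Gy and inverted numerically; any monotone model meeting
the 1 % round-trip contract would be conformant. Registration is
least-squares rigid (2-D Kabsch, no scaling) on the four holder-pin
marks. The synthetic film applies the inverse calibration, additive
Gaussian response noise and a known rigid misregistration, so the full
pipeline (register → convert → normalize → compare) closes exactly at
zero noise.

The gamma index is global (Low-style): dose differences are normalized to
a plateau dose, the evaluated plane is resampled to ≤0.1 mm steps aligned
with the reference pixels, and the DTA search scans all fine-lattice
offsets within 3·DTA. Pixels below 10 % of the normalization dose are
excluded from the pass rate. Defaults (3 %/1 mm, plateau normalization)
follow SRS practice; all knobs are exposed in `GammaParams`. The plateau
region is operator-supplied; `find_plateau_region` automates the choice
as the highest-dose square region (default ±3 mm) whose relative
gradient stays below 0.5 %/mm everywhere, and its validity is judged on
the *planned* plane so film noise cannot veto the operator's region.

`area_sensitivity(w, δ) = 100·δ/w` is the first-order width-to-area
(hence width-to-delivered-dose, for a scanned delivery) sensitivity; the
suite checks it against numerical quadrature of the actual profile shape
to 0.05 percentage points for widths 15–40 mm and perturbations up to
1 mm. `error_band_analysis` evaluates `k·SD` and the two-sided normal
tail `2(1−Φ(k))`. Outcome classification treats the measurement as truth:
a Type I error is a false fail of the independent check, Type II a false
pass; an optional distance criterion must be met jointly with the dose
criterion.

## Numerical conventions and degenerate inputs

Ties in low-gradient point selection break by largest dose, then smallest
distance to the structure centroid. FWHM is measured by linear
interpolation of the half-maximum crossings and requires a unimodal
profile. Collinear registration marks, non-monotone calibration
responses, all-equal calibration volumes, empty outcome lists,
out-of-grid points and uncovered (collimator, cup) pairs raise explicit
errors rather than degrading silently. All stochastic components take
integer seeds; reports round floats to six decimals so fixed-seed runs
are byte-identical.

## Problem sizes

The default validation assets use: 20 centered single-shot plans for the
oracle-equivalence check; 50 full-size synthetic plans (≈360–810 shots
each) for the volume-factor study, evaluated on 11³ voxel grids at the
chamber; 61×61 to 81×81 1 mm planes for the gamma and film suites; and
three ~320-shot plans on 2 mm grids for the orchestration tests. These
sizes were chosen so the whole suite runs in about a minute while every
check retains its discriminating power.
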