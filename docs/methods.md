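# Methods

## Scope and model

`cardiotfm` measures the contractile output of single micropatterned
cardiomyocytes by traction force microscopy (TFM). A cell adheres to a
rectangular extracellular-matrix micropattern printed on a soft
polyacrylamide hydrogel seeded with fluorescent fiducial beads; each beat
deforms the gel, the bead motion is tracked, and the traction stress the
cell exerted is reconstructed by solving the elastic inverse problem.

The substrate is treated as a linearly elastic, isotropic half-space.
That approximation requires the gel to be much thicker than the lateral
decay length of the deformation; gels of at least 100 µm are treated as
valid half-spaces (`ElasticSubstrate.half_space_valid`). Young's modulus
E is a free parameter (10 kPa ≈ healthy myocardium, 35 kPa ≈ fibrotic).
The Poisson ratio is not measured by the workflow; the package defaults to
ν = 0.5 (incompressible polyacrylamide, the standard assumption in
Fourier-space traction cytometry) and exposes it as a parameter.

For purely tangential surface traction T(x) the surface displacement is
u = K * T (convolution) with the Boussinesq/Cerruti surface kernel. In
Fourier space, per wavevector k (rad/µm):

    u(k) = G(k) T(k),
    G(k) = 2(1+ν)/(E|k|³) [ (1−ν)k² + ν k_y²,  −ν k_x k_y
                            −ν k_x k_y,        (1−ν)k² + ν k_x² ]

G is symmetric and positive definite for k ≠ 0; its eigenvalues depend
only on |k|. The k = 0 mode is undefined (traction of an isolated cell
is determined only up to a uniform offset) and is nulled by convention,
which also enforces global force balance on reconstructions.

## Forward model and phantoms (`phantom`)

Because single-cell TFM ground truth cannot be observed directly, the
package ships a first-class synthetic-data generator used by every
downstream test:

* **Traction truth** — a contracting cell on a 7:1 pattern is emulated as
  a force dipole: two Gaussian patches (default σ = 5–6 µm, peak 400 Pa)
  at the ends of the pattern's long axis, pointing inward. The field is
  exactly zero-mean per component, so it is force-balanced by
  construction. The analytic total scalar force of the dipole is
  2·(2πσ²·peak).
* **Displacement truth** — the forward Boussinesq solution evaluated with
  `rfft2` on a zero-padded grid (padding factor 2; padding suppresses
  periodic wrap-around of the slowly decaying 1/r kernel). Working in the
  real-input half spectrum keeps the inverse transform exactly real.
* **Beat modulation** — traction(t) = s(t)·T_peak with a raised-cosine
  pulse train s(t) ∈ [0,1]: each period starts fully relaxed, the active
  fraction (duty 0.4) rises smoothly to full contraction and back. The
  pulse is smooth (well-defined velocities), symmetric (contraction and
  relaxation impulses match), and frame 0 coincides with full relaxation.
  Default pacing 1 Hz.
* **Bead rendering** — beads are sampled uniformly at 0.08 beads/µm²
  (≥ 5 beads per default DIC subset in expectation, keeping subset
  tracking well-posed), advected by bilinear interpolation of the
  displacement field, and rendered as Gaussian spots (PSF σ = 0.3 µm) on
  a 16-bit background, with optional Poisson shot noise and Gaussian read
  noise. All randomness flows through one integer seed; identical seeds
  give byte-identical TIFFs.
* **Brightfield / survey phantoms** — the cell body is a textured capsule
  (rectangle with semicircular caps) on the pattern footprint; survey
  tiles contain textured ellipses on a 200 µm pitch with an exact truth
  table of area, aspect ratio and center.

What the phantoms do *not* emulate: out-of-plane traction, finite gel
thickness, photobleaching, focus drift, bead aggregation, cell doublets,
and optical aberrations. Passing the benchmark therefore demonstrates the
correctness of the numerical chain under the stated elastic model, not
robustness to every experimental artifact.

## Displacement tracking (`dic`)

Subset-based digital image correlation against a relaxed reference frame,
with the parameter set standard for these videos: subset radius 15 px,
node spacing 5 px, magnitude cutoff 10⁶, at most 20 sub-pixel iterations,
at 0.275 µm/px and 30 frames/s.

1. **Integer search** — zero-normalized cross-correlation (ZNCC) of each
   (2·15+1)² subset over a ±subset-radius search window. Box sums come
   from separable uniform filters over the whole frame, so each lag costs
   one filtered product image regardless of node count. In videos the
   previous frame's field seeds the search, narrowing it to ±2 px around
   the rounded guess.
2. **Sub-pixel** — a 9-point least-squares paraboloid on the 3×3 ZNCC
   neighborhood, then iterative refinement: both subsets are resampled by
   cubic B-splines at ±u/2 (symmetric resampling cancels the classic
   S-shaped interpolation bias to first order) and a Gauss–Newton step
   with the averaged reference/moving Jacobian (ESM) updates u until the
   update drops below 0.01 px or the iteration cap. ESM converges
   near-quadratically, so the stopping rule leaves errors well below the
   threshold. Nodes at a perfect integer match (ZNCC ≈ 1) skip
   refinement, which keeps pure integer shifts exact.
3. **Validity** — subsets that leave the frame, subsets without fiducial
   texture (std < 0.2× the frame std, e.g. no bead landed there), or
   non-finite results are flagged invalid, never raised.
4. **Outlier filtering** — a vector is replaced by the median of its valid
   8-neighbors when |u| exceeds the cutoff (interpreted as a permissive
   magnitude guard in px; it never fires at the default and is logged if
   it does), its correlation is below 0.5, or its normalized median-test
   residual (ε = 0.1 px) exceeds 2. More than 10% outliers rejects the
   field as corrupt tracking.

**Reference-frame selection.** A coarse pass (4× node spacing, ±4 px
search, no sub-pixel iteration) against frame 0 yields the mean-|u| trace
m(t). A naive "argmin of m(t)" would always return frame 0 (m(0) = 0 by
construction) and, when frame 0 is itself contracted, would select frames
at the *same contraction level* as frame 0 rather than relaxed ones. The
package instead uses the plateau of m(t): with a duty fraction below 0.5
the cell spends the majority of each cycle fully relaxed, so relaxed
frames form the densest plateau, located at the median of m(t). The
selected frame is the one closest to that median whose temporal neighbors
also sit on the plateau (excluding brief crossings during a stroke); ties
break toward the lowest index, so a constant video returns frame 0.

Measured accuracy on clean phantoms: integer shifts exact, 0.3 px shifts
recovered with MAE ≈ 0.001 px, smooth dipole fields with RMSE ≈ 0.05 px.
The residual floor is dominated by rendering/interpolation systematics,
not camera noise.

## Traction reconstruction (`fttc`)

Per wavevector, zeroth-order Tikhonov inversion

    T(k) = (G(k)ᵀG(k) + λ_abs² I)⁻¹ G(k)ᵀ u(k),   T(0) = 0,

computed on the mean-subtracted, zero-padded (factor 2) displacement with
`rfft2`; after cropping, the residual mean of each component is removed so
the reconstruction is exactly force-balanced. The dimensionless parameter
λ is scaled by λ_abs = λ·√(mean_k diag GᵀG), making the default grid (40
log-spaced points over ten decades, 10⁻⁶–10⁴) independent of stiffness and
grid geometry. Because G ∝ 1/E, relabeling the same displacement with a
different stiffness scales the traction exactly proportionally.

**L-curve selection.** Over the λ grid the solver records the residual
norm ρ(λ) = ‖G·T − u‖ and solution norm η(λ) = ‖T‖ (Parseval, in the
weighted half spectrum). ρ is non-decreasing and η non-increasing in λ
(Tikhonov monotonicity, asserted in tests). The corner of the smoothed
(3-point moving average) log-log curve is located by discrete curvature.
Two numerical subtleties matter for a square FTTC system:

* The curve has a *second*, often stronger knee at very large λ where the
  regularization starts erasing the signal itself (ρ → ‖u‖, η → 0).
  Corner candidates are therefore restricted to the well-fitted branch
  (ρ ≤ 0.2·max ρ) and the *first* significant curvature minimum from the
  under-regularized side is returned (ties toward smaller λ).
* For effectively noiseless input there is no noise corner at all; the
  selector then falls back to the largest second difference of log η
  within the well-fitted branch (warned), which lands at weak
  regularization, as it should.

On the standard noisy phantom the selected λ sits about half a decade
below the λ that minimizes the true interior traction error — inside the
broad flat minimum of the error curve — and the recovered mask-restricted
force is within a few percent of truth.

## Contractile metrics (`contractility`)

**Outline detection** uses the texture contrast of the cell body in a
single brightfield frame: local standard deviation (9 px window) → Otsu
threshold → closing → erosion by the texture-window half-width (the
variance map spreads the boundary outward by that much) → largest
component → hole filling. A blank pattern is rejected when the Otsu
threshold does not clear twice the median local std (pure noise splits).

**Traces.** The cell mask is dilated by 2 µm before integration —
reconstruction spreads traction slightly beyond the cell edge, and with a
200 µm pattern pitch the dilation cannot reach a neighbor. Per frame:
F(t) = Σ|T|·a over the mask (Pa·µm² = pN → nN), U(t) = ½Σ(T·u)·a
(Pa·µm³ → fJ), X(t) = mean |u| over the mask, v(t) = dX/dt smoothed by a
local quadratic polynomial over 5 frames (Savitzky–Golay). The force
baseline is the 5th percentile of F(t), robust to recordings that never
fully relax. Velocity is displacement-based (µm/s), following TFM
contractility conventions.

**Beat detection.** Peaks of F(t) with prominence ≥ 25% of
(max − baseline) and minimum separation of one period of the upper pacing
band (default band 0.4–1.6 Hz); the excursion must also clear 8× the
trace's high-frequency noise floor (1.4826·MAD of F minus its 5-point
median filter), otherwise the recording is rejected as "unidentifiable
contraction peaks" — the same bookkeeping used to exclude non-beating or
low-SNR cells in batch runs. Onset and end are the crossings of
baseline + 10% of cycle amplitude on each side of the peak, bounded by
the midpoints to neighboring peaks so events never overlap. Fewer than
two peaks is a rejection.

**Metrics** (averaged over detected cycles; `f_max_mode="max"` switches
the force to the single largest cycle):

| metric | definition | units |
|---|---|---|
| F_max | peak F − baseline | nN |
| E_max | peak U − baseline U (5th pct) | fJ |
| f_contr | 1 / mean inter-peak interval | Hz |
| v_contr | max v during rise | µm/s |
| v_rel | \|min v\| during decay | µm/s |
| I_contr | ∫(F − baseline)dt, onset→peak | nN·s |
| I_rel | same, peak→end | nN·s |
| t_contr | end − onset | s |
| t_vmax | time of peak v − onset | s |
| W_max | ∫(F − baseline)·v dt, onset→peak | fJ |
| P_max | max (F − baseline)·v during rise | fW |

W_max and P_max are defined as mechanical work and power along the
contraction stroke relative to the relaxed state; t_vmax is the
onset-to-peak-velocity interval. These operational definitions are
recorded in output metadata so cross-study comparisons can adjust. With
F − baseline ∝ s(t) and v ∝ ṡ(t), P_max/(F_max·v_contr) is a pure shape
constant of the pulse, which is the internal consistency property the
amplitude-sweep benchmark asserts.

## Cell locator (`locator`)

Survey tiles are flattened with a black top-hat (grey closing, 81 px
square footprint, separable), thresholded with Otsu, and measured with
second central moments. Aspect ratio is the major/minor axis ratio of the
second-moment equivalent ellipse — an estimator choice recorded here
because oriented-bounding-box definitions give systematically different
values for the same cell. Gates are inclusive on both bounds (defaults:
aspect ratio 1.5–12, area 300–3500 µm²), and the quadrant split against
median area / median aspect ratio uses ≥ on both medians for quadrant I.

Position lists are written in a versioned canonical JSON schema and the
Micro-Manager `.pos` dialects (1.4 `POSITIONS` and 2.x `map/StagePositions`)
are imported best-effort. Longitudinal matching estimates the rigid x-y
stage offset between days as the component-wise median of nearest-neighbor
displacement vectors (robust to attrition), then pairs mutually nearest
neighbors within 50 µm (< half the pattern pitch); several candidates
within tolerance of one target are all dropped with a warning rather than
guessed. The z coordinate is carried through but ignored by matching.

## Pipeline and summaries (`cohort`)

`run_tfm_pipeline` chains crop (default 200 × 85 µm window) → optional
2×2 binning → reference selection → per-frame DIC with outlier filtering
→ λ selection on the frame of maximal mean |u| from the tracked fields
(the corner is best defined at maximal signal), reused for all frames
(per-frame selection available) → FTTC → outline → traces → events →
metrics. Every failure becomes a status (`rejected_segmentation`,
`rejected_tracking`, `rejected_no_peaks`), so batch accounting is exact.

`summarize_group` reports n, arithmetic mean ± sd, geometric mean with a
log-t 95% interval (the appropriate summary for lognormally distributed
forces), and fold changes of group means against a declared control group
(arithmetic by default, geometric optional). Hypothesis testing is
deliberately left to downstream statistics environments.

## Benchmark problem sizes

The validation phantom used throughout the tests and the acceptance
script is a scaled-down single cell: a 900 µm², 7:1 pattern in a
110 × 44 µm field of view (400 × 160 px at 0.275 µm/px), 7 s at 30 fps,
paced at 1 Hz, 400 Pa peak patch stress on 10 kPa; secondary checks use a
400 µm² cell in a 66 × 27 µm field for 3 s. These sizes keep the full
render → DIC → FTTC → metrics chain fast enough to run many times in a
test suite while leaving ≥ 1.8 px of peak bead motion and thousands of
grid nodes — the same regime as production recordings. The geometry
helper and locator benchmarks use the full-size 2500 µm² pattern.

## Known limitations

* 2-D tangential traction only; no out-of-plane component and no
  finite-thickness correction.
* Translation-only subset shape functions (no affine subsets); adequate
  for the ≲ 2 µm displacements of single cardiomyocytes.
* The L-curve corner is found on a discrete 40-point grid; λ is resolved
  to about a quarter decade.
* Regularization biases the total reconstructed force downward while
  displacement noise biases it upward; comparisons against truth are made
  on the mask-restricted force, where the two effects are small and
  partially cancel. Absolute forces from different λ choices should not
  be mixed in one analysis.
* The locator's morphology gates are the only gating channels
  implemented; fluorescence-intensity or contractility-threshold gates
  are out of scope.
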