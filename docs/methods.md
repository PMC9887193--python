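# Methods

## The flow model

Blood in a vessel is modeled as two concentric Newtonian phases: an
RBC-rich core of viscosity μ_c occupying radii 0 ≤ r ≤ λ·r_v, and a
cell-free plasma annulus of viscosity μ_p between λ·r_v and the wall at
r_v. λ = 1 − δ/r_v, with δ the cell-free-layer width produced by RBC
migration toward the axis. During diastole the flow is treated as steady
Stokes flow in a rigid tube:

    dp/dz = μ(r) · (1/r) d/dr ( r dv_z/dr ),

with no-slip at the wall, regularity on the axis, and velocity and shear
stress continuous at the interface. Writing A = dp/dz (< 0 for forward
flow), the momentum first integral gives a shear stress τ_rz = A·r/2
independent of the viscosity profile; integrating once more yields the
two-segment parabola implemented in `two_phase_flow.analytic_velocity`.
The r² coefficients of the two branches are A/4μ_p and A/4μ_c, so their
ratio is μ_c/μ_p: the whole blood relative viscosity η_r. This identity is
what lets an image of v(r) act as a viscometer. (As typeset in its source,
the core branch of the closed form carries a sign inconsistency — its
interface value is the negative of the plasma branch's; the form
implemented here is re-derived from the boundary conditions and satisfies
no-slip, continuity, and the coefficient-ratio identity to round-off,
which the tests assert.)

`solve_profile_numeric` is an independent check, not a restatement: it
discretizes the conservative form d/dr(r μ v′) = A r by finite volumes on
a grid that places the interface on a node (piecewise-uniform spacing),
with zero flux at the axis and no-slip at the wall, and solves the
tridiagonal system. Because the exact solution is piecewise quadratic and
the scheme's flux and source quadratures are exact for that class, the
oracle agrees with the closed form to round-off; the tests only require
1e−6 relative.

Assumptions worth keeping in mind: both phases Newtonian (no Casson yield
core), rigid wall, axisymmetric steady diastolic flow, and a sharp
core/plasma interface. Pulsatility is reduced to a two-level waveform (see
below), not a Womersley solution.

## The forward image model

The acquisition saturates a slab of thickness 5 mm perpendicular to the
vessel, waits T_delay, and reads out with a T1-weighted FLASH sequence;
the flow-sensitive window is τ = T_delay + TE. Default protocol: TR/TE =
100/2.428 ms, T_delay = 17.572 ms (τ = 20 ms, the top of the 10–20 ms
validity band), flip 40°, FOV 20 × 14 mm², matrix 128 × 96 (pixels
0.156 × 0.146 mm²), 20 averages (scan time 192 s).

The renderer models exactly the geometry the inversion relies on and
nothing more. Per excitation at cardiac phase φ, an in-lumen pixel at
radius r and depth z into the slab is at full signal (1) if
z < v(r)·g(φ)·τ, else at the mono-exponential recovery level
1 − exp(−τ/T1) with T1 = 2200 ms (arterial blood at 7 T); pixels outside
the slab are at full signal; static tissue is a configurable constant
(default 0.05). Flip-angle and steady-state effects are folded into the
normalization. A pixel is bright if its *center* is reached
(nearest-center partial volume — no sub-pixel graying), which makes the
image a binary-per-pixel observation of the edge; this is the property
that dominates the error budget below. Noise is Gaussian on intensities by
default (σ as a fraction of full signal; Rician available), added once to
the excitation-averaged image.

The cardiac cycle is two-level: diastole occupies the phase fraction
d = 0.6 of a T_C = 160 ms cycle (375 bpm, an anesthetized-rat rate chosen
here as the package default — T_C is never assumed silently and must be
passed explicitly); during systole the whole profile is scaled by
`systolic_gain` (default 2, a typical PSV/EDV ratio). Excitation phases
advance deterministically by TR/T_C per excitation; with TR = 100 ms and
T_C = 160 ms the phases cycle through 8 equispaced values, of which 5 fall
in diastole.

**Segmentation threshold.** A pixel reached only by systolic inflow is
bright only on systolic excitations, so its averaged intensity is the
systolic sampling fraction (≈ 0.38 here) while the diastolic tongue stays
at 1. The probability that the flow-sensitive window is *not* wholly
diastolic is P = 1 − (T_dia − τ)/T_C; with the defaults P = 0.525 and the
80 % safety factor (guarding weak near-wall signal) gives the working
threshold 0.42, comfortably above the systolic plateau. Thresholding
therefore removes systolic information exactly in noise-free renders —
the pulsatile and diastole-only pipelines return identical η̂_r, which the
acceptance suite checks.

## The inverse pipeline and its error budget

Stages: optional crop → segmentation at the threshold above, applied on
the acquired grid → cubic-spline subpixel localization of the tongue
boundary along the read axis (one upstream unsaturated column kept as an
interpolation anchor) → per-row displacement = the half-signal crossing at
the end of the contiguous bright run from the slab boundary → vessel
axis/tilt correction → constrained two-parabola fit.

Design choices that matter, and why:

* **Segment before interpolating.** The systolic plateau sits only ~0.04
  below the threshold; interpolating first lets spline ringing at the
  bright/plateau step push values back over the threshold and extend runs
  irregularly. Zeroing sub-threshold pixels first leaves a clean 1→0 step
  whose half-signal crossing is the unbiased midpoint estimate of the
  boundary.
* **Contiguous run, not furthest bright pixel.** Identical on noise-free
  images (laminar inflow is contiguous with the upstream bright blood),
  but robust to isolated supra-threshold noise deeper in the slab.
* **Radial samples stay at acquired rows.** Interpolating intensities
  *across* rows manufactures no radial information and measurably biases
  the steep near-wall segment; the read-axis spline supplies all the
  subpixel benefit. For the same reason, upsample factors 1 and 4 perform
  equivalently here — the inverse-interpolated crossing at factor 1
  already has subpixel precision — and the test asserts equivalence rather
  than improvement.
* **Quantization is the noise floor.** With binary partial volume the
  tongue boundary in each row is known only to within one read pixel
  (0.156 mm); the crossing estimates its midpoint, so per-row displacement
  errors are bounded, near-uniform, ± h/2. Over a ~2 mm displacement this
  is a 4 % per-row error that no interpolation can reduce.
* **Fit: exhaustive breakpoint search with physical constraints.** For
  each candidate λ on a 0.01 grid in [0.5, 0.98], the plasma branch is fit
  as v = a_p(r_v² − r²) (no-slip built in) and the core branch as
  v = a_c(λ²r_v² − r²) + v_if with v_if = a_p·r_v²(1 − λ²) (continuity
  built in); λ̂ minimizes the objective, ties breaking toward larger λ
  (resolution overestimates the layer width). Two losses are provided:
  plain least squares (`loss="lsq"`, the default for analytic point sets,
  where it is exact) and minimax (`loss="linf"`, a small linear program),
  which the image pipeline uses because for bounded uniform quantization
  errors the minimax solution is the center of the model set consistent
  with the per-row brackets, whereas least squares inherits the particular
  quantization draw (measured: worst-case η error ~3 % vs 7–17 % across
  otherwise identical conditions).
* **Axis and tilt.** The tilt is found by grid search (±10°, 0.1° steps)
  maximizing even symmetry of the de-rotated displacement curve, with a
  parsimony rule — among angles within 5 % of the best symmetry score the
  smallest |angle| wins — because quantization leaves shallow spurious
  minima. Mirror symmetry locates the axis only to ~0.02 mm, which is
  enough to move η̂ by several percent, so the pipeline refines the center
  by minimizing the fit objective over sub-row shifts with the breakpoint
  search narrowed around the first pass.
* η_r < 1 and an objective curve flat across all candidate breakpoints
  (single-parabola flow) are flagged, not raised; zero displacement
  everywhere is an error, never a number.

## The synthetic battery (what passing tests show, and what they don't)

The recovery battery images a flow-phantom-scale vessel: r_v = 5 mm,
diastolic centerline velocity 120 mm/s, μ_p = 1.2 mPa·s, vessel axis at
mid-FOV plus 0.3 pixel, crossed over η_r ∈ {2, 4, 8}, λ ∈ {0.85, 0.9},
noise ∈ {0, 0.05}. The radius is set by identifiability: the cell-free
layer (0.5–0.75 mm) must span several pixels for the breakpoint to be
estimable at all — at rat-carotid scale (δ below one pixel) the layer
width is unresolvable, a limitation of the method itself, not of the
implementation. The velocity keeps peak systolic displacement
(2 × 120 mm/s × 20 ms = 4.8 mm) inside the 5 mm slab, the protocol's own
design condition for choosing T_delay. The sub-pixel axis offset is the
generic case: a vessel exactly aligned with the pixel raster is degenerate
(mirrored rows sample identical quantizer phases, halving the radial
information).

Under these conditions the pipeline recovers η_r to ~3 % worst case
noise-free (λ̂ exact on the grid) and a median within ~1 % under σ = 0.05
Gaussian noise over 20 seeds. At other sub-pixel alignments the noise-free
worst case grows to ~8 % — the quantization floor moves with the arbitrary
alignment, which is the honest statement of the resolution limit.

What the synthetic battery does **not** emulate: graded partial-volume
edges (real voxels average, they don't binarize), flow-related phase
dispersion (absorbed into the 80 % threshold safety factor in the original
protocol), vessel wall signal and motion, Bloch/k-space physics,
through-plane curvature, and physiologic waveforms beyond the two-level
systole/diastole approximation. Passing the battery shows the inversion is
correct and well-conditioned against the stated forward model; it does not
by itself establish in-vivo accuracy.

## Rheology and statistics

WBRV on the rheometer side is WBV/PV per shear rate; the bundled 13-rat
panel reproduces every reported WBRV cell within rounding (one cell is off
by one unit in the last place, consistent with one-off rounding). Group
comparison uses an exact two-sided rank test computed by full enumeration
of all C(n_A + n_B, n_A) relabelings (U with midrank ties; p = proportion
of relabelings at least as extreme as observed). With five animals per
group the smallest attainable p is 2/252 ≈ 0.0079, which is exactly what
the completely separated NC/EPO comparison at 200 s⁻¹ yields. A pooled
t-test is provided as a labeled alternative; with n = 5 the exact test's
freedom from normality assumptions is the reason it is the default. The
vascular resistance index is (PSV − EDV)/PSV from pulsed Doppler.

## Numerical details

Units are mm, mm/s, mPa·s and Pa/m throughout; these are mutually
consistent (Pa/m · mm² / mPa·s = mm/s), so no conversion constants appear
in the formulas. Problem sizes: profiles are solved on 2000-point radial
grids (1000 in the oracle-comparison tests); images are 96 × 128; the
noisy battery uses 20 seeds. All randomness flows through
`numpy.random.default_rng` seeded explicitly; noise-free renders are
seed-independent and bit-reproducible, and the fixture generator writes
SHA-256 checksums to its manifest. The minimax fit is solved with HiGHS
via `scipy.optimize.linprog`; degenerate candidate splits (no plasma rows,
rank-deficient core) are skipped rather than fit.
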