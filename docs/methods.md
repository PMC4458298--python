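# Methods

## Measurement model

Continuous-wave photon transport in tissue is modelled by coupled
diffusion equations at the excitation (x) and emission (m) wavelengths,

    div(D_x ∇Φ_x) − μ_ax Φ_x = −q ,
    div(D_m ∇Φ_m) − μ_am Φ_m = −x·Φ_x ,

with D = 1/(3(μ_a + μ_s′)) and the Robin boundary condition
Φ + 2 A_n D ∂Φ/∂n = 0.  The fluorescent yield x = η·μ_af with
μ_af = ln(10)·ε·C (ε molar extinction, C concentration, η quantum yield)
drives the emission field linearly, so the boundary readings obey
φ = A x for a weight matrix A.

A dynamic acquisition stacks K such measurement vectors: with P sources
(dye-holding regions), frame k is Σ_p c_p(t_k)·a_p + B + ε, where a_p is
the pattern A applied to region p's unit-yield indicator, c_p its time
course, B a static background (removed by pre-injection subtraction) and
ε zero-mean Gaussian noise with PSNR = 10·log10(s²/σ²), s² the peak power
of the clean frames.

### Discretization

Piecewise-linear Galerkin elements on a structured right-triangle mesh of
a rectangle (no external mesher; point location is a grid lookup).  The
assembled operator D·K + μ_a·M + (1/2A_n)·M_boundary is symmetric positive
definite; solves use a cached sparse LU factorization.  The collimated
laser is an isotropic point source one transport mean free path (1/μ_s′)
inside the boundary — the standard diffusion-theory convention — and a
detector reads the nodal photon density at a boundary node.  The weight
matrix is assembled by one adjoint emission solve per detector
(n_detectors ≪ n_nodes), each row being (M g_d) ∘ Φ_x,s.

A_n defaults to 1 for matched boundaries; for n ≠ 1 the Groenhuis
polynomial approximation of the internal diffuse reflectance is used.
FEM order, mesh density and the Robin constant are conventions (the
modelled physics does not pin them); they are exposed in configuration.

Validation: on a 40×40 mm mesh at h = 0.5 mm with μ_a = 0.02 mm⁻¹,
μ_s′ = 1.0 mm⁻¹, the solution for a central point source deviates from
the analytic 2-D infinite-medium Green's function K₀(μ_eff r)/(2πD) by
under 1% at radii 3–8 mm (the acceptance script recomputes this bound).

## Convex separation (CAMNS)

After sum-normalizing the frames (each divided by its pixel sum, so that
mixing weights sum to one and the observation affine hull coincides with
the source affine hull), the frames lie in the (P−1)-dimensional affine
hull of the sum-normalized sources.  Under **local dominance** — every
source owns at least one pixel where the others are exactly zero — the
sources are precisely the extreme points of

    { s = Hβ + d : s ≥ 0 } ,

with d the mean observation and H an orthonormal basis of the centered
observation span (computed through the K×K Gram eigendecomposition; K ≪
N).  Each vertex is obtained from a pair of linear programs minimizing and
maximizing rᵀ(Hβ + d) for a seeded random direction r, with r projected
orthogonal to the vertices already accepted so every draw explores a new
face.  A candidate is accepted as new if its distance to every accepted
vertex exceeds 10⁻⁶·‖d‖; at most 10·P draws are attempted before a
non-identifiability error (carrying the per-draw diagnostics) is raised.
Estimated time courses come from nonnegative least squares of the frames
on the recovered sources.

### Noise handling

Three devices make the vertex search stable under measurement noise; all
three reduce to no-ops on noise-free data.

1. **Inverse-variance-weighted affine fit.**  Sum-normalization divides
   frame k's noise by its sum, so dim (late washout) frames are noisier.
   Inside the separation path the affine hull is fitted with per-frame
   weights sum_k² (inverse noise variance).  Any weighting spans the same
   hull on exact data; the public affine-fit operation remains the plain
   unweighted estimator.
2. **Constraint screening.**  A pixel with no source at it contributes a
   nonnegativity constraint that is never active in exact arithmetic (its
   row of H and entry of d are zero) but, under noise, cuts the feasible
   set at a random position — the worst such pixel dominates and biases
   every vertex inward.  Pixels are therefore screened by a χ²_K test on
   their frame energy in the raw (homoscedastic) stack, with the noise
   scale estimated from the energy outside the rank-P singular subspace
   and a Bonferroni-corrected level of 10⁻³ per stack.
3. **Slack and de-biasing.**  The polyhedron is relaxed to
   Hβ + d ≥ −(10⁻⁹ + 3σ̂_d), σ̂_d the noise level of the weighted mean,
   so noise-driven negative pixels cannot empty it; each LP optimizer is
   then shrunk along the ray from the mean until its binding constraint
   sits at zero, removing the deliberate inflation.

The noise sensitivity that remains is intrinsic: vertices are located by
the most-binding constraint, so sources surrounded by a halo of
faint-intensity pixels (e.g. heavily blurred patterns) degrade vertex
accuracy faster than crisp patterns do.  This matches the field
observation that separation improves with the number and strength of pure
pixels.

## Baselines

**PCA** takes the top-P right singular vectors of the frame-centered
stack, sign-aligned (largest-magnitude entry positive) with the score
columns flipped consistently.  It is exact only for spatially orthogonal
sources with uncorrelated centered courses, and its outputs may be
negative (flagged).

**ICA** is a fixed-point negentropy FastICA written for this package:
row-centering, whitening to P components, deflation with the log-cosh
contrast (tolerance 10⁻⁶, 500 iterations), three restarts keeping the
highest total negentropy, per-component convergence flags.  Because
row-centering shifts every component image by a constant, the source
images are re-derived by regressing the uncentered frames on the
estimated mixing courses.  A test cross-checks the component span against
scikit-learn's FastICA.

## Source counting

The K×K correlation matrix of the stack with per-frame pixel means
removed is eigendecomposed.  Two rules read off P: `ratio` counts
eigenvalues above 10⁻⁶·λ₁ (suited to noise-free data, where the spectrum
falls to round-off beyond the true rank; the default threshold sits far
below the smallest ratio observed between genuine and negligible
eigenvalues in practice), and `log-gap` places P at the largest gap of
the log-eigenvalues (suited to noisy data, where trailing eigenvalues
form a flat noise floor).  The log-gap rule assumes the spread among the
signal eigenvalues is smaller than the signal-to-floor gap; when the
sources' courses are strongly correlated the weakest signal eigenvalue
shrinks and the rule can undercount at moderate PSNR — inspecting the
returned spectrum is advised in that regime.

## Error metric and matching

δ = Σ_p Σ_n (ȳ_pn − s̄_pn)² on max-normalized images, after exhaustive
best-permutation matching (P ≤ 6) with optional per-source sign flips for
the baselines.  The formula is used literally — no square root, no
division by N — so values scale with image size; a conventional
sqrt-of-mean variant exists behind a flag but is not used in any
benchmark here.  The joint sum over all sources is reported (not
per-source tables).  Negative baseline outputs are kept when normalizing,
as clipping would hide exactly the failure mode the metric should expose.

## Synthetic scenes

The generator produces the study conditions; its defaults are fixed, not
tuning knobs.

* **Local-dominance instances** (unit tests and exact-recovery checks):
  P patterns on N pixels, each owning a disjoint block of pure pixels
  (values U(0.5, 1.5)) with all sources U(0, 1) elsewhere; courses are
  U(0.1, 1) K×P matrices redrawn until the condition number is ≤ 15
  (distinct pharmacokinetics; a nearly collinear draw would make the
  mixture unidentifiable for any method).
* **Acquisition grid**: six time points at 5, 10, 15, 30, 60, 120 min.
* **Correlated scene** (two organs sharing a rim): overlapping uniform
  ellipses on a 32×32 image; blood-pool course (immediate peak, washout)
  and perfused-organ course (slightly delayed peak), temporal correlation
  0.82.  Each organ core retains pure pixels while the overlap breaks
  spatial orthogonality.
* **Uncorrelated scene** (dye tubes in different body regions): two
  disjoint uniform ellipses covering ≈1.5% of a 32×32 image each —
  comparable to 2 mm tubes in a 25–30 mm phantom — with the uptake course
  orthogonalized (after centering) against the blood-pool course and
  rescaled to its own dynamic swing, late frames kept above dark by
  residual dye.  Clean frames are scaled to peak amplitude 1 so the noise
  variance grid {1, 10⁻¹, …, 10⁻⁶} corresponds to PSNR 0–60 dB.

Sources are uniform-intensity with crisp boundaries, as for dye-filled
tubes or segmented organ maps.  What these scenes do **not** emulate:
camera optics (PSF, vignetting), Poisson shot noise, 3-D geometry,
scattering-blurred *image-domain* sources (a faint halo degrades any
vertex-seeking method — see Noise handling), or pharmacokinetic model
fitting.  Passing benchmarks on them demonstrates the separation
mathematics under the stated assumptions, not end-to-end hardware
performance.

## Monte Carlo protocol

For each variance in the grid and each repetition, noise is regenerated
from a seed derived deterministically from (base seed, variance index,
rep); each method separates the stack with the true P, and δ against the
known truth is recorded (sign flips allowed for PCA/ICA).  Failures of a
cell are stored as NaN and excluded from means with a failure count; at
0 dB the convex method's LP typically has no feasible polyhedron and is
reported as failed, mirroring the regime where no method separates.
Benchmarks use 20 repetitions — large enough for stable means on these
scenes while keeping the default suite fast.

## Numerical choices

* LP solver: HiGHS via `scipy.optimize.linprog`; polyhedron slack as
  above; degenerate LP ties are broken by the next seeded direction.
* Affine fit requires centered rank ≥ P−1; identical frames raise a
  degenerate-stack error rather than returning an arbitrary basis.
* Sum normalization rejects nonpositive frame sums (empty-frame error).
* Background subtraction never clips negatives and a flag prevents double
  subtraction.
* All randomness flows through integer seeds; per-draw LP objectives and
  accepted candidates are logged for replay.

## Known limitations

* 2-D forward model only; the separation mathematics is
  dimension-agnostic but absolute photon densities are not comparable to
  3-D phantoms.
* Counting rules can undercount strongly correlated sources at moderate
  PSNR (see above) and the ratio rule overcounts on noisy data; pick the
  rule to match the noise regime.
* Vertex accuracy degrades gracefully but measurably below ≈30 dB PSNR;
  no spatial regularization is applied (out of scope).
* Exhaustive matching in the evaluator limits comparisons to P ≤ 6.
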