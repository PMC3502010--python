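# Methods

`nodemorph` implements a three-stage pipeline for characterizing lymph
nodes on CT slices: edge-preserving denoising, boundary segmentation, and
morphometric classification of node status (benign vs malignant).  This
note records the models, the numerical choices, and what the synthetic
test surface does and does not demonstrate.

## 1. Edge-enhanced nonlinear diffusion

The denoiser evolves the image `u(x, t)` from the observed image `I` under

    u_t = mu * div( g(|∇G_σ0 ∗ u|) ∇u ) − (|∇u| / max|∇u|) (u − I)

with homogeneous Neumann (no-flux) boundaries.  Two mechanisms cooperate:
the diffusivity `g` (monotone decreasing, `g(0) = 1`) shuts diffusion down
across strong pre-smoothed gradients, and the fidelity term is weighted by
the normalized local gradient, so the solution is pinned to the data
exactly where edges live while flat regions relax to their local mean.
On a constant image both terms vanish identically.

Choices and defaults:

* **Diffusivity.** `g(s) = 1 / (1 + (s/k)²)` by default; a total-variation
  flavored alternative is available as `g(s) = k / (s + k + ε)` — the TV
  form `1/(s+ε)` rescaled so that `g(0) = 1`, because an unbounded
  diffusivity both violates the `g ∈ (0, 1]` contract of the API and
  destroys the explicit scheme's stability bound.
* **Contrast parameter** `k`: defaults to the 90th percentile of
  `|∇G_σ0 ∗ I|` at `t = 0`, a standard automatic choice that adapts to
  image contrast.  `σ0 = 1` px, `mu = 1`, 50 iterations.
* **Discretization.** Explicit forward Euler; central differences with
  edge replication for gradients; a conservative 5-point flux form for
  `div(g ∇u)` with arithmetic-mean half-point diffusivities.  Because the
  replicated edges carry zero flux, the scheme conserves the image sum
  exactly (the Perona-Malik baseline inherits mean conservation and, with
  `g ≤ 1` and `dt ≤ 0.25`, a discrete maximum principle).  The time step
  is validated against the 2-D explicit stability bound 0.25.
* **Fidelity weight degeneracy.** `max|∇u|` is recomputed globally each
  iteration; when it is zero (constant image) the weight is defined as 0;
  otherwise `ε = 1e−12` guards the division.
* **TV/ROF baseline.** `u_t = div(∇u / (|∇u| + ε)) − λ(u − I)` with
  `ε = 1e−3`.  The TV diffusivity is unbounded in flat regions, so the
  step is capped adaptively at `0.25 / max g` and `0.9 / λ` per iteration;
  with large `λ` this correctly degenerates toward the identity.
* The median and bilateral baselines are conventional; the bilateral
  window is truncated at 4 spatial sigmas so its wide-range limit matches
  the Gaussian smoother exactly.

## 2. Repulsive-force GVF snake

The snake minimizes the usual energy (tension `α`, rigidity `β`, external
weight `λ`).  The external force is the gradient vector flow of the edge
map `f = |∇(G_σ0 ∗ I)|²`: the field `(u, v)` solving

    μ ∇²u − (f_x² + f_y²)(u − f_x) = 0     (and likewise for v).

**GVF solver.** The discretized equations are solved by Jacobi iteration
`u ← (μ Σ_neighbors u + b f_x) / (4μ + b)` with `b = f_x² + f_y²`,
starting from `(f_x, f_y)`, with replicated-edge (Neumann) Laplacian.
The system is strictly diagonally dominant, so the iteration converges
unconditionally to the unique solution; tests verify agreement with a
direct sparse solve to 1e−8.

**Repulsion.** Adjacent bright structures bend the GVF field in the gap
toward their stronger edges, so a plain GVF snake leaks onto the
neighbor.  The repulsive field keeps the vector at pixels inside the
initialization region R (the filled interior of the user's initial
contour) and negates it everywhere else.  Forces beyond the
initialization therefore push the curve back toward its own object — an
exact, magnitude-preserving sign flip, involutive outside R.

Numerical choices:

* The edge map is rescaled to `[0, 1]` before the GVF solve so the force
  amplitude (and hence the per-step vertex displacement) is independent
  of image contrast.
* Pipeline order is fixed as edge map → GVF diffusion → repulsion.
* The evolution starts from the initial contour shrunk 2 px toward its
  centroid (in both plain and repulsive modes): the repulsed field
  changes sign exactly on the boundary of R, so vertices seeded on that
  line would sample an ill-defined force direction.
* Evolution is semi-implicit: internal forces through the inverse of the
  cyclic pentadiagonal stiffness system (step `γ = 1`), external force
  explicit, sampled by bilinear interpolation at vertex positions
  (x = column, y = row, pixel centers at integers).  Vertices are
  redistributed to uniform arc length every 10 iterations; convergence is
  declared when the largest vertex displacement falls below 0.05 px.
* Defaults `α = β = 0.1`, `λ = 1`, `μ_gvf = 0.2`, 200 GVF iterations,
  400 evolution iterations.  Raw (unnormalized) GVF vectors are used; a
  unit-normalization flag exists.
* Masks are rasterized by the pixel-center rule (centers on the polygon
  boundary count as inside), implemented with shapely predicates.

A known limitation follows from the repulsion definition: the sign flip
protects only against attractors *outside* the initialization region, so
an initial contour drawn loosely enough to enclose part of a neighboring
object gains nothing from it.  The initialization should encircle the
target snugly.

## 3. Morphometry

Nineteen features per segmented node, in a fixed canonical order (a
published contract): area, perimeter, long/short axis diameter (from the
moment-equivalent ellipse), axis ratio, circularity `4πA/P²`,
eccentricity, extent, solidity, compactness, boundary fractal dimension,
boundary irregularity (perimeter / convex perimeter), nodal density
(mean intensity), heterogeneity (intensity SD), intensity entropy
(32-bin), skewness, kurtosis, edge sharpness (mean boundary gradient),
and normalized radial-length variance.  This panel is a reconstruction
of a standard shape + first-order-texture battery: the seven
discriminative measurements it must contain (fractal dimension,
heterogeneity, both axis diameters, nodal density, solidity, plus
circularity as the seventh shape descriptor) are all present.
Heterogeneity is defined as the population SD of intensities; histogram
entropy is kept as a separate feature.

* **Fractal dimension** is the box-counting dimension of the 8-connected
  inner boundary over dyadic box sizes from 2 to `min(h, w)/4`, clipped
  to `[1, 2]`.  The box grid is anchored at the array origin, so the
  estimate can move by a few hundredths under translation — inherent to
  fixed-grid box counting.
* **Solidity** divides the pixel count of the region by the number of
  pixel centers covered by the convex hull of the region's pixel
  centers.  Measuring both areas in the same currency makes digitized
  convex shapes score 1.0 (a polygon-area denominator systematically
  penalizes small disks).
* Size features are multiplied by the pixel spacing (mm) when provided;
  higher moments of a constant region are reported as 0.

## 4. Feature selection and classification

The labeled table is split once into two stratified halves S1/S2 (seeded).
A classifier trained on S1 gives each feature a permutation importance:
the mean drop in S2 accuracy over 20 seeded permutations of that
feature's S2 column (a single permutation is noisy; 20 repeats stabilize
the ranking at modest cost).  Backward elimination removes the
least-important feature (ties broken by canonical order) but refuses a
removal that pushes the consistency loss

    Loss = |P(S1) − P(S2)| + 2 |Q(S1) − Q(S2)|

(P accuracy, Q sensitivity) above the best value recorded so far, and
never goes below 2 features.  The doubled sensitivity term reflects the
clinical asymmetry: a missed malignant node costs more than a false
alarm.  Forward selection then greedily re-adds removed features while
S2 accuracy strictly improves (ties to the lower canonical index).  The
two passes alternate until the active set is stable, at most 10 rounds.
Importance ranking uses the accuracy drop; the stopping rule uses the
loss — the two roles are deliberately separated.

Classification is an SVM (default RBF, `C = 1`, `gamma = "scale"`,
features standardized on the training fold); evaluation is leave-one-out
cross-validation with accuracy, sensitivity (positives = malignant = +1)
and specificity from the confusion table.  A metric whose denominator is
empty is reported as missing, never as 0.  No class weighting by default.

## 5. Synthetic data

The generators are pure functions of (spec, seed):

* **Shape scenes** — piecewise-constant disk/rectangle/annulus images
  with exact masks and boundary edge maps; Gaussian noise is recentred
  and rescaled so the realized SNR matches the requested dB exactly.
  The denoising protocol uses 128×128 scenes at 9.46 dB.
* **Adjacency scene** — two disks of radius 20 separated by a 2 px gap;
  the distractor is twice as bright, emulating a node abutting an
  enhancing vessel, which is what makes the plain GVF snake leak.
* **Node phantoms** — star-shaped regions `r(θ)` with seeded harmonic
  perturbations (low harmonics for lobulation, high for spiculation)
  whose amplitude scales with the irregularity parameter, plus i.i.d.
  Gaussian internal texture; the Koch-snowflake phantom provides a
  boundary of known dimension log 4 / log 3 ≈ 1.262.
* **Feature tables** — informative columns `N(±effect/2, 1)` by class,
  noise columns `N(0, 1)`.  The recovery simulation uses n = 200,
  3 informative features at effect size 2, 16 noise features.  The
  phantom-derived table renders 100 phantoms (overlapping class ranges
  of irregularity and texture SD, size and attenuation uninformative)
  and measures them with the real feature extractor.

What these fixtures do *not* emulate: CT noise correlation and artifacts
(beam hardening, partial volume), 3-D structure, anatomic context, and
the correlation structure of real nodal morphometry.  Passing tests
demonstrate the algorithms' contracts and directional behavior, not
clinical performance; the clinical accuracy of the original application
is not reproducible from synthetic data and is not claimed.

## 6. Problem sizes and determinism

The test suite and the acceptance script use 128×128 images, ≤ 9×9 grids
for exact GVF comparisons, 100–200-sample tables, and 20-seed selection
simulations — sizes at which every reference quantity is computable
exactly or with negligible Monte-Carlo error.  All randomness flows
through explicit seeds (`numpy.random.default_rng`); the pipeline derives
a named substream per stage from the single global seed, so every
artifact is byte-reproducible.
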