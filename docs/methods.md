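# Methods

This note documents the models and procedures implemented in
`osteomorph`, the parameters that matter, the synthetic data the test
suite and the acceptance script run on, and the numerical choices made
where the design was genuinely open.

## 2D outline model

A closed outline is treated as a pair of periodic coordinate functions
`x(t), y(t)` of the arc-length parameter `t ∈ [0, T]` and expanded in
elliptic Fourier descriptors (EFD). For a polygonal contour the
coefficients have the classic piecewise-linear closed form over segment
increments `Δx_p, Δy_p, Δt_p`; `A0, C0` are the arc-length centroid.
One harmonic describes an ellipse; the default of **26 harmonics**
reconstructs the synthetic outlines to well under 1% of the perimeter
(asserted in the suite).

Two consequences of the arc-length parametrization are worth spelling
out because they are easy to get wrong:

* The EFD of an axis-aligned `(2, 1)` ellipse is **not** `a1 = 2,
  d1 = 1`. Those are the coefficients of the trigonometric
  parametrization; under arc length the first harmonic is
  `a1 ≈ 1.8284, d1 ≈ 1.0730`, with energy pushed into odd higher
  harmonics (`a3 ≈ 0.1289, d3 ≈ 0.0893`). The test suite freezes these
  values from an independent oracle (dense numeric reparametrization by
  cumulative arc length followed by an FFT) and requires agreement to
  1e-4 at 1024 contour points.
* `efd ∘ reconstruct` is idempotent only for constant-speed curves. A
  truncated Fourier curve is not arc-length parametrized, so re-applying
  the transform re-parametrizes it and perturbs the coefficients at the
  order of the truncated energy. The suite asserts exact idempotence
  (1e-9) on a circle and a 1e-2 relative bound on generic outlines.

**Longest-radius normalization** removes translation (curve centroid to
origin), rotation (centroid-to-farthest-vertex radius onto +x), scale
(that radius to 1) and the starting point (moved to that vertex), then
recomputes coefficients. Radius ties within 1e-9 (circles, symmetric
ellipses) are broken at the smallest arc-length position and flagged.
Normalized coefficients are invariant to similarity transforms and
start-point shifts of the input to better than 1e-6 (property-tested
with 100 random draws). Reflections are deliberately not removed: left
and right bones are biologically chiral objects.

Chain coding uses Moore-neighbour boundary tracing with Jacob's
stopping criterion on the largest connected, hole-filled foreground
component (Otsu threshold by default). Boundaries are emitted
counterclockwise in an x = column, y = −row frame; Freeman direction 0
is +x, numbering counterclockwise.

Ordination is PCA on the **covariance** matrix of coefficient vectors
(correlation PCA is not offered; coefficients share units). Columns
with variance below 1e-12 are dropped and recorded. The per-axis
wireframe export reconstructs outlines at mean ± 2 SD along a
component.

## 3D surface model

Meshes are cleaned (vertex merge, degenerate-face removal, hole
filling) and brought within 10% of a target face count by quadric-error
edge collapse (area-weighted plane quadrics, optimal vertex placement,
link-condition and normal-fold guards) or midpoint subdivision. On a
5120-face icosphere decimated to 2000 faces the surface moves by less
than 0.3% of the radius (checked against a brute-force point-to-
triangle oracle).

Surfaces are compared as area-weighted uniform point samples
(default 2000 points per specimen). Superimposition is a modified ICP:
principal-axes initialization with gross scale matched first and all
four proper axis-sign branches evaluated (the best by PSM wins; a
clearly better improper branch only raises a "mirrored?" flag — no
reflection is ever applied), then alternating nearest-neighbour
correspondence and SVD least-squares similarity estimation, accepting
only PSM-decreasing steps. Axis signs are canonicalized by the third
moment of the projections on the first and last principal axes, with
the middle axis completing the right-handed frame; plate-shaped bones
have strong skew on those two axes, which makes the winning branch
stable across resamplings — the property the prototype-screening
consistency criterion relies on.

The **Procrustes surface metric** between aligned clouds is the
symmetrized root-mean-square nearest-neighbour distance
`sqrt(Σ d(a,B)²/(2m_A) + Σ d(b,A)²/(2m_B))`; its exact formula is a
package convention (a one-directional prototype-to-specimen variant is
available by flag for sensitivity checks).

**Generalized alignment** superimposes every specimen to the prototype
points, homologizes (closest specimen point per prototype point, giving
a specimens × 3m matrix), and replaces each prototype point by the
homologized mean, iterating while the mean PSM improves by more than a
**5% relative tolerance**. The cut-off is deliberate: iterating the
mean surface to numerical convergence progressively erodes features
carried by only part of the cohort (the planted medial tips vanish from
the prototype within ~10 iterations), which is the surface-analysis
analogue of fine structure absent from the prototype being lost. For
the same reason the deviation heat map is most informative with a
prototype that carries the cohort's distinctive features — the
"intermediate specimen covering the variation" guidance; the
localization test therefore nominates a tip-bearing specimen.

Scale removal (Procrustes convention) is the default: the prototype is
normalized to unit centroid size and per-specimen scale is estimated in
the ICP step; centroid sizes are always recorded separately so size can
be analysed on its own. Without scale removal a doubled specimen
separates on PC1 (asserted).

**Misalignment rule** (the original procedure relied on visual
inspection; this package needs an automatic criterion): a specimen is
flagged when its final PSM exceeds the cohort median by 3 IQRs *and*
1.5× the median (the floor stops hair-trigger flags in tightly
clustered cohorts), or when its initialization branch deviates from its
modal branch in ≥ 2 of the alignment repeats. Branches are recorded
from the first outer pass — against the nominated prototype itself —
because branch stability against the evolving mean cloud says nothing
about prototype suitability.

## Prototype and resolution screening

Candidate (prototype, face-count) combinations are screened in two
strictly ordered stages. (1) *Consistency*: the generalized alignment
runs `n_alignment_repeats` (default 5) times per combination with fresh
sampling seeds — sampling is the stochastic element that makes repeats
informative — and the union of flagged specimens is counted; only
minimal-count combinations survive. (2) *Disparity*: each surviving
combination's retained PC scores are z-scored per axis and per repeat,
stacked into one matrix (so disparity reflects every repeat, not just
the last), and the sum-of-ranges and convex-hull-surface indices are
bootstrapped (default 5000 resamples of specimens). The chosen
combination minimizes the median hull surface and, among hull ties,
maximizes the median range, on the premise that a large morphospace
with little inter-specimen structure is noise. The full metric table
(medians, quartiles, Bonferroni-corrected pairwise Welch t on the
bootstrap distributions) is always emitted so the choice can be
overruled. Exact ties fall back to (face count, prototype id) order and
are flagged.

## Statistics

* **Broken stick**: retain leading axes while the observed variance
  share exceeds `b_k = (1/p) Σ_{i=k..p} 1/i`, stopping at the first
  failure. Configured axis exclusions (e.g. an axis known to carry a
  preprocessing artifact) are skipped and the retained count is
  extended past them.
* **PERMANOVA**: sequential (Type-I) sums of squares on the
  Gower-centred inner-product matrix of Euclidean distances between
  retained scores; pseudo-F per term; p-values from free row
  permutations, `p = (1 + #{F* ≥ F}) / (1 + n_perm)` with 9999
  permutations by default (so the attainable floor is 1/10000 = 0.0001).
  Orderings that alias a term (zero added rank) are refused. Because
  reproductive strategy is constant within species, the two are
  partially confounded; the pipeline emits both a species-last and a
  species-first ordering rather than privileging one. Agreement with
  vegan's `adonis2` (sequential SS, Euclidean) is asserted to 1e-8 on a
  fixture. A type-I calibration over 1000 null cohorts stays within
  [0.03, 0.07] at α = 0.05.
* **Disparity**: per group, sum of per-axis score ranges and the convex
  hull boundary measure (perimeter in 2D, surface area in 3D+),
  bootstrapped by resampling specimens with replacement; degenerate
  point sets are measured in their affine span with the dimensionality
  reported. Pairwise Welch t on bootstrap distributions with Bonferroni
  correction.
* **PGLS**: GLS with covariance `V(λ)` — the Brownian shared-path
  matrix with off-diagonals scaled by Pagel's λ — with λ profiled on
  [0, 1] by **REML**. Plain-ML λ tests are markedly anticonservative at
  phylogenetic sample sizes (with 8 species the ML LRT against λ = 1
  rejected ~12% of Brownian simulations at α = 0.05; REML ~4–5%, and
  the suite requires ≤ 7%). LRTs against the boundaries use the 50:50
  chi-square mixture. Policy: if λ̂ does not differ significantly from
  1, the model is refit at λ = 1 (a conservative reading of
  phylogenetic signal). Responses are per-sex species means of the
  retained PCs plus a dimorphism score defined as the male-minus-female
  species-mean **difference** (a quotient of near-zero PC scores is
  unstable; the ratio variant is available by flag); predictors are
  reproductive strategy and standard length. Polytomies enter the
  covariance as true multifurcations. Fixed-λ fits agree with
  `nlme::gls` + `ape::corPagel` to 1e-6 on a fixture.

## Synthetic study conditions

The generator does not imitate real pelvic bones metrically; it
reproduces the qualitative contrasts the analyses must recover, with
full ground truth (applied poses, per-specimen effect specs, species
trait values). The base shape is a star-shaped (hence simple) closed
curve with an elongated anterior arm, posterior plate, unequal
external/internal wings (fixed chirality) and a narrow lateral process;
meshes wrap the same radius function onto a uv-sphere parametrization
with tapered thickness and an asymmetric dorsal dome, giving watertight
meshes within 10% of any target face count. Fin rays are never
generated (non-rigid structures have no place in rigid-shape
comparison).

Default cohort: 8 species (3 pelvic-brooding) × 2 sexes × 5 specimens,
with one species reduced to 3 females + 4 males — 77 specimens. Group
effects (package choices, documented here because no quantitative
effect sizes exist to copy): pelvic-brooding females carry medial tips
(amplitude 0.30 of the base radius, three bumps of angular width 0.12
rad — wide enough to be resolved by desk-scale meshes) and an internal
wing scaled ×1.3; conspecific males faint tips (0.05) and wing ×1.1;
everyone shares lateral-process angular variability (SD 8°), smooth
radial coefficient noise (SD 0.02), mesh vertex jitter (SD 0.004 of the
bounding-box diagonal) and a random similarity pose. Species-level
Brownian offsets (rate 0.0025 per unit depth on a depth-0.5 tree, Pagel
λ transform, default λ = 1) are added to the tip amplitude and clipped
at zero. At these settings the planted strategy × sex interaction is
recovered at α = 0.01 in ≥ 90% of replicate cohorts with n = 5 per
group — clear but not trivial.

What the generator does *not* emulate: segmentation artifacts, fin-ray
removal scars, bilateral pairs, allometry beyond a size covariate, and
production-scale mesh resolution. The last point matters for reading
the 3D results: at 1500-face meshes and ~10³ sample points,
homologization noise spreads ordination variance thinly (PC1–6 carry
~15–20% on the synthetic cohort, and the broken stick may retain
nothing), yet the group structure remains clearly detectable by
PERMANOVA on the leading axes. Passing tests show the machinery is
correct at desk scale; they do not certify effect-size estimates on
real μ-CT material.

## Problem sizes used by the acceptance script

`scripts/acceptance.py` regenerates the 77-specimen cohort at 1500
faces per mesh, uses 26 harmonics, 750 surface points per specimen for
the cohort-wide 3D stage, 9999 PERMANOVA permutations, 5000 disparity
bootstrap replicates, and screens 2 prototypes × 2 face counts × 3
repeats on a 17-specimen subset. These sizes are the package's
synthetic-work defaults; every number in the output JSON is computed at
run time from the seed given on the command line.

## Known limitations

* The longest-radius frame is undefined for radius-tied shapes
  (circles); the deterministic tie-break keeps runs reproducible but
  such shapes have no meaningful orientation.
* ICP is a local optimizer; the four-branch initialization handles the
  plate-like geometry here, but shapes without stable principal axes
  would need a global registration front-end.
* The misalignment rule is a heuristic stand-in for visual inspection;
  its two components (PSM outlier, branch instability) are tuned for
  plate-like bones with strong axis skew.
* PERMANOVA assumes exchangeable specimens under the null; species
  structure is handled only through the fixed terms, not through
  restricted permutation blocks.
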