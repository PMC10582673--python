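# osteomorph

Landmark-free geometric morphometrics for small, complex skeletal
elements — built around the pelvic girdle bone (basipterygium) of
ricefishes, where females of pelvic-brooding species grow medial bony
tips and enlarged wings that classical landmarks cannot capture.

The package implements two complementary shape pipelines plus the
statistics to compare them across species, sexes and reproductive
strategies:

* **2D outline analysis.** A silhouette is binarized, its boundary
  traced into a Freeman 8-direction chain code, and the closed outline
  expanded in elliptic Fourier descriptors (EFD): truncated Fourier
  series of the arc-length parametrized coordinates,

  ```
  x(t) = A0 + Σₙ aₙ cos(2πnt/T) + bₙ sin(2πnt/T)
  y(t) = C0 + Σₙ cₙ cos(2πnt/T) + dₙ sin(2πnt/T),   n = 1..26
  ```

  normalized by the longest-radius convention (translation to the
  centroid, rotation of the centroid-to-farthest-point radius onto +x,
  that radius scaled to 1, parameter start moved there) and ordinated
  by covariance PCA.

* **3D landmark-free surface analysis.** Each bone mesh is resampled
  to an even point cloud and superimposed onto a prototype with a
  modified iterative-closest-point algorithm; fit is measured by the
  Procrustes surface metric

  ```
  PSM(A,B) = sqrt( Σₐ d(a,B)²/(2m_A) + Σ_b d(b,A)²/(2m_B) ),
  ```

  the prototype is iteratively replaced by the mean of homologized
  (closest) points, and the homologized coordinates are ordinated by
  PCA. Per-point RMS deviation fields export as heat maps.

* **Prototype / mesh-resolution selection.** Candidate (prototype,
  face count) combinations are screened first by alignment consistency
  over repeated samplings, then by bootstrapped disparity of z-scored
  scores — choosing the combination with the smallest convex-hull
  surface and the largest score ranges.

* **Statistics.** Broken-stick PC retention, sequential PERMANOVA
  (pseudo-F, 9999 free permutations), range/convex-hull disparity with
  a 5000-replicate bootstrap and Bonferroni t-tests, and phylogenetic
  GLS with Pagel's λ (profiled by REML, conservatively reset to 1 when
  not significantly lower).

A synthetic shape generator produces outlines and watertight meshes of
a stylized plate-with-arm bone with planted, ground-truth-recorded
group effects (medial tips, wing enlargement, variable lateral
process), individual noise, random poses and Brownian species effects
on a phylogeny — so every stage of the pipeline can be validated
against a known truth.

## Worked example

```python
import numpy as np
import osteomorph as om
from osteomorph.config import RunConfig
from osteomorph.pipeline import outline_stage, read_tree_from_string
from osteomorph.stats import permanova

tree = read_tree_from_string(om.default_tree_newick())
design = om.default_design(seed=0)            # 77 specimens, 8 species
cohort = om.make_cohort(design, tree=tree, seed=0, with_meshes=False)

cfg = RunConfig(rng_seed=0)
space, _ = outline_stage(cohort.outlines, cfg)
print(f"PC1-6 variance: {100 * space.proportions[:6].sum():.1f}%")
print(f"retained axes (broken stick): {len(space.retained)}")

tab = permanova(space.scores[:, space.retained], design.frame,
                terms=["strategy", "sex", "strategy:sex",
                       "standard_length", "species"],
                n_perm=9999, seed=0)
for t in tab.terms:
    print(f"{t:16s} df={tab.df[t]} R2={tab.r2[t]:.3f} "
          f"F={tab.f[t]:.2f} p={tab.p[t]:.4f}")
```

prints (seed 0):

```
PC1-6 variance: 89.0%
retained axes (broken stick): 5
strategy         df=1 R2=0.313 F=54.52 p=0.0001
sex              df=1 R2=0.103 F=17.94 p=0.0001
strategy:sex     df=1 R2=0.170 F=29.64 p=0.0001
standard_length  df=1 R2=0.004 F=0.74 p=0.5098
species          df=6 R2=0.031 F=0.90 p=0.5653
```

The planted contrast — medial tips and enlarged internal wings in
pelvic-brooding females only — surfaces exactly where it should: a
strong reproductive-strategy effect, a highly significant
strategy-by-sex interaction (the brooding *females* differ, p at the
permutation floor 1/10000), and no residual species effect beyond it.

The same cohort's meshes feed the 3D pipeline (`surface_stage`,
`generalized_alignment`) whose ordination and deviation heat maps
localize the planted tips on the bone surface.

## Command line

```bash
osteomorph simulate --seed 1 --out sim/            # cohort to disk
osteomorph outline  --seed 1 --out efd/ --outlines sim/outlines
osteomorph surface  --seed 1 --out gpsa/ --meshes sim/meshes
osteomorph select-prototype --seed 1 --out sel/ --meshes sim/meshes \
    --prototype sp06_f1 --prototype sp01_m1 --faces 1000 --faces 2000
osteomorph stats --seed 1 --out stats/ --scores efd/efd_scores.csv \
    --design sim/design.csv
osteomorph pgls  --seed 1 --out pgls/ --scores efd/efd_scores.csv \
    --design sim/design.csv --tree sim/tree.nwk
osteomorph run-all --seed 1 --out run/
```

Every stage writes CSV tables with a JSON provenance sidecar (config
hash, seed, package version); reruns with the same seed are
byte-identical.

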