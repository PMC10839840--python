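# Methods

This note documents the models, numerical choices, defaults, and known
limitations of `mdsurf`. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Element abstraction

All analyses operate on "elements" — vertices of a triangulated cortical
surface or, equivalently, voxels of a labeled grid. Every statistical
operation (conjunction, overlap, preference, profiles, fingerprints) is
agnostic to which, so the subcortical variant of the pipeline is the same
code path with a grid element space and an extra 4 mm FWHM smoothing pass
applied first.

## Surface geometry

**Meshes.** A `SurfaceMesh` is a triangulated 2-manifold, possibly with
two disconnected hemisphere components, coordinates in mm, 0-based vertex
indices, and an optional symmetric homolog map pairing mirror vertices
across hemispheres. Invariants (valid indices, ≤2 triangles per edge,
strictly positive edge lengths, cross-component symmetric homologs) are
enforced at construction.

**Geodesics.** Distances are shortest paths on the weighted mesh edge
graph augmented with *unfolding shortcuts*: for every interior edge the
two adjacent triangles are unfolded into a plane and the two opposite
vertices are joined with the unfolded straight-line length whenever that
segment crosses the shared edge — exactly the case where the shortcut
shortens paths. This removes most of the lattice overestimation of a
plain edge graph while remaining a pure graph problem, so correctness is
testable to 1e-9 against a brute-force shortest-path oracle on the same
graph (an independent Dijkstra with the priority queue replaced by linear
scans). Exact polyhedral (window-propagation) geodesics are deliberately
out of scope; the contract is the graph geodesic. Vertices in a component
with no source are flagged `inf`, never silently NaN.

**Borders and segments.** A border vertex has at least one
differently-labeled mesh neighbor; the pair index maps each unordered
adjacent area pair (canonicalized by sorted identifier) to its shared
border vertices, and a junction vertex belongs to every pair it touches.
Distance segmentation sorts each area's vertices by geodesic distance to
the pair's border subset (stable tie-break by vertex index) and splits
them into equal-count segments, sizes differing by at most one with extra
vertices assigned to the *nearer* segments; border vertices are included;
segment 1 abuts the border. The segment count is a parameter: the
border-profile analyses default to 10 segments per area; 5 is the other
documented convention.

**Smoothing.** Surface smoothing is iterative diffusion with cotangent
edge weights (clipped at zero, with a tiny positive floor so no vertex
star freezes) and barycentric vertex areas. One step transfers mass
τ·w_ij across each edge, so the area-weighted total Σ aᵢvᵢ is conserved
exactly and the step is monotone (all coefficients nonnegative) under the
stability cap τ·Σⱼw_ij/aᵢ ≤ ½. Interpreting the step as a lazy random
walk, the per-axis variance it adds is τ·Σⱼ w_ij ℓ_ij²/(2aᵢ); the step
count is the smallest n for which the cap allows total variance
σ² = (FWHM/2√(2 ln 2))², and τ is then shrunk to hit σ² exactly. Cotangent
weights make the kernel isotropic (on a right-triangulated grid the
diagonals get weight zero); on a fine planar grid the impulse response
matches the analytic Gaussian of the target FWHM with normalized RMS
error well under 0.05. Masked smoothing removes all edges leaving the
mask, so nothing leaks across the mask boundary and the masked total is
conserved. FWHM 0 is the identity.

## Statistics

- **t-tests.** One-sample t against zero, two-sided p; paired t is the
  one-sample test on differences. Zero-variance samples are flagged
  degenerate: statistic 0 / p 1 for an exactly-zero sample, p 0 with
  signed infinite statistic for a nonzero constant sample. "Significantly
  activated" everywhere means *reject and positive direction* — a
  deliberately explicit, conservative reading of one-sided claims.
- **Multiplicity.** `adjust` implements Bonferroni (threshold
  α/(n·extra)) and Benjamini–Hochberg step-up at level α/extra, where
  `extra` is a secondary Bonferroni factor (3 task comparisons, 3
  subcortical structures, 5 networks × 3 tasks, …) applied as an alpha
  division. BH rather than Benjamini–Yekutieli is used where only "FDR"
  is specified. NaN p-values never reject.
- **Repeated-measures ANOVA.** Fully-crossed within-subject designs of
  any number of factors. Sums of squares come from the inclusion–
  exclusion identity over marginal-mean squared totals with subject as a
  crossed random factor; each within effect is tested against its own
  subject × effect interaction mean square. For a single 2-level factor
  F = (paired t)² exactly. No sphericity (Greenhouse–Geisser) correction
  is applied — degrees of freedom are uncorrected, a documented
  limitation. A zero error mean square is flagged degenerate (F = 0 when
  the effect SS is also zero, else ∞).
- **Correlation.** Plain product-moment correlation over an optional
  retained-element mask (≥3 elements required); zero variance returns
  NaN, flagged undefined. Fingerprint p-values use the t transform with
  df = retained − 2.

## Activation analyses

**Percent signal change.** Scanner betas are converted as
100·(beta/10000), i.e. beta/100, the divisor being the grand mean to
which each element's time series is scaled during preprocessing.

**Areal conjunction.** Area × task one-sample t-tests on areal means
(unweighted vertex averages), Bonferroni over areas; an area survives iff
it rejects positively in every task. An optional either-hemisphere mode
unions each area with its homolog per task before requiring all tasks
(off by default).

**Per-subject vertex conjunction.** Per-subject inference needs a
within-subject error term; cohorts therefore carry per-subject,
per-element standard errors (the synthetic generator derives them from
its known noise model as noise_sd/√pseudo-runs, 4 pseudo-runs by
default). The per-subject test is value/SE against a large-sample normal
reference — run-level GLM errors have hundreds of time points behind
them, so the normal reference is appropriate — followed by element-wise
BH-FDR per subject and task, a positive-direction conjunction across
tasks, and summation across subjects into the overlap map.

**Task preference.** For each candidate task, its pairwise paired-t
p-values are pooled across the restricted elements and BH-corrected at
α/(number of tasks); a task wins an element only if every pairwise
comparison rejects with positive direction, which makes double labels
impossible (directional exclusivity). Whether the FDR family pools tasks
or not is genuinely ambiguous as a convention; pooling per candidate task
is the implemented default and the restriction set (all cortex vs core
areas only) is a parameter.

**RGB composites.** The three group maps are jointly min-max normalized
(one min and one max across all three), scaled by 255 with half-away-from-
zero rounding (the rounding rule is our choice; only the scaling is
prescribed), channel order n-back → red, switch → green, stop → blue.
The composite is invariant to jointly affine rescaling of the maps.

**Network comparisons.** Per subject, a network's value is the mean over
its member vertices (equivalently the vertex-count-weighted mean of its
areas' means), split by hemisphere where component labels exist. Task
contrasts are pairwise paired t-tests Bonferroni-corrected over
pairs × networks; lateralization is paired_t(left, right) per task.

## Border analyses and the smoothing null

**Profiles.** The profile axis spans area A far→border then B
border→far (2·n segments); per subject each segment's value is the mean
over its vertices, and the subjects × (segment × task) grid feeds the
repeated-measures ANOVA whose segment × task interaction is the test of
border-locked task peaks.

**Top-fraction overlap.** Per subject and task the ⌈fraction·n⌉
highest-valued elements are flagged — ties broken by element index —
and summed; survivors are elements whose count strictly exceeds the
subject-fraction threshold (defaults: top 5%, >50% of subjects). The
selection is invariant to per-map monotone transforms and is applied per
task per subject before binarization.

**Homogeneous null.** Every vertex of an area receives that subject's
areal mean, the area borders having first been jittered per subject —
seeded rounds in which each border vertex adopts a random
differently-labeled neighbor's label with probability ½, with round count
≈ jitter/mean-edge-length (default one edge length) — then the maps are
smoothed at each FWHM level (default 4, 12, 20 mm). The jitter emulates
inter-subject border misalignment, the mechanism by which smoothness
could fake border peaks. At FWHM → 0 with zero jitter the null is exactly
piecewise constant and areal averaging recovers the input means exactly.

**Border proximity.** The fraction of surviving vertices within a
geodesic radius of any border vertex (optionally only borders between
two named networks). The radius defaults to twice the mean edge length —
a numeric criterion of our choosing for what is otherwise a visual
comparison. The headline property is that bump-planted cohorts beat the
homogeneous nulls on this quantity at every FWHM over seeded replicates
(sign test).

## Connectivity fingerprints

The exclusion mask removes the seed's own area, every area sharing at
least one border vertex with it (junction contact counts as adjacent),
and the contralateral homologs of all removed vertices; a retained set
below 10 elements is an error (a two-area hemisphere excludes
everything). Per subject, each core seed's connectivity row is correlated
with the subject's three contrast maps over the retained set; p-values
are BH-corrected over the full seeds × tasks family per subject; a seed
is labeled with the arg-max-r task among those passing both the FDR
rejection and r > 0.2. Winner-take-all then assigns each seed the task
with the strictly greatest subject count — ties and all-none seeds stay
unlabeled. The r-threshold, α, and FDR family are parameters; per-subject
correlation against a single group connectivity matrix is the default
convention.

## Synthetic cohort generator

The generator defines the study conditions; its defaults are fixed:

| parameter | default | meaning |
|---|---|---|
| tasks | n-back, switch, stop | executive contrasts, yoked to DMN / DAN / CON |
| mesh | icosphere subdiv 2 (162 vertices/hemisphere), radius 32 mm, mirrored pair | border analyses use subdiv 3 |
| areas | 8 per hemisphere, geodesic Voronoi from farthest-point seeds, mirrored labels | the most-neighbored area is core MD; neighbors cycle CON/DAN/DMN as penumbra |
| area means | base 0.0; core 0.8 PSC in all tasks; preferred task +0.6 | executive contrasts are near zero over uninvolved cortex |
| gradients | +0.3 PSC linear ramp over 4 mean edge lengths toward each yoked border | within core areas |
| bumps | 0.6 PSC Gaussian ridge, width 1 mean edge length, on yoked borders | the border-peak signal |
| noise | sd 0.3 PSC i.i.d., smoothed to 2 mean edge lengths FWHM | no variance rescale after smoothing, so effective sd is below 0.3 |
| subject offset | sd 0.2, shared across tasks and vertices | global responder effect; cancels in paired tests |
| SEs | 0.3/√4 with a normal reference | 4 pseudo-runs |
| preference margin | 0.15 PSC | minimum lead in the noiseless field for a vertex to carry a true label |

The planted preference truth is computed from the actual noiseless field
(means + gradients + bumps), so recovery tests measure inference under
noise, not agreement with a shortcut. Seed assignments give each core
vertex the task of its geodesically nearest yoked border, mirroring the
gradient claim the fingerprint analysis is designed to detect. The
connectivity matrix is Σ_t λ_tλ_tᵀ with z-scored task maps as loadings,
core seeds loading only on their assigned task, plus symmetric Gaussian
noise scaled relative to the rms off-diagonal signal; it is symmetrized
with unit diagonal. Every generator is a pure function of (parameters,
seed); labels and counts reproduce bitwise.

What the generator does *not* emulate: realistic folding geometry,
hemodynamics or time series, distance-dependent connectivity, inter-area
baseline heterogeneity, or spatially structured (non-Gaussian) artifacts.
Passing recovery tests therefore demonstrates correctness of the
inference machinery under the stated noise model, not performance on real
acquisitions.

## Problem sizes and calibration checks

The simulation-based checks use these sizes, chosen as the smallest
problems at which the quantities of interest are stable: BH-FDR control
with m = 1000 tests, 10% true effects of standardized size 1.0, n = 20
subjects, 500 replicates; ANOVA type-I calibration on a 3 × 4 × 2 design
with 12 subjects and 2000 replicates; preference and fingerprint recovery
on the default two-hemisphere subdiv-2 cohort with 20 (resp. 10)
subjects; the border-versus-null contrast on subdiv-3 meshes over 20
seeded replicates in the test suite (12 in the acceptance script) with a
sign test per FWHM level.

## Pipeline

One global seed is split per stage by hashing (seed, stage name), so any
stage subset reproduces exactly; the provenance record next to each
output carries the seed, the stage seed, and a hash of the
computation-relevant configuration (excluding the output directory and
the stage toggles, so toggling a stage leaves other outputs
byte-identical). Structured logs report every threshold actually applied:
the effective per-test alpha, the top-k count, and retained-mask sizes.

## Known limitations

- Graph geodesics overestimate true polyhedral distances slightly even
  with unfolding shortcuts (worst on long thin triangles).
- The diffusion smoother's FWHM calibration assumes a near-uniform mesh;
  strongly graded meshes would need per-region step sizes.
- No sphericity correction in the ANOVA; with many segment levels the
  interaction test can be liberal under non-spherical covariance.
- The subcortical pathway is exercised through the element abstraction
  (grids flow through every operation), not through a dedicated NIfTI
  voxel pipeline.
- Tukey-style post-hoc comparisons are approximated by pairwise paired
  t-tests with Bonferroni correction.
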