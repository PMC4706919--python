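# Methods

This note documents the models, numerical choices and limitations of
`longconn`. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Connectome construction

Node time series are the mean BOLD signal over all gray-matter voxels
whose *center* lies within `radius_mm` (default 5 mm, Euclidean distance
in world mm) of a landmark. Distances are computed in world
coordinates, not voxel indices, because the emulated acquisition grid is
anisotropic (3.125 × 3.125 × 3.5 mm): an index-space sphere would be an
ellipsoid in the scanner frame. Landmarks are world-mm RAS; voxel
indices are 0-based. An empty neighborhood (landmark outside the mask
support) is an error naming every offending node — no silent NaNs.

FC is the Pearson correlation matrix of the node series, symmetrized,
clipped to [−1, 1], unit diagonal. Vectorization walks the lower
triangle row-major over *i* ≥ *j*; with the diagonal this yields
n(n+1)/2 features — 64261 at n = 358, the "unique features" count of
the full landmark set. The diagonal is *included* in that count but
always *excluded* from statistics (self-correlation is the constant 1).
Edge statistics default to Fisher-z transformed values (`atanh`),
the standard variance-stabilizing scale for correlations; raw-`r`
analysis is available via `scale="r"` since the choice is not forced by
the design.

## Mixed 2×2 edge statistics

The design crosses group (control/patient, between-subject, sizes may
differ) with session (acute/subacute, within-subject). For a two-level
within factor the classical sums-of-squares mixed ANOVA collapses to
per-subject session means `m` and differences `d`:

* `F_group = t²` — pooled unpaired t on `m`, tested against
  subjects-within-group; df (1, N−2);
* `F_interaction = t²` — pooled unpaired t on `d`; df (1, N−2);
* `F_time = t²` — overall mean of `d` over √(MSE_d/N), with MSE_d the
  pooled within-group variance of `d` (the time × subjects-within-group
  error); df (1, N−2).

This is the *weighted* (classical, sequential) decomposition: it holds
the F = t² identities to machine precision at unequal group sizes and
agrees exactly with `pingouin.mixed_anova`, which the test suite uses as
an independent oracle. Simple effects are the pooled unpaired t between
groups at a fixed session (Welch optional) and the paired t across
sessions within a group.

Degenerate edges — zero variance in the relevant error term — return
statistic 0 with a `degenerate` flag rather than NaN, and are excluded
from thresholding. The zero-variance check uses a relative floor
(`1e-24·(1 + mean square)`) so that numerically identical values whose
mean differs by an ulp still count as degenerate.

## Network-based statistic

Thresholding is on the signed |t| scale — for the 1-df ANOVA effects the
threshold 3.5 is compared against √F with the effect's sign. The
t-versus-F scale of the conventional 3.5 cutoff is ambiguous in the
literature this mirrors; |t| was chosen because 3.5 is far outside any
plausible F convention and matches how the companion figure annotates
"T-values". Strict inequality at the threshold; ties are excluded.

Components are node-connected subgraphs of the suprathreshold edge set
(two edges connect iff they share a node), extracted by union-find;
extent is the edge count. The permutation p-value is
`(1 + #{maxima ≥ K})/(M + 1)`, which cannot be zero and is exact under
exchangeability — a deliberate divergence from implementations that
report `count/M`. By default components mix both effect signs
(`direction="both"`), each edge annotated with its sign; one-sided modes
exist. Exchangeability schemes: subjects are the blocks for group and
interaction (group labels permuted, both sessions moving together);
session sign-flips within subjects for time. The permuted statistics are
recomputed for all edges per permutation via chunked matrix products
(sums and sums of squares of `m` or `d` against permutation indicator
matrices), which keeps 5000 permutations × 63903 edges under a minute
per effect on one CPU.

Thresholds trade granularity: 3.5 maximizes component-level detection at
moderate effects, but NBS's FWER guarantee is at the component level
only — random suprathreshold edges (per-edge two-sided p ≈ 0.0012 at
df 38) freely chain onto a true component. Analyses that need edge-level
precision against a known truth (the planted-recovery test uses Jaccard
overlap) should raise the threshold; at per-edge t ≈ 13, threshold 5
keeps full recall while suppressing null attachments.

## Synthetic cohorts

`generate_cohort` emulates the post-preprocessed data of a 24-control /
16-patient, two-session landmark study: 358 nodes × 240 time points at
TR = 2 s by default. Signals follow a latent-factor model

```
x_i(t) = a·g(t) + b·f_block(i)(t) + c·e_i(t)
```

with `a² = between_block_corr`, `a² + b² = within_block_corr`,
`a² + b² + c² = 1`: population correlations are exactly the configured
within/between values, the covariance is positive semidefinite by
construction, and sampling is O(nodes × time). Noise is white by
default — the emulated pipeline prewhitens — with an AR(1) option
(unit marginal variance) for serial-correlation sensitivity checks.

Planted effects are exact increments on the Fisher-z scale, implemented
in the idiosyncratic-residual space: each planted edge's residual pair
receives correlation `ρ = (tanh(atanh(r₀)+δ) − r₀)/c²`, and the residual
correlation matrix over the effect-component nodes is completed to PSD —
zero fill-in when the prescribed pattern is already PSD, the Gaussian
tree (Markov path-product) completion for tree-shaped edge sets, Dykstra
alternating projections otherwise. Consequences worth knowing:

* the patient-minus-control population z difference on planted edges is
  *exactly* δ; edges outside the effect component are *exactly*
  unperturbed;
* any completion fill-in perturbs only pairs *within* the effect
  component (path-product correlations between non-adjacent effect
  nodes); it is zero whenever ρ stays below the chain-feasibility bound
  (≈ 0.5 for long paths);
* feasibility requires ρ < 1, i.e. the increment must fit inside the
  residual variance headroom `c² = 1 − within_block_corr`. A
  between-block edge at the default 0.6/0.1 structure supports δ up to
  ≈ 0.21 with zero fill-in and ≈ 0.9 with tree fill-in; larger
  increments (the δ = 0.8 power simulations) use a lower-coherence
  background (within 0.3, between 0.05) where the headroom accommodates
  them. This bound is not an implementation artifact: a correlation
  matrix cannot raise one cross-community entry arbitrarily while
  pinning every other entry;
* randomly generated planted sets are *paths* (degree ≤ 2 over
  n_edges + 1 distinct nodes) — still a single connected component, and
  the shape that maximizes the feasible increment. Explicit edge lists
  of any connected shape are accepted and validated;
* `effect_delta_z ≥ 0`: the construction plants hyperconnectivity, the
  direction of interest for this design.

Effect types map to affected conditions: `group` → patients, both
sessions; `time` → all subjects, subacute; `interaction` → patients,
subacute only.

What the generator does **not** emulate: hemodynamics, motion and
physiological noise, and — importantly — *between-subject heterogeneity*
of connectivity. All subjects of a condition share one population
matrix, so between-subject variance is pure sampling noise of the
correlation estimate (z-scale sd ≈ 1/√(T−3) ≈ 0.065 per session). Group
contrasts are therefore far "cleaner" than real cohorts at the same δ:
a δ of 0.2 already yields per-edge t ≈ 13 at 24 vs 16. Passing
power/recovery tests demonstrate the *procedure's* correctness and
calibration, not expected sensitivity on real data, where subject-level
variance would push detectable deltas much higher.

The volume fixture places landmarks on a lattice with ≥ 12 mm
separation (disjoint 5 mm neighborhoods), stamps each node's series into
every gray-matter voxel of its neighborhood and fills the rest of the
grid with independent noise: extraction must return the injected series
up to the floating-point cost of averaging identical copies.

The node-to-category table uses a fixed **synthetic** 53-subcategory
taxonomy nested under the five major functional domains (8 Action,
12 Perception, 14 Cognition, 9 Interoception, 10 Emotion), patterned on
meta-analytic behavioral-domain hierarchies; real landmark labels can be
supplied as a TSV with the same nesting.

## Annotation

Each signature edge increments exactly one cell — the canonically
ordered category pair of its endpoints — so the grand total of the pair
matrix equals the edge count and aggregating the 53×53 matrix by parent
reproduces the 5×5 matrix cell-for-cell (`symmetric()` mirrors for
display). Percentages are shares of the signature total; with zero
signatures they are reported as 0 with `percent_defined = False`.
Counts are the primary output; the percentage normalization is a package
definition, since "percent change" color scales in this literature are
rarely defined precisely. Ranking is by count descending, ties broken
lexicographically.

## Multiview clustering

The cited clustering approach is under-specified in the source
literature; the package's concrete instantiation of "projecting each
view on the others" is co-training multiview spectral clustering:

1. per view, affinity = positive part of FC (|r| by flag), zero
   diagonal, symmetric degree normalization `D^{-1/2} W D^{-1/2}`;
2. top-k eigenvectors per view (LAPACK `eigh` on the index subset;
   deterministic, sign-fixed so each vector's largest-magnitude entry is
   positive);
3. each view's normalized affinity is projected onto the *average*
   spectral projector of the other views, `M_v ← sym(P̄₋ᵥ M_v)`, and
   embeddings recomputed — up to `n_iter` (default
   10) rounds, stopping early when the consensus assignment stabilizes
   (typically 2–3 rounds);
4. consensus: row-normalized embeddings concatenated column-wise,
   k-means with 20 restarts under one seed, best inertia kept; labels
   relabeled 1..k by first appearance.

Identical views are a fixed point of the projection, so duplicating one
view reproduces plain spectral clustering of that view — a property the
tests verify. k defaults to 8 (the cluster count this analysis style
reports) but is free; the mean eigengap at k is reported as a
diagnostic, never applied automatically. Affinities with more connected
components than k, or isolated zero-degree nodes, raise an error
suggesting an affinity floor. The per-view agreement diagnostic is the
ARI between the consensus and each view's single-view partition.

## Pipeline

One YAML config; a global seed derives per-stage seeds through
`SeedSequence([seed, stage_index])` (all below 2³¹), so stages are
individually reproducible without seed collisions. Effect selection
follows the longitudinal convention: interaction first; if null, group
and time main effects; if significant, simple-effect t maps are written
instead. Every stage persists self-describing artifacts (TSV with
headers, JSON sidecars); the FC stack is stored as one compressed array
plus a JSON manifest rather than 80 per-subject TSV matrices — at 358
nodes the TSV round-trip would dominate runtime; per-matrix TSV I/O
remains available in the library. The report contains no timestamps
(elapsed times go to the log), and the config hash excludes the output
directory, so identical analyses are byte-identical wherever they are
written.

Problem sizes used by the shipped test suite — chosen as desk-scale
stand-ins for the study dimensions: FWER calibration on 200 null cohorts
of 60 nodes (12 vs 8 subjects, 500 permutations); power on 100
replicates of 100 nodes (24 vs 16, δ = 0.8, 500 permutations); cluster
recovery on 120 nodes × 40 views × 20 seeds; determinism at the full
358 nodes / 24+16 subjects / 5000 permutations (one full run ≈ 2.5 min
on one CPU).

## Known limitations

* No covariate adjustment, partial-correlation or regularized FC
  estimators, FDR edge-wise alternative, or intensity-based component
  measure — all outside the analysis this package replicates.
* Landmark *prediction* (tractography-based localization) and fMRI
  preprocessing are out of scope; landmark coordinates and preprocessed
  series/volumes are inputs.
* The planted-effect feasibility bound above means very large z
  increments cannot be combined with very coherent backgrounds; the
  generator fails loudly rather than silently distorting targets.
* Cluster anatomical naming (atlas lookup) is not provided; clusters are
  numbers.
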