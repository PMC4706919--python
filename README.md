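# longconn

Longitudinal functional-connectome statistics over cortical landmark
nodes: edge-wise mixed 2×2 (group × time) ANOVA, network-based-statistic
(NBS) permutation inference with family-wise error control, functional-
domain annotation of significant edges, and multiview group-wise
clustering of per-subject connectivity views.

## The problem

Longitudinal resting-state fMRI studies of mild traumatic brain injury
(and similar two-group, two-session designs) ask whether *connectome-
scale* functional connectivity differs between patients and controls,
and whether that difference changes from the acute to the subacute
stage. The analysis objects are per-subject-session **functional
connectivity (FC) matrices**: Pearson correlations between the BOLD
time series assigned to each of *n* cortical landmark nodes — for the
358-node landmark set, a symmetric matrix with 358·359/2 = **64261**
unique features. Node series are the mean over gray-matter voxels
within a 5 mm (world-mm) neighborhood of each landmark.

Testing 64k edges individually has no power after multiplicity
correction. The NBS instead tests *connected structures*: edges whose
statistic exceeds a threshold (3.5 on the |t| scale) are grouped into
connected components, and each observed component of extent *K* (edge
count) is assigned

```
fwer_p = (1 + #{permutation maxima ≥ K}) / (M + 1)
```

where the null distribution of the **maximal** component extent comes
from M permutations of the design (group labels permuted across
subjects with sessions moving together; session labels sign-flipped
within subjects for the time effect). This controls the family-wise
error rate at the component level.

Edge statistics come from the classical mixed 2×2 ANOVA. With two
sessions the decomposition reduces exactly to three t statistics from
per-subject session means *m* and differences *d*:
`F_group = t²(m)`, `F_interaction = t²(d)` (pooled unpaired t between
groups, unequal group sizes supported), and `F_time = t²` of the overall
mean of *d* against the pooled within-group variance of *d* — all on
(1, N−2) df, computed on Fisher-z transformed correlations by default.

Significant edges ("connectomic signatures") are then summarized two
ways: by the functional domains of their endpoints (5 major categories —
Action, Perception, Cognition, Interoception, Emotion — and 53 nested
subcategories), and by consensus functional clusters derived from all
subjects' FC matrices via co-training multiview spectral clustering
(k = 8 by default), splitting signatures into within- vs between-cluster
interactions.

Because no patient dataset is distributable, the package ships a
first-class synthetic cohort generator with known ground truth
(block-community structure, planted connected hyperconnectivity effects
that are *exact* Fisher-z increments, white or AR(1) noise), so every
stage is testable end to end.

## Worked example

`examples/06_full_pipeline.py` simulates a 24-vs-16 cohort (100 nodes,
240 time points, a 20-edge planted group effect of +0.2 Fisher-z) and
runs the full pipeline:

```
longconn pipeline report
========================

seed: 11
config hash: c4cb96ee3351
cohort: 24 controls vs 16 patients, 100 nodes, 240 time points
edges tested: 4950
NBS [interaction]: 0 component(s), 0 significant, 0 signature edge(s)
NBS [group]: 1 component(s), 1 significant, 20 signature edge(s)
NBS [time]: 0 component(s), 0 significant, 0 signature edge(s)
signatures annotated: 20 (top major pair: Action-Interoception)
clusters: k=8, between-cluster signature share 75.0% (15/20)
```

Reading it: the group-by-time interaction and the time effect are null
(as planted), while the group effect surfaces as **one** significant
connected component whose 20 edges are exactly the planted
hyperconnectivity path; its endpoints' functional categories rank
Action–Interoception first in this synthetic labeling, and 75% of the
signatures connect *different* functional clusters. Rerunning with the
same config and seed reproduces the report byte for byte.

The other examples each demonstrate one capability: cohort simulation
(01), volume → time-series extraction and the 64261-feature contract
(02), edge statistics + NBS (03), domain annotation (04), multiview
clustering (05).

A thin CLI mirrors the stages:

```bash
longconn run --config pipeline.yaml
longconn simulate --out sim/ --seed 3
longconn nbs --stack stack/ --effect group --threshold 3.5 \
             --permutations 5000 --seed 1 --out nbs/
```

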