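# Methods

`netstrat` implements a multi-layer network analysis for small immunotherapy
cohorts profiled on two data types: a tumour gene-expression panel (GEP,
counts for ~438 genes) and circulating immune profiling (CIP, percentages of
31 blood immune subsets at baseline and after two treatment cycles), with a
binary clinical response label and overall survival. This note records the
models, the defaults and why, the synthetic-data design, and the numerical
choices.

## Correlation networks (CIP)

For each response group and timepoint, all pairwise Spearman correlations
are computed from midranks; p-values use the t-approximation
`t = rho * sqrt((n-2)/(1-rho^2))` on `n-2` df, which is standard at the
cohort sizes targeted here (n ≈ 20–44; an optional seeded permutation p is
available for n < 10). Benjamini–Hochberg control is applied once per
network over the V(V−1)/2 unordered pairs (one family per group/timepoint
network; a pooled family across networks is available by flag, since either
convention is defensible). An edge is kept iff |rho| > 0.55 and q < 0.05 and
carries the signed coefficient as weight. Constant variables stay in the
node set as isolated nodes so the 31-node universe is identical across
groups.

## Differential co-expression network (GEP)

Group-wise co-expression networks use the same machinery at |rho| > 0.7,
q < 0.05. Differential co-expression between responders (A) and
non-responders (B) is tested with the Fisher z-statistic

    Z = (atanh(rho_A) − atanh(rho_B)) / sqrt(1/(n_A−3) + 1/(n_B−3)),

keeping pairs with |Z| > 2 (no FDR on Z — the raw cut is the method's stated
operating point). The 1/(n−3) variance is the Pearson-based convention even
though the coefficients are Spearman, mirroring the widely used DiffCorr
implementation; the rank-based 1.06/(n−3) inflation is exposed as an
option. The candidate-pair universe defaults to the union of the two group
networks' edge sets — the group networks are built first and then
differenced — with an all-pairs mode available. Pairs with a perfect sample
correlation are excluded with a warning (atanh diverges).

Hubs are the right tail of the DCN degree distribution: the threshold is
the 95th percentile (linear interpolation) of the degrees of nodes with
degree ≥ 1, nodes strictly above it are hubs, and nodes tied at the
smallest included degree are kept so discrete ties are not split
arbitrarily. Communities come from Louvain modularity optimisation
(networkx, seeded, unweighted by default with |Z| weights by flag).

## Over-representation analysis

Hub neighbourhoods (hub + first neighbours of a chosen edge sign) and
communities are tested with the hypergeometric upper tail P(X ≥ k) against
a panel-restricted background (all panel genes), which avoids the
panel-composition bias a whole-genome universe would introduce. Terms with
fewer than 3 background genes or zero overlap are dropped before BH; one BH
family per query. Gene sets are user-supplied GMT files — nothing is
downloaded. Composition tests of patient clusters reuse the same tail; note
that the strict-inequality convention P(X > k) also circulates in the
literature and is exposed as an option, because the two conventions differ
visibly at these sample sizes.

## Similarity network fusion and clustering

Each layer's patient affinity is the scaled-exponential kernel
`W(i,j) = exp(−d²/(mu·eps_ij))` on Euclidean distances between per-variable
z-scores, with `eps_ij` the mean of the two patients' average distances to
their K nearest neighbours and `d(i,j)`. The GEP layer uses log2(count+1)
expression of the hub genes only; the CIP layer uses all 31 baseline
variables (post-therapy by flag). Fusion is the standard cross-diffusion:
full kernels P_v (row-stochastic, half mass on the diagonal) and K-NN
kernels S_v per layer, iterating `P_v ← S_v · mean(P_u, u≠v) · S_vᵀ` with
re-normalisation each step for t iterations, then averaging and
symmetrising. Hyperparameters follow the cited method's conventions —
K = 20 capped at N−1, mu = 0.5, t = 20 — because the operating point is not
otherwise pinned down; all are configurable and logged. The number of
clusters maximises the eigengap of the normalised Laplacian over [2, 5];
clustering embeds rows in the k smallest-eigenvalue eigenvectors,
row-normalises, and runs seeded k-means++ with 50 restarts (best inertia),
making the whole stage deterministic under a seed.

## Survival statistics

Kaplan–Meier, the two-group log-rank test and Cox proportional hazards are
delegated to lifelines. Cox uses Efron tie handling (times are recorded at
month resolution, so ties are common) with Wald 95% CIs; non-convergence
and separation are flagged, never silent. The KM median is the first time
with S(t) ≤ 0.5, undefined when the curve never reaches 0.5. Cluster
characterisation: hypergeometric composition per cluster,
majority-mapping accuracy for the 2-cluster design, per-variable
Mann–Whitney (exact enumeration when both groups ≤ 10 without ties, else
the tie-corrected normal approximation with continuity correction) with BH
across variables, and baseline balance via two-sided Fisher exact tests
(full enumeration up to 2×3; chi-square fallback flagged beyond) or
Wilcoxon rank-sum.

## Validation

LOOCV removes one common patient at a time and repeats the *entire*
process — differential network, hub selection, both affinity layers,
fusion, clustering — on the remainder, always requesting 2 clusters (the
concordance statistic is defined for the 2-cluster design). Accuracy and
the between-cluster log-rank p are evaluated on the retained N−1 patients;
the held-out patient is not assigned a cluster (a nearest-centroid
assignment exists but is off by default). Per-iteration seeds derive
deterministically from the base seed and the left-out id. The percentile
sweep rebuilds the pipeline from hub sets at the 75th/90th/95th/98th/99th
degree percentiles and reports hub counts, ARI against the 95th-percentile
reference partition, and accuracy.

## Synthetic cohorts

No public dataset carries this exact design, so the generator emulates its
statistical structure with planted ground truth:

- **Expression.** 23 hub genes each anchor a "star" of ~18 satellites over
  the 438-gene panel. Within responders, a star factor drives hub and
  satellites (hub–satellite Spearman = `rho_within_module`, default 0.8);
  in non-responders the hub decouples while satellites keep the factor, so
  hub–satellite pairs are the differentially co-expressed pairs and
  satellite–satellite correlations are equal across groups. Satellite
  residuals are equicorrelated at −1/(s−1) — the positive-semidefiniteness
  floor — keeping satellite pairs as far below the co-expression threshold
  as the hub correlation permits. A latent-cluster mean shift
  (`cluster_separation_gep`, default 1.2 latent SD) lives *inside* each
  star factor, so hubs and satellites inherit it coherently and the
  within-group correlation targets are unchanged; decoupled hubs keep the
  shift. Latent values map to counts through gene-specific log-normal
  scales (means ~80–600, log-SD 0.4–0.7), large enough that integer
  rounding barely attenuates rank correlations.
- **Immune profile.** Gaussian copula with a myeloid block (corr 0.7) in
  every group/timepoint, an NK block (corr 0.5), and an NK–myeloid bridge
  (corr 0.45) only in responders pre-therapy; NK subsets are elevated in
  the favourable latent cluster (`cluster_separation_cip`, default 1.0).
  A logistic transform maps latents onto the open (0, 100) percentage
  scale.
- **Survival.** Exponential, favourable-cluster median 32 months, hazard
  multiplied by `hazard_ratio` (4.5) in the unfavourable cluster. The
  latent cluster is the response label flipped independently with
  probability 0.2, so clusters and response agree imperfectly, as real
  cohorts do. Censoring: with probability 0.2 a patient is censored at a
  uniform fraction of their event time.
- **Clinical covariates** (age, sex, smoking, histology, PD-L1 category,
  ECOG) are drawn independently of the cluster, so baseline-balance tests
  are null by construction.

The single-factor-per-star design was chosen over one global module factor
after calibration: a global factor makes *all* module pairs co-expressed,
flooding the differential network with neighbour–neighbour edges and
breaking the "hubs are the top 5% of the degree distribution" geometry,
whereas independent stars concentrate differential edges on the hubs.

What the generator does **not** emulate: count overdispersion families,
probe chemistry, batch effects, missing data, informative censoring, or
correlated clinical covariates. Tests passing on these cohorts demonstrate
that the pipeline recovers the structures it assumes; they do not certify
performance on real nCounter or cytometry data.

### A structural limit worth knowing

At the method's fixed operating point (438 genes, 23 hubs, |rho| > 0.7
candidate universe, |Z| > 2, 95th-percentile hubs) hub recovery and
edge-level precision trade off against each other *in any* generator: hubs
can only occupy the top ~5% of the degree distribution if ~all 415
non-hub genes carry differential edges to hubs at sample |rho| > 0.7, which
(by positive semidefiniteness of the correlation matrix) forces ~3,500
same-star satellite pairs above ~0.62 correlation; those equal-correlation
pairs enter the candidate set and pass |Z| > 2 at the test's own ~5% type-I
floor, capping edge precision near 0.5–0.6 while hub recovery sits at
~0.85. The test suite asserts both properties; the precision assertion
documents this ceiling rather than hiding it.

## Numerical choices

- Spearman p-values: two-sided t survival function; rho clipped away from
  ±1 only for the t computation, never for reported coefficients.
- BH: mergesort (stable) ordering; NaN entries pass through and do not
  count toward the family size.
- Hypergeometric tail: `scipy.stats.hypergeom.sf(k−1, N, K, n)`, verified
  against exact rational enumeration to 1e−12 for N ≤ 60.
- Eigendecompositions use `numpy.linalg.eigh` on the symmetrised
  Laplacian; eigengap candidates are restricted to [k_min, k_max] and a
  graph with more components than k_max returns k_max with a warning.
- k-means labels are canonicalised by first appearance so identical seeds
  give byte-identical assignments.
- LOOCV iteration seeds: SHA-256 of `"{base_seed}:{left_out_id}"`, reduced
  mod 2³¹−1.

## Problem sizes in the shipped tests

Unit tests that refit the whole pipeline use a scaled-down cohort (72
genes, 8 hubs, 28/24 patients); recovery statistics and the end-to-end
check run the full 438×44 design. Monte-Carlo sizes (5,000 null pairs, 500
log-rank simulations, 50 Cox replicates at n = 200, 10 recovery seeds) were
fixed when the corresponding expected values were calibrated and keep the
whole suite under a few minutes on one CPU.
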