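# netstrat

Multi-layer network analysis for small immunotherapy cohorts: group-wise
correlation networks of circulating immune profiles, differential
co-expression networks of panel gene expression, hub/community topology
with panel-restricted enrichment, Similarity Network Fusion (SNF) of the
two patient-similarity layers, survival stratification of the fused
clusters, and leave-one-out validation of the whole procedure.

## Who this is for

Translational groups analysing trial-sized cohorts (tens of patients)
profiled on a targeted expression panel plus blood immune phenotyping, who
want to ask: *do co-expression patterns — rather than single-gene shifts —
separate responders from non-responders, and does integrating tumour and
blood layers stratify survival better than either alone?*

## The method

1. **CIP networks.** Per response group and timepoint, Spearman
   correlations between the 31 immune subsets; edges kept at |ρ| > 0.55,
   BH-FDR < 0.05.
2. **Differential co-expression (DCN).** Group co-expression networks at
   |ρ| > 0.7, FDR < 0.05; every candidate pair (union of the two edge
   sets) is tested with the Fisher z-statistic

   $$Z = \frac{\operatorname{atanh}\rho_A - \operatorname{atanh}\rho_B}
             {\sqrt{\tfrac{1}{n_A-3}+\tfrac{1}{n_B-3}}},$$

   keeping |Z| > 2. Positive edges mark pairs more strongly co-expressed
   in responders.
3. **Topology.** Hubs = nodes above the 95th percentile of the DCN degree
   distribution; communities by seeded Louvain; hypergeometric
   over-representation of hub neighbourhoods and communities against the
   gene panel as background (user-supplied GMT).
4. **Integration.** Patient affinities from hub-gene expression and from
   the immune profile are fused by SNF cross-diffusion; the cluster count
   maximises the Laplacian eigengap; spectral clustering yields patient
   subtypes.
5. **Survival & validation.** Kaplan–Meier / log-rank / Cox (Efron ties)
   on the clusters, composition and balance tests, leave-one-out refits of
   the entire pipeline, and a hub-percentile sensitivity sweep.

Because cohorts of this design are not publicly deposited, the package
ships a synthetic-cohort generator (`netstrat.datagen`) with planted
hubs, differential pairs, a latent prognostic cluster and exponential
survival — the ground truth every recovery test measures against.

## Worked example

```bash
netstrat simulate --seed 1 --out cohort/
netstrat run --cohort cohort/ --out run/ --seed 1
```

or in Python:

```python
import netstrat as ns

cohort = ns.generate_cohort(ns.CohortConfig(seed=1))
net   = ns.build_dcn(cohort.expression, cohort.gep_groups())
hubs  = ns.select_hubs(net, percentile=95)
print(len(net.edges), len(hubs.genes))
# 782 20

truth = set(cohort.truth.planted_hub_genes)
print(f"hub recovery: {len(set(hubs.genes) & truth) / len(truth):.2f}")
# hub recovery: 0.87
```

The pipeline run writes, under `run/`: the four CIP network edge lists
with summaries, the two co-expression networks, `dcn_edges.tsv` /
`dcn_hubs.tsv` / `dcn_communities.tsv`, the fused similarity matrix and
`cluster_assignment.csv`, `survival_report.json` (medians, log-rank, Cox
univariate and covariate-adjusted hazard ratios, composition tests),
`loocv_report.json`, `sensitivity.tsv`, and a `manifest.json` with a
SHA-256 hash per artifact. For the seed-1 cohort the survival report
shows two clusters with accuracy 0.68 against response and log-rank
p = 0.015, and the LOOCV mean accuracy is 0.69 — the same regime the
method reports on real data.

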