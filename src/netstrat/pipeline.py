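"""Configuration-driven orchestration of the full multi-layer analysis.

Stage order mirrors the analysis design: immune-profile correlation networks
per response group and timepoint; group co-expression networks and the
differential co-expression network with hubs and communities; optional
over-representation analysis of hub neighbourhoods and communities;
patient-similarity layers (hub-gene expression, immune profile), SNF fusion,
eigengap model selection and spectral clustering; survival and
cluster-characterisation statistics; leave-one-out cross-validation and
hub-percentile sensitivity.  Every artifact lands under one run directory
with a hash manifest at its root.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import corrnet, dcn as dcn_mod, enrich as enrich_mod, fuse, survstats
from .datagen import SyntheticCohort, read_cohort

log = logging.getLogger("netstrat")

__all__ = ["PipelineConfig", "StratificationResult", "run_pipeline",
           "stratify", "read_expression", "load_config"]


@dataclass
class PipelineConfig:
    """Thresholds and knobs of the full analysis; defaults are the published
    operating point of the method."""

    # correlation-network thresholds
    cip_rho: float = 0.55
    gep_rho: float = 0.7
    q_max: float = 0.05
    z_min: float = 2.0
    hub_percentile: float = 95.0
    pair_universe: str = "union_of_networks"
    pooled_cip_fdr: bool = False
    # SNF / clustering
    snf_K: int = 20
    snf_mu: float = 0.5
    snf_t: int = 20
    k_min: int = 2
    k_max: int = 5
    n_clusters: int | None = None      # None: pick by eigengap
    restarts: int = 50
    # flags
    weighted_louvain: bool = False
    cip_timepoint: str = "pre"
    layers: str = "fused"              # fused | gep_only | cip_only
    enrichment_sign: str = "positive"
    seed: int = 0

    def __post_init__(self):
        for name in ("cip_rho", "gep_rho"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if not 0 < self.q_max <= 1:
            raise ValueError("q_max must be in (0, 1]")
        if self.z_min <= 0:
            raise ValueError("z_min must be positive")
        if not 0 < self.hub_percentile <= 100:
            raise ValueError("hub_percentile must be in (0, 100]")
        if self.cip_timepoint not in ("pre", "post"):
            raise ValueError("cip_timepoint must be 'pre' or 'post'")
        if self.layers not in ("fused", "gep_only", "cip_only"):
            raise ValueError("layers must be fused/gep_only/cip_only")


def load_config(path) -> PipelineConfig:
    """Read a flat YAML mapping of config keys."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


# ---------------------------------------------------------------------------
# I/O


def read_expression(path) -> pd.DataFrame:
    """Genes x samples TSV: first column gene id, header = sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate gene id(s): {dup}")
    bad_cells = []
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna()]
        bad_cells.extend((g, col) for g in bad)
        out[col] = converted
    if bad_cells:
        raise ValueError(
            f"non-numeric or missing cells (gene, sample): {bad_cells[:10]}"
        )
    return out


# ---------------------------------------------------------------------------
# core stratification (reused verbatim by the LOOCV refits)


@dataclass
class StratificationResult:
    dcn: "dcn_mod.DifferentialNetwork"
    hubs: "dcn_mod.HubSet"
    assignment: fuse.ClusterAssignment
    fused: fuse.FusedNetwork | None
    k_selected: int
    accuracy: float | None = None
    confusion: pd.DataFrame | None = None
    logrank: tuple[float, float] | None = None


def _log_counts(expression: pd.DataFrame) -> pd.DataFrame:
    return np.log2(expression + 1.0)


def stratify(
    expression: pd.DataFrame,
    groups: dict[str, str],
    immune: pd.DataFrame,
    common_ids: list[str],
    cfg: PipelineConfig,
    hub_genes: list[str] | None = None,
) -> StratificationResult:
    """DCN -> hubs -> similarity layers -> SNF -> spectral clustering.

    ``hub_genes`` overrides hub selection (used by the percentile-sensitivity
    sweep); otherwise hubs are selected from the DCN at
    ``cfg.hub_percentile``.  The patient-similarity layers are restricted to
    ``common_ids`` (patients with both data types).
    """
    network = dcn_mod.build_dcn(
        expression,
        groups,
        z_min=cfg.z_min,
        rho_min=cfg.gep_rho,
        q_max=cfg.q_max,
        pair_universe=cfg.pair_universe,
    )
    if hub_genes is None:
        hubs = dcn_mod.select_hubs(network, percentile=cfg.hub_percentile)
    else:
        deg = network.degree()
        hubs = dcn_mod.HubSet(
            genes=sorted(hub_genes, key=lambda g: (-deg.get(g, 0), g)),
            degree={g: deg.get(g, 0) for g in hub_genes},
            percentile_used=float("nan"),
            degree_threshold=float("nan"),
        )
    if not hubs.genes:
        raise ValueError("empty hub set: cannot build the expression layer")

    gep_features = _log_counts(expression.loc[hubs.genes, common_ids]).T
    cip_features = immune.loc[common_ids]
    aff_gep = fuse.affinity_matrix(gep_features, K=cfg.snf_K, mu=cfg.snf_mu)
    aff_gep.params["layer"] = "gep"
    aff_cip = fuse.affinity_matrix(cip_features, K=cfg.snf_K, mu=cfg.snf_mu)
    aff_cip.params["layer"] = "cip"

    fused = None
    if cfg.layers == "fused":
        fused = fuse.snf_fuse([aff_gep, aff_cip], K=cfg.snf_K, t=cfg.snf_t)
        W, ids = fused.P, fused.patient_ids
    elif cfg.layers == "gep_only":
        W, ids = aff_gep.W, aff_gep.patient_ids
    else:
        W, ids = aff_cip.W, aff_cip.patient_ids

    if cfg.n_clusters is None:
        k, _ = fuse.eigengap_k(W, k_min=cfg.k_min, k_max=cfg.k_max)
    else:
        k = cfg.n_clusters
    assignment = fuse.spectral_cluster(
        W, k=k, seed=cfg.seed, restarts=cfg.restarts, patient_ids=ids
    )
    return StratificationResult(
        dcn=network, hubs=hubs, assignment=assignment, fused=fused, k_selected=k
    )


def evaluate_stratification(
    result: StratificationResult, clinical: pd.DataFrame
) -> StratificationResult:
    """Attach response concordance and survival separation to a result."""
    ids = list(result.assignment.labels)
    labels = clinical.loc[ids, "response"]
    if result.k_selected == 2:
        acc, confusion, _ = survstats.cluster_accuracy(
            result.assignment.labels, labels
        )
        result.accuracy = acc
        result.confusion = confusion
        cl = pd.Series(result.assignment.labels).loc[ids]
        if cl.nunique() == 2:
            stat, p = survstats.logrank_test(
                clinical.loc[ids, "time_months"],
                clinical.loc[ids, "event"],
                cl.to_numpy(),
            )
            result.logrank = (stat, p)
    return result


# ---------------------------------------------------------------------------
# full run


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    cohort: SyntheticCohort | str | Path,
    out_dir,
    cfg: PipelineConfig | None = None,
    gmt_path=None,
) -> dict:
    """Run every stage on a cohort (object or cohort directory) and write all
    artifacts plus a hash manifest under ``out_dir``.  Returns the manifest.
    """
    cfg = cfg or PipelineConfig()
    if not isinstance(cohort, SyntheticCohort):
        cohort = read_cohort(cohort)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    produced: list[Path] = []
    warnings_seen: list[str] = []
    stage = "start"

    def save_tsv(df: pd.DataFrame, name: str, index=True):
        path = out / name
        df.to_csv(path, sep="\t", index=index)
        produced.append(path)

    def save_json(obj, name: str):
        path = out / name
        path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=str))
        produced.append(path)

    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")

            # -- stage 1: CIP correlation networks ----------------------
            stage = "cip_networks"
            log.info("stage %s", stage)
            common = cohort.common_ids()
            resp = cohort.clinical.loc[common, "response"]
            cip_summaries = {}
            for timepoint, table in (
                ("pre", cohort.immune_pre), ("post", cohort.immune_post)
            ):
                for lab in ("responder", "non-responder"):
                    sub = table.loc[resp[resp == lab].index]
                    net = corrnet.build_correlation_network(
                        sub, rho_min=cfg.cip_rho, q_max=cfg.q_max,
                        metadata={"group": lab, "timepoint": timepoint},
                    )
                    name = f"cip_{timepoint}_{lab.replace('-', '')}"
                    corrnet.write_edge_list(net, out / f"{name}_edges.tsv")
                    produced.append(out / f"{name}_edges.tsv")
                    s = corrnet.network_summary(net)
                    cip_summaries[name] = {
                        "n_nodes": s.n_nodes, "n_edges": s.n_edges,
                        "n_positive": s.n_positive, "n_negative": s.n_negative,
                        "n_components": s.n_components,
                    }
            save_json(cip_summaries, "cip_network_summaries.json")

            # -- stage 2: DCN -------------------------------------------
            stage = "dcn"
            log.info("stage %s", stage)
            groups = cohort.gep_groups()
            net_a, net_b = dcn_mod.build_coexpression_networks(
                cohort.expression, groups, rho_min=cfg.gep_rho, q_max=cfg.q_max
            )
            for net, name in ((net_a, "coexpression_responders"),
                              (net_b, "coexpression_nonresponders")):
                corrnet.write_edge_list(net, out / f"{name}_edges.tsv")
                produced.append(out / f"{name}_edges.tsv")
            result = stratify(
                cohort.expression, groups, getattr(
                    cohort, f"immune_{cfg.cip_timepoint}"
                ), common, cfg,
            )
            save_tsv(result.dcn.edge_table(), "dcn_edges.tsv", index=False)
            save_tsv(
                pd.DataFrame(
                    {"gene": result.hubs.genes,
                     "degree": [result.hubs.degree[g] for g in result.hubs.genes]}
                ),
                "dcn_hubs.tsv", index=False,
            )
            communities = dcn_mod.louvain_communities(
                result.dcn, seed=cfg.seed, weighted=cfg.weighted_louvain
            )
            save_tsv(
                pd.DataFrame(
                    sorted(communities.membership.items()),
                    columns=["gene", "community"],
                ),
                "dcn_communities.tsv", index=False,
            )
            save_json(
                {"n_edges": len(result.dcn.edges),
                 "n_positive": sum(1 for e in result.dcn.edges if e.Z > 0),
                 "n_negative": sum(1 for e in result.dcn.edges if e.Z < 0),
                 "n_hubs": len(result.hubs.genes),
                 "hub_degree_threshold": result.hubs.degree_threshold,
                 "n_communities": len(set(communities.membership.values())),
                 "modularity_Q": communities.modularity_Q},
                "dcn_summary.json",
            )

            # -- stage 3: enrichment ------------------------------------
            stage = "enrichment"
            if gmt_path is not None:
                log.info("stage %s", stage)
                collection = enrich_mod.read_gmt(gmt_path)
                background = set(cohort.expression.index)
                tables = []
                for hub in result.hubs.genes:
                    query = enrich_mod.hub_neighborhood(
                        result.dcn, hub, sign=cfg.enrichment_sign
                    )
                    try:
                        tbl = enrich_mod.enrich(query, collection, background)
                    except ValueError:
                        continue
                    tbl.insert(0, "query", f"hub:{hub}")
                    tables.append(tbl)
                comm_sets: dict[int, set] = {}
                for g, cid in communities.membership.items():
                    comm_sets.setdefault(cid, set()).add(g)
                for cid, members in sorted(comm_sets.items()):
                    try:
                        tbl = enrich_mod.enrich(members, collection, background)
                    except ValueError:
                        continue
                    tbl.insert(0, "query", f"community:{cid}")
                    tables.append(tbl)
                if tables:
                    save_tsv(
                        pd.concat(tables, ignore_index=True),
                        "enrichment.tsv", index=False,
                    )

            # -- stage 4: fusion + clustering ---------------------------
            stage = "fusion"
            log.info("stage %s", stage)
            if result.fused is not None:
                save_tsv(
                    pd.DataFrame(result.fused.P, index=common, columns=common),
                    "fused_similarity.tsv",
                )
            assign = pd.Series(result.assignment.labels, name="cluster")
            assign.rename_axis("patient_id").to_frame().to_csv(
                out / "cluster_assignment.csv"
            )
            produced.append(out / "cluster_assignment.csv")
            save_json(
                {"k": result.k_selected,
                 "eigengap_values": result.assignment.eigengap_values,
                 "snf": {"K": cfg.snf_K, "mu": cfg.snf_mu, "t": cfg.snf_t},
                 "layers": cfg.layers},
                "clustering_report.json",
            )

            # -- stage 5: survival + characterisation -------------------
            stage = "survival"
            log.info("stage %s", stage)
            result = evaluate_stratification(result, cohort.clinical)
            clin = cohort.clinical.loc[common].copy()
            clin["cluster"] = assign.loc[common]
            km_rows = []
            for cl in sorted(clin["cluster"].unique()):
                sub = clin[clin["cluster"] == cl]
                km = survstats.km_curve(sub["time_months"], sub["event"])
                step = km.step_function()
                step.insert(0, "cluster", cl)
                km_rows.append((cl, km, step))
            save_tsv(
                pd.concat([s for _, _, s in km_rows], ignore_index=True),
                "km_curves.tsv", index=False,
            )
            surv_report = {
                "medians_by_cluster": {
                    str(cl): km.median for cl, km, _ in km_rows
                },
            }
            if result.logrank is not None:
                surv_report["logrank_statistic"] = result.logrank[0]
                surv_report["logrank_p"] = result.logrank[1]
            if result.accuracy is not None:
                surv_report["accuracy_vs_response"] = result.accuracy
                enr = survstats.cluster_enrichment(
                    clin["cluster"], clin["response"]
                )
                surv_report["cluster_composition"] = enr.to_dict("records")
            sizes = clin["cluster"].value_counts()
            if (
                clin["cluster"].nunique() == 2
                and sizes.min() >= 2
                and clin["event"].sum() >= 2
            ):
                uni = survstats.cox_ph(clin, ["cluster"])
                adj = survstats.cox_ph(
                    clin, ["cluster", "age", "smoking", "histology",
                           "pdl1", "ecog"],
                )
                surv_report["cox_univariate"] = _cox_dict(uni)
                surv_report["cox_adjusted"] = _cox_dict(adj)
                balance = survstats.baseline_balance(
                    clin[["age", "sex", "smoking", "histology", "pdl1", "ecog"]],
                    clin["cluster"],
                )
                save_tsv(balance, "baseline_balance.tsv", index=False)
                hub_vars = _log_counts(
                    cohort.expression.loc[result.hubs.genes, common]
                ).T
                save_tsv(
                    survstats.compare_clusters(hub_vars, clin["cluster"]),
                    "cluster_comparison_gep.tsv", index=False,
                )
                save_tsv(
                    survstats.compare_clusters(
                        getattr(cohort, f"immune_{cfg.cip_timepoint}").loc[common],
                        clin["cluster"],
                    ),
                    "cluster_comparison_cip.tsv", index=False,
                )
            save_json(surv_report, "survival_report.json")

            # -- stage 6: validation ------------------------------------
            stage = "validation"
            log.info("stage %s", stage)
            from . import validate

            loocv_rep = validate.loocv(cohort, cfg)
            save_json(validate.loocv_report_dict(loocv_rep), "loocv_report.json")
            sens = validate.percentile_sensitivity(cohort, cfg)
            save_tsv(validate.sensitivity_table(sens), "sensitivity.tsv",
                     index=False)

            warnings_seen = sorted({str(w.message) for w in caught})
    except Exception as err:
        manifest = {
            "status": "failed", "failed_stage": stage, "error": str(err),
            "partial_outputs": [p.name for p in produced],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    stage = "manifest"
    manifest = {
        "status": "ok",
        "config": dataclasses.asdict(cfg),
        "software_version": _version(),
        "files": {p.name: _sha256(p) for p in sorted(produced)},
        "warnings": warnings_seen,
        "wall_seconds": round(time.time() - t0, 2),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _cox_dict(fit: survstats.CoxFit) -> dict:
    return {
        "converged": fit.converged,
        "flagged": fit.flagged,
        "n": fit.n,
        "n_events": fit.n_events,
        "covariates": {
            name: {
                "coef": float(fit.coefficients[name]),
                "HR": float(fit.hazard_ratios[name]),
                "ci": [float(fit.ci_lower[name]), float(fit.ci_upper[name])],
                "p": float(fit.p[name]),
            }
            for name in fit.coefficients.index
        },
    }


def _version() -> str:
    from . import __version__

    return __version__
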