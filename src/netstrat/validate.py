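"""Internal validation: leave-one-out refits, hub-percentile sensitivity and
partition-agreement metrics.

Each LOOCV iteration removes one patient and repeats the entire process —
differential network, hub selection, similarity fusion, spectral clustering
— on the remaining patients, then scores concordance with clinical response
and survival separation on that retained set.  The percentile sweep rebuilds
the expression layer from hub sets at several degree thresholds and compares
the resulting partitions to the reference one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import survstats
from .datagen import SyntheticCohort
from .pipeline import PipelineConfig, StratificationResult, evaluate_stratification, stratify

__all__ = [
    "LoocvReport",
    "SensitivityReport",
    "adjusted_rand_index",
    "loocv",
    "percentile_sensitivity",
]

DEFAULT_PERCENTILES = (75.0, 90.0, 95.0, 98.0, 99.0)


@dataclass
class LoocvIteration:
    left_out_id: str
    accuracy: float | None
    logrank_p: float | None
    failed: str | None = None


@dataclass
class LoocvReport:
    per_iteration: list[LoocvIteration]
    mean_accuracy: float
    sd_accuracy: float
    fraction_significant_logrank: float


@dataclass
class SensitivityRow:
    percentile: float
    n_hubs: int
    ari_vs_reference: float | None
    accuracy: float | None
    failed: str | None = None


@dataclass
class SensitivityReport:
    per_percentile: list[SensitivityRow]
    reference_percentile: float


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions of the same items."""
    a = np.asarray(list(labels_a))
    b = np.asarray(list(labels_b))
    if a.shape != b.shape:
        raise ValueError(f"size mismatch: {a.shape} vs {b.shape}")
    from sklearn.metrics import adjusted_rand_score

    return float(adjusted_rand_score(a, b))


def _iteration_seed(base_seed: int, left_out: str) -> int:
    """Deterministic per-iteration seed below 2**31, independent across ids."""
    import hashlib

    h = hashlib.sha256(f"{base_seed}:{left_out}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def loocv(
    cohort: SyntheticCohort,
    cfg: PipelineConfig | None = None,
) -> LoocvReport:
    """Leave-one-out refit of the whole stratification pipeline.

    Each common patient is withheld in turn; the differential network, hub
    set, similarity layers, fusion and clustering are recomputed from the
    remaining data (two clusters are always requested — the concordance
    statistic is defined for the two-cluster design), and the iteration
    records the retained-set accuracy vs response and the between-cluster
    log-rank p.  Failed iterations are recorded, never silently dropped.
    """
    cfg = cfg or PipelineConfig()
    common = cohort.common_ids()
    if len(common) < 10:
        raise ValueError(f"need at least 10 patients for LOOCV, got {len(common)}")
    immune = getattr(cohort, f"immune_{cfg.cip_timepoint}")
    groups_all = cohort.gep_groups()
    iterations = []
    for left_out in common:
        retained = [p for p in common if p != left_out]
        expr = cohort.expression.drop(columns=left_out)
        groups = {p: g for p, g in groups_all.items() if p != left_out}
        it_cfg = PipelineConfig(
            **{
                **_cfg_dict(cfg),
                "seed": _iteration_seed(cfg.seed, left_out),
                "n_clusters": 2,
            }
        )
        try:
            result = stratify(expr, groups, immune, retained, it_cfg)
            result = evaluate_stratification(result, cohort.clinical)
            iterations.append(
                LoocvIteration(
                    left_out_id=left_out,
                    accuracy=result.accuracy,
                    logrank_p=None if result.logrank is None else result.logrank[1],
                )
            )
        except Exception as err:  # recorded, not skipped
            iterations.append(
                LoocvIteration(left_out_id=left_out, accuracy=None,
                               logrank_p=None, failed=str(err))
            )
    accs = [it.accuracy for it in iterations if it.accuracy is not None]
    ps = [it.logrank_p for it in iterations if it.logrank_p is not None]
    return LoocvReport(
        per_iteration=iterations,
        mean_accuracy=float(np.mean(accs)) if accs else float("nan"),
        sd_accuracy=float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
        fraction_significant_logrank=(
            float(np.mean([p < 0.05 for p in ps])) if ps else float("nan")
        ),
    )


def percentile_sensitivity(
    cohort: SyntheticCohort,
    cfg: PipelineConfig | None = None,
    percentiles=DEFAULT_PERCENTILES,
) -> SensitivityReport:
    """Hub-threshold sensitivity sweep.

    For each degree percentile the hub set, expression layer, fusion and
    2-cluster partition are recomputed; each row reports the hub count, the
    adjusted Rand index against the reference partition (the configured
    ``hub_percentile``, 95 by default) and the accuracy vs response.  An
    empty hub set flags the row and the sweep continues.
    """
    from . import dcn as dcn_mod

    cfg = cfg or PipelineConfig()
    common = cohort.common_ids()
    immune = getattr(cohort, f"immune_{cfg.cip_timepoint}")
    groups = cohort.gep_groups()
    base_cfg = PipelineConfig(**{**_cfg_dict(cfg), "n_clusters": 2})
    reference = stratify(cohort.expression, groups, immune, common, base_cfg)
    reference = evaluate_stratification(reference, cohort.clinical)
    ref_labels = [reference.assignment.labels[p] for p in common]
    rows = [
        SensitivityRow(
            percentile=cfg.hub_percentile,
            n_hubs=len(reference.hubs.genes),
            ari_vs_reference=1.0,
            accuracy=reference.accuracy,
        )
    ]
    for pct in percentiles:
        if pct == cfg.hub_percentile:
            continue
        try:
            hubs = dcn_mod.select_hubs(reference.dcn, percentile=pct)
            if not hubs.genes:
                raise ValueError("empty hub set")
            result = stratify(
                cohort.expression, groups, immune, common, base_cfg,
                hub_genes=hubs.genes,
            )
            result = evaluate_stratification(result, cohort.clinical)
            rows.append(
                SensitivityRow(
                    percentile=pct,
                    n_hubs=len(hubs.genes),
                    ari_vs_reference=adjusted_rand_index(
                        ref_labels,
                        [result.assignment.labels[p] for p in common],
                    ),
                    accuracy=result.accuracy,
                )
            )
        except ValueError as err:
            rows.append(
                SensitivityRow(percentile=pct, n_hubs=0, ari_vs_reference=None,
                               accuracy=None, failed=str(err))
            )
    rows.sort(key=lambda r: r.percentile)
    return SensitivityReport(
        per_percentile=rows, reference_percentile=cfg.hub_percentile
    )


# ---------------------------------------------------------------------------
# serialisation helpers


def _cfg_dict(cfg: PipelineConfig) -> dict:
    import dataclasses

    return dataclasses.asdict(cfg)


def loocv_report_dict(rep: LoocvReport) -> dict:
    return {
        "mean_accuracy": rep.mean_accuracy,
        "sd_accuracy": rep.sd_accuracy,
        "fraction_significant_logrank": rep.fraction_significant_logrank,
        "n_iterations": len(rep.per_iteration),
        "n_failed": sum(1 for it in rep.per_iteration if it.failed),
        "per_iteration": [
            {"left_out_id": it.left_out_id, "accuracy": it.accuracy,
             "logrank_p": it.logrank_p, "failed": it.failed}
            for it in rep.per_iteration
        ],
    }


def sensitivity_table(rep: SensitivityReport) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"percentile": r.percentile, "n_hubs": r.n_hubs,
             "ari_vs_reference": r.ari_vs_reference, "accuracy": r.accuracy,
             "failed": r.failed or ""}
            for r in rep.per_percentile
        ]
    )
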