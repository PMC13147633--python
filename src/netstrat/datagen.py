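"""Synthetic immunotherapy cohorts with planted network structure.

The generator emulates the data layout of a phase-II immunotherapy cohort:
a panel expression matrix (438 genes x 44 patients on the count scale), two
circulating immune-profile tables (31 subset percentages at baseline and
after two treatment cycles) for the 38 patients with both data types, a
clinical table (response, overall survival, baseline covariates) and a
ground-truth object for parameter-recovery tests.

Planted structure
-----------------
*Expression* — 23 "hub" genes each anchor a star of ~18 satellite genes.
In responders a satellite's latent expression tracks its hub with Spearman
correlation ``rho_within_module`` (0.8); in non-responders the hub decouples
while the satellites keep their shared per-star factor, so hub-satellite
pairs (and only those) are differentially co-expressed between the groups.
Satellite residuals within a star are equicorrelated at -1/(s-1), the
positive-semidefiniteness floor, to keep satellite-satellite correlations as
far below the co-expression threshold as the hub correlation allows.
Latent values are mapped to counts via a gene-specific log-normal scale.

*Immune profile* — a Gaussian copula with a myeloid correlation block in
every group/timepoint and an NK-myeloid bridging block present only in
responders before therapy, pushed through a logistic transform onto the
(0, 100) percentage scale.

*Survival* — exponential, with hazard multiplied by ``hazard_ratio`` in the
unfavourable latent cluster; the latent cluster equals the response label
flipped independently with probability ``cluster_flip_prob`` so clustering
and response agree imperfectly, as observed cohorts do.  Censoring is
independent: each patient is censored with probability ``censoring_rate``
at a uniform fraction of their event time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CohortConfig", "GroundTruth", "SyntheticCohort",
           "generate_cohort", "write_cohort", "read_cohort"]

#: immune-subset variable names: a myeloid block, an NK block, and lymphoid /
#: other subsets, 31 in total, mirroring a typical cytometry panel.
MYELOID_VARS = [
    "monocytes", "neutrophils", "m_mdsc", "g_mdsc", "classical_cd14",
    "cd14_hla_dr", "granulo_hla_drdim", "eosinophils",
]
NK_VARS = [
    "nk_cd3neg_cd56pos", "nk_cd56dim_cd16pos", "nk_cd56bright", "nk_t_like",
    "nk_cd69pos", "nk_nkg2dpos",
]
OTHER_VARS = [
    "cd3_t", "cd4_t", "cd8_t", "treg", "b_cells", "plasmablasts",
    "cd4_naive", "cd4_memory", "cd8_naive", "cd8_memory", "gamma_delta_t",
    "pd1_cd4", "pd1_cd8", "ctla4_t", "dendritic", "basophils", "ilc",
]
IMMUNE_VARS = MYELOID_VARS + NK_VARS + OTHER_VARS


@dataclass
class CohortConfig:
    """Cohort dimensions and effect sizes; defaults are the study conditions."""

    n_patients_gep: int = 44
    n_patients_common: int = 38
    n_responders_common: int = 20
    n_responders_gep: int = 22
    n_genes: int = 438
    n_immune_vars: int = 31
    n_planted_hubs: int = 23
    rho_within_module: float = 0.8
    hazard_ratio: float = 4.5
    censoring_rate: float = 0.2
    cluster_flip_prob: float = 0.2
    cluster_separation_gep: float = 1.2
    cluster_separation_cip: float = 1.0
    median_survival_good_months: float = 32.0
    seed: int = 0

    def __post_init__(self):
        counts = {
            "n_patients_gep": self.n_patients_gep,
            "n_patients_common": self.n_patients_common,
            "n_responders_common": self.n_responders_common,
            "n_responders_gep": self.n_responders_gep,
            "n_genes": self.n_genes,
            "n_immune_vars": self.n_immune_vars,
            "n_planted_hubs": self.n_planted_hubs,
        }
        for name, v in counts.items():
            if int(v) != v or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v}")
        if not (self.n_responders_common <= self.n_patients_common
                <= self.n_patients_gep):
            raise ValueError(
                "need n_responders_common <= n_patients_common <= n_patients_gep"
            )
        if self.n_responders_gep < self.n_responders_common or (
            self.n_patients_gep - self.n_responders_gep
            < self.n_patients_common - self.n_responders_common
        ):
            raise ValueError(
                "per-group counts of common patients cannot exceed the "
                "corresponding expression-cohort group counts"
            )
        if not 0 <= self.rho_within_module < 1:
            raise ValueError("rho_within_module must lie in [0, 1)")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")
        if self.n_planted_hubs >= self.n_genes:
            raise ValueError("n_planted_hubs must be smaller than n_genes")


@dataclass
class GroundTruth:
    planted_hub_genes: list[str]
    planted_differential_pairs: list[tuple[str, str]]
    latent_cluster: dict[str, int]      # 0 = favourable, 1 = unfavourable
    true_log_hazard_ratio: float

    def to_json(self) -> str:
        payload = asdict(self)
        payload["planted_differential_pairs"] = [
            list(p) for p in self.planted_differential_pairs
        ]
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            planted_hub_genes=list(d["planted_hub_genes"]),
            planted_differential_pairs=[
                tuple(p) for p in d["planted_differential_pairs"]
            ],
            latent_cluster={k: int(v) for k, v in d["latent_cluster"].items()},
            true_log_hazard_ratio=float(d["true_log_hazard_ratio"]),
        )


@dataclass
class SyntheticCohort:
    expression: pd.DataFrame        # genes x samples, integer counts
    immune_pre: pd.DataFrame        # common samples x immune vars, percent
    immune_post: pd.DataFrame
    clinical: pd.DataFrame          # indexed by patient id
    truth: GroundTruth
    config: CohortConfig = field(repr=False, default=None)

    @property
    def response(self) -> pd.Series:
        return self.clinical["response"]

    def gep_groups(self) -> dict[str, str]:
        """sample id -> response label for every expression-cohort patient."""
        return self.clinical.loc[self.expression.columns, "response"].to_dict()

    def common_ids(self) -> list[str]:
        return list(self.immune_pre.index)


# ---------------------------------------------------------------------------
# generation


def _spearman_to_pearson(rho_s: float) -> float:
    """Latent Pearson correlation giving Spearman ``rho_s`` for a bivariate
    normal pair (Pearson's classical relation)."""
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


def generate_cohort(config: CohortConfig | None = None, **kwargs) -> SyntheticCohort:
    """Draw a complete synthetic cohort from ``config`` (deterministic in
    ``config.seed``)."""
    if config is None:
        config = CohortConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a CohortConfig or keyword fields, not both")
    rng = np.random.default_rng(config.seed)

    # ---- patient bookkeeping -------------------------------------------
    n_gep = config.n_patients_gep
    n_common = config.n_patients_common
    patients = [f"P{i + 1:03d}" for i in range(n_gep)]
    n_r_gep = config.n_responders_gep
    response = np.array(
        ["responder"] * n_r_gep + ["non-responder"] * (n_gep - n_r_gep)
    )
    # common patients: the first n_responders_common responders and the first
    # (n_common - n_responders_common) non-responders
    common = (
        patients[: config.n_responders_common]
        + patients[n_r_gep : n_r_gep + (n_common - config.n_responders_common)]
    )

    # ---- latent prognostic cluster -------------------------------------
    # response label flipped independently with cluster_flip_prob, so the
    # prognostic structure and the response agree imperfectly
    latent_cluster = {}
    for p, lab in zip(patients, response):
        flip = rng.random() < config.cluster_flip_prob
        good = (lab == "responder") != flip
        latent_cluster[p] = 0 if good else 1
    cluster_ind = np.array([latent_cluster[p] for p in patients], float)

    # ---- expression: planted star structure ----------------------------
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    n_hubs = config.n_planted_hubs
    hub_idx = list(range(n_hubs))
    sat_idx = np.array_split(np.arange(n_hubs, config.n_genes), n_hubs)
    c = _spearman_to_pearson(config.rho_within_module)
    # the latent-cluster mean shift lives inside each star factor, so hubs
    # and satellites inherit it coherently (the "immune program" is elevated
    # in the favourable cluster); decoupled hubs keep the shift but lose the
    # program, so satellite-satellite correlations stay equal across groups
    # while hub-satellite pairs are strongly differential
    delta = config.cluster_separation_gep

    resp_cols = np.where(response == "responder")[0]
    nonr_cols = np.where(response == "non-responder")[0]
    latent = np.empty((config.n_genes, n_gep))
    for cols, coupled in ((resp_cols, True), (nonr_cols, False)):
        block = np.empty((config.n_genes, len(cols)))
        shift = delta * (0.5 - cluster_ind[cols])
        for h in range(n_hubs):
            f = rng.standard_normal(len(cols)) + shift
            base = f if coupled else rng.standard_normal(len(cols)) + shift
            block[h] = base
            sats = sat_idx[h]
            s = len(sats)
            U = rng.standard_normal((s, len(cols)))
            if s > 1:
                U = U - U.mean(axis=0, keepdims=True)
                U = U / np.sqrt((s - 1) / s)
            block[sats] = c * f + np.sqrt(1.0 - c**2) * U
        latent[:, cols] = block

    # log-normal count scale: gene-specific abundance, moderate dispersion
    log_mean = rng.uniform(np.log(80), np.log(600), size=config.n_genes)
    log_sd = rng.uniform(0.4, 0.7, size=config.n_genes)
    counts = np.rint(
        np.exp(log_mean[:, None] + log_sd[:, None] * latent)
    ).astype(int)
    counts = np.maximum(counts, 0)
    expression = pd.DataFrame(counts, index=genes, columns=patients)

    # ---- immune profile: copula with group/timepoint-specific blocks ---
    immune_tables = {}
    n_my, n_nk = len(MYELOID_VARS), len(NK_VARS)
    var_names = IMMUNE_VARS[: config.n_immune_vars]
    if config.n_immune_vars > len(IMMUNE_VARS):
        var_names = var_names + [
            f"subset_{j}" for j in range(len(IMMUNE_VARS), config.n_immune_vars)
        ]
    v = len(var_names)
    base_loc = rng.normal(-1.2, 0.7, size=v)     # logit-scale abundance
    for timepoint in ("pre", "post"):
        rows = np.empty((len(common), v))
        for gi, lab in enumerate(("responder", "non-responder")):
            members = [i for i, p in enumerate(common)
                       if response[patients.index(p)] == lab]
            corr = np.eye(v)
            my = slice(0, min(n_my, v))
            corr[my, my.start:my.stop] = np.where(
                np.eye(my.stop - my.start), 1.0, 0.7
            )
            bridge = lab == "responder" and timepoint == "pre"
            if v >= n_my + n_nk:
                nk = slice(n_my, n_my + n_nk)
                corr[nk, nk.start:nk.stop] = np.where(
                    np.eye(n_nk), 1.0, 0.5
                )
                if bridge:
                    corr[my, nk] = 0.45
                    corr[nk, my] = 0.45
            # nearest-PSD guard (block values chosen PSD; cheap validation)
            np.linalg.cholesky(corr + 1e-10 * np.eye(v))
            z = rng.multivariate_normal(
                np.zeros(v), corr, size=len(members), method="cholesky"
            )
            # NK subsets are elevated in the favourable latent cluster
            if v >= n_my + n_nk:
                ind = np.array(
                    [latent_cluster[common[m]] for m in members], float
                )
                z[:, n_my : n_my + n_nk] += (
                    config.cluster_separation_cip * (0.5 - ind)[:, None]
                )
            rows[members] = 100.0 / (1.0 + np.exp(-(base_loc + 0.6 * z)))
        immune_tables[timepoint] = pd.DataFrame(
            rows, index=common, columns=var_names
        )

    # ---- survival and clinical covariates ------------------------------
    rate_good = np.log(2.0) / config.median_survival_good_months
    times, events = [], []
    for p in patients:
        rate = rate_good * (
            config.hazard_ratio if latent_cluster[p] == 1 else 1.0
        )
        t = rng.exponential(1.0 / rate)
        if rng.random() < config.censoring_rate:
            times.append(t * rng.uniform())
            events.append(0)
        else:
            times.append(t)
            events.append(1)
    clinical = pd.DataFrame(
        {
            "response": response,
            "time_months": np.round(np.maximum(times, 0.25), 2),
            "event": events,
            "age": np.clip(np.rint(rng.normal(67, 8, n_gep)), 38, 88).astype(int),
            "sex": rng.choice(["male", "female"], size=n_gep, p=[0.6, 0.4]),
            "smoking": rng.choice(
                ["never", "former", "current"], size=n_gep, p=[0.1, 0.55, 0.35]
            ),
            "histology": rng.choice(
                ["squamous", "non-squamous"], size=n_gep, p=[0.25, 0.75]
            ),
            "pdl1": rng.choice(["<1%", "1-49%"], size=n_gep, p=[0.3, 0.7]),
            "ecog": rng.choice(["0-1", "2"], size=n_gep, p=[0.85, 0.15]),
            "common": [p in set(common) for p in patients],
        },
        index=pd.Index(patients, name="patient_id"),
    )

    pairs = []
    for h in range(n_hubs):
        for sidx in sat_idx[h]:
            pairs.append((genes[h], genes[sidx]))
    truth = GroundTruth(
        planted_hub_genes=[genes[i] for i in hub_idx],
        planted_differential_pairs=pairs,
        latent_cluster=latent_cluster,
        true_log_hazard_ratio=float(np.log(config.hazard_ratio)),
    )
    return SyntheticCohort(
        expression=expression,
        immune_pre=immune_tables["pre"],
        immune_post=immune_tables["post"],
        clinical=clinical,
        truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# on-disk format


def write_cohort(cohort: SyntheticCohort, directory) -> dict[str, str]:
    """Write a cohort directory: expression TSV (genes x samples), immune and
    clinical CSVs, ground-truth JSON and a manifest; returns name -> path."""
    directory = Path(directory)
    if not directory.parent.exists():
        raise FileNotFoundError(
            f"parent directory does not exist: {directory.parent}"
        )
    directory.mkdir(exist_ok=True)
    files = {}
    ex = directory / "expression.tsv"
    cohort.expression.rename_axis("gene_id").to_csv(ex, sep="\t")
    files["expression"] = ex.name
    for name, tbl in (
        ("immune_pre", cohort.immune_pre),
        ("immune_post", cohort.immune_post),
        ("clinical", cohort.clinical),
    ):
        path = directory / f"{name}.csv"
        tbl.rename_axis("patient_id").to_csv(path)
        files[name] = path.name
    tr = directory / "truth.json"
    tr.write_text(cohort.truth.to_json())
    files["truth"] = tr.name
    manifest = directory / "manifest.json"
    manifest.write_text(json.dumps(
        {"files": files, "config": asdict(cohort.config) if cohort.config else None},
        indent=1, sort_keys=True,
    ))
    files["manifest"] = manifest.name
    return {k: str(directory / v) for k, v in files.items()}


def read_cohort(directory) -> SyntheticCohort:
    """Read a cohort directory written by :func:`write_cohort`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    expression = pd.read_csv(
        directory / "expression.tsv", sep="\t", index_col="gene_id"
    )
    immune_pre = pd.read_csv(directory / "immune_pre.csv", index_col="patient_id")
    immune_post = pd.read_csv(directory / "immune_post.csv", index_col="patient_id")
    clinical = pd.read_csv(directory / "clinical.csv", index_col="patient_id")
    clinical["common"] = clinical["common"].astype(bool)
    truth = GroundTruth.from_json((directory / "truth.json").read_text())
    cfg = manifest.get("config")
    return SyntheticCohort(
        expression=expression,
        immune_pre=immune_pre,
        immune_post=immune_post,
        clinical=clinical,
        truth=truth,
        config=CohortConfig(**cfg) if cfg else None,
    )
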