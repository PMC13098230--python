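"""Synthetic donor-patient multi-omic cohort generator.

Emulates the structure of a paired FMT study: a fixed donor provides a pool
of reference samples, each patient contributes one baseline and one
post-treatment sample, and patients split into responders and
non-responders. Two kinds of signal are planted so that every downstream
stage has a ground-truth recovery test:

* **Response-associated features.** On the (log) latent scale, selected taxa
  and metabolites are shifted by ``effect_size * noise_sd`` in all patient
  baselines relative to donors. In responders' post samples the feature
  returns to the donor mean ("shift to donor levels"); in non-responders'
  post samples it stays at the baseline mean ("persistence of baseline
  levels").
* **Planted correlation edges.** Designated (clinical, taxon, metabolite)
  node pairs share a per-sample latent factor with loading ``latent_loading``
  (a value in (0, 1)); each endpoint is ``loading * factor`` plus independent
  residual noise scaled so the marginal variance is unchanged, giving a pair
  correlation of ``loading**2`` on the latent scale and a monotone
  association detectable by Spearman correlation. Keeping marginal variances
  fixed prevents planted taxa from dominating the compositional closure and
  leaking spurious edges into the rest of the network. Baseline edges are
  realized in patient baseline samples, post edges in post samples; a
  configurable fraction of baseline edges recurs (same pair, same sign) in
  the post set, defining the ground-truth edge persistence.

Taxon abundances are generated as log-scale Gaussians and closed to relative
abundances last; metabolite concentrations are log-normal without closure,
matching an absolutely quantified LC-MS/MS panel. An optional dominance-skew
mode sharpens patient baseline (and non-responder post) compositions to
emulate dysbiotic communities with reduced richness and elevated Simpson
dominance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import (
    FeatureTable,
    SampleMetadata,
    ROLE_DONOR,
    ROLE_PATIENT,
    TIME_BASELINE,
    TIME_POST,
)
from .clinical_outcomes import (
    CDActivity,
    MayoScore,
    OutcomeRecord,
    cd_clinical_response,
    cd_remission,
    uc_clinical_response,
    uc_remission,
)

CLINICAL_MARKERS = ("CRP", "calprotectin", "disease_activity")

# latent-scale means for the clinical markers (log mg/dL, log ug/g, log score)
_CLINICAL_MU = {"CRP": 1.6, "calprotectin": 4.0, "disease_activity": 1.2}


@dataclass
class SynthConfig:
    """Study-condition parameters for one synthetic cohort.

    Defaults mirror the UC arm of the emulated study: 15 patients with an
    80% responder fraction (12 of 15), one fixed donor shared by all
    patients, and a baseline correlation network whose edges persist
    post-treatment at a 7% rate.
    """

    n_patients: int = 15
    responder_fraction: float = 0.8
    n_donor_samples: int = 16
    n_taxa: int = 40
    n_metabolites: int = 30
    n_response_taxa: int = 6
    n_response_metabolites: int = 6
    effect_size: float = 2.0
    n_planted_edges_baseline: int = 15
    n_planted_edges_post: int = 20
    planted_persistence_fraction: float = 0.07
    latent_loading: float = 0.92
    noise_sd: float = 1.0
    dysbiosis_skew: float = 0.0
    per_patient_donors: bool = False
    cohort: str = "UC"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.responder_fraction <= 1:
            raise ValueError("responder_fraction must be in [0, 1]")
        if not 0 <= self.planted_persistence_fraction <= 1:
            raise ValueError("planted_persistence_fraction must be in [0, 1]")
        if self.n_response_taxa > self.n_taxa:
            raise ValueError("n_response_taxa exceeds n_taxa")
        if self.n_response_metabolites > self.n_metabolites:
            raise ValueError("n_response_metabolites exceeds n_metabolites")
        for name in ("n_patients", "n_donor_samples", "n_taxa", "n_metabolites"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 < self.latent_loading < 1:
            raise ValueError("latent_loading must be in (0, 1)")
        if self.cohort not in ("UC", "CD"):
            raise ValueError("cohort must be 'UC' or 'CD'")
        # each planted edge needs two dedicated non-response nodes per context
        free_taxa = self.n_taxa - self.n_response_taxa
        free_mets = self.n_metabolites - self.n_response_metabolites
        pool = len(CLINICAL_MARKERS) + free_taxa + free_mets
        need = 2 * max(self.n_planted_edges_baseline, self.n_planted_edges_post)
        if need > pool:
            raise ValueError(
                f"requested planted edges need {need} nodes but only {pool} are available"
            )


@dataclass
class GroundTruth:
    """Planted-signal bookkeeping for recovery tests."""

    response_feature_ids: set[str]
    planted_edges_baseline: set[tuple[str, str]]
    planted_edges_post: set[tuple[str, str]]
    edge_signs_baseline: dict[tuple[str, str], int] = field(default_factory=dict)
    edge_signs_post: dict[tuple[str, str], int] = field(default_factory=dict)
    responder_ids: set[str] = field(default_factory=set)
    feature_directions: dict[str, str] = field(default_factory=dict)

    @property
    def realized_persistence_fraction(self) -> float:
        if not self.planted_edges_baseline:
            return float("nan")
        shared = self.planted_edges_baseline & self.planted_edges_post
        return len(shared) / len(self.planted_edges_baseline)

    def to_json(self, path) -> None:
        payload = {
            "response_feature_ids": sorted(self.response_feature_ids),
            "planted_edges_baseline": sorted(map(list, self.planted_edges_baseline)),
            "planted_edges_post": sorted(map(list, self.planted_edges_post)),
            "responder_ids": sorted(self.responder_ids),
            "feature_directions": self.feature_directions,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _edge_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def _build_metadata(cfg: SynthConfig, rng: np.random.Generator) -> SampleMetadata:
    rows = []
    if cfg.per_patient_donors:
        donor_of = {f"P{i + 1:02d}": f"donor_{i + 1:02d}" for i in range(cfg.n_patients)}
        donors = sorted(set(donor_of.values()))
        per = max(1, cfg.n_donor_samples // len(donors))
        k = 0
        for d in donors:
            for _ in range(per):
                k += 1
                rows.append((f"D{k:02d}", d, ROLE_DONOR, TIME_BASELINE, "NA", d))
    else:
        donor_of = {f"P{i + 1:02d}": "donor_01" for i in range(cfg.n_patients)}
        for k in range(cfg.n_donor_samples):
            rows.append((f"D{k + 1:02d}", "donor_01", ROLE_DONOR, TIME_BASELINE, "NA", "donor_01"))

    n_resp = int(round(cfg.responder_fraction * cfg.n_patients))
    patients = [f"P{i + 1:02d}" for i in range(cfg.n_patients)]
    responders = set(rng.choice(patients, size=n_resp, replace=False))
    for p in patients:
        lbl = "R" if p in responders else "NR"
        rows.append((f"{p}_B", p, ROLE_PATIENT, TIME_BASELINE, lbl, donor_of[p]))
        rows.append((f"{p}_F", p, ROLE_PATIENT, TIME_POST, lbl, donor_of[p]))
    df = pd.DataFrame(
        rows, columns=["sample_id", "subject_id", "role", "timepoint", "responder", "donor_id"]
    ).set_index("sample_id")
    return SampleMetadata(df)


def _plant_edges(
    cfg: SynthConfig,
    rng: np.random.Generator,
    taxa_pool: list[str],
    met_pool: list[str],
) -> tuple[list[tuple[str, str, int]], list[tuple[str, str, int]]]:
    """Choose baseline and post edge pairs with per-context disjoint endpoints.

    Within each context a node carries at most one planted edge, so each
    pairwise association is driven by a single latent factor and the expected
    correlation is ``latent_loading**2`` on the latent scale. Persisting
    edges copy the baseline pair identity and sign into the post set.
    """
    n_persist = int(round(cfg.planted_persistence_fraction * cfg.n_planted_edges_baseline))
    n_persist = min(n_persist, cfg.n_planted_edges_post)

    def sample_pairs(n_edges: int, forbidden: set[tuple[str, str]], used: set[str] = frozenset()):
        clin = [c for c in CLINICAL_MARKERS if c not in used]
        taxa = [t for t in taxa_pool if t not in used]
        mets = [m for m in met_pool if m not in used]
        rng.shuffle(taxa)
        rng.shuffle(mets)
        rng.shuffle(clin)

        def pop(pool, what):
            if not pool:
                raise ValueError(f"planted edge counts exceed available {what} nodes")
            return pool.pop()

        pairs = []
        # a few clinical-anchored edges (clinical nodes act as hubs across
        # contexts but carry one edge per context), remainder taxon-metabolite
        n_clin = min(len(clin), max(1, n_edges // 5)) if n_edges else 0
        for i in range(n_edges):
            if i < n_clin:
                a = pop(clin, "clinical")
                b = pop(taxa, "taxon") if i % 2 == 0 else pop(mets, "metabolite")
                b_pool, b_what = (taxa, "taxon") if i % 2 == 0 else (mets, "metabolite")
            else:
                a, b = pop(taxa, "taxon"), pop(mets, "metabolite")
                b_pool, b_what = mets, "metabolite"
            key = _edge_key(a, b)
            while key in forbidden:  # avoid re-planting a baseline pair as "new"
                b = pop(b_pool, b_what)
                key = _edge_key(a, b)
            sign = int(rng.choice([-1, 1]))
            pairs.append((key[0], key[1], sign))
        return pairs

    baseline = sample_pairs(cfg.n_planted_edges_baseline, set())
    persisting = [baseline[i] for i in rng.choice(
        len(baseline), size=n_persist, replace=False)] if n_persist else []
    base_keys = {_edge_key(a, b) for a, b, _ in baseline}
    # new post edges may not touch a persisting edge's endpoints (each node
    # carries one latent factor per context) nor re-plant a baseline pair
    persist_nodes = {n for a, b, _ in persisting for n in (a, b)}
    new_post = sample_pairs(cfg.n_planted_edges_post - n_persist, base_keys, persist_nodes)
    return baseline, persisting + new_post


def generate_cohort(
    config: SynthConfig,
) -> tuple[FeatureTable, FeatureTable, FeatureTable, SampleMetadata, GroundTruth]:
    """Generate one synthetic cohort.

    Returns ``(taxa, metabolites, clinical, metadata, ground_truth)`` where
    the three feature tables share the same sample index. Identical config
    and seed yield bit-identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    meta = _build_metadata(cfg, rng)

    taxa_ids = [f"taxon_{i + 1:03d}" for i in range(cfg.n_taxa)]
    met_ids = [f"met_{i + 1:03d}" for i in range(cfg.n_metabolites)]
    samples = meta.sample_ids
    n = len(samples)
    idx = {s: i for i, s in enumerate(samples)}

    baseline_rows = [idx[s] for s in meta.baseline_samples()]
    post_rows = [idx[s] for s in meta.post_samples()]
    resp_post_rows = [idx[s] for s in meta.post_samples("R")]
    nonresp_post_rows = [idx[s] for s in meta.post_samples("NR")]
    patient_base_rows = baseline_rows

    # log-scale community means: a spread of abundant-to-rare taxa
    mu_taxa = np.linspace(3.0, -3.0, cfg.n_taxa)
    mu_mets = np.linspace(3.5, 0.5, cfg.n_metabolites)
    mu_clin = np.array([_CLINICAL_MU[m] for m in CLINICAL_MARKERS])

    x_taxa = mu_taxa + rng.normal(scale=cfg.noise_sd, size=(n, cfg.n_taxa))
    x_mets = mu_mets + rng.normal(scale=cfg.noise_sd, size=(n, cfg.n_metabolites))
    x_clin = mu_clin + rng.normal(scale=0.5 * cfg.noise_sd, size=(n, len(CLINICAL_MARKERS)))

    # --- response features: shifted at baseline, restored in responders ---
    resp_taxa = list(rng.choice(cfg.n_taxa, size=cfg.n_response_taxa, replace=False))
    resp_mets = list(rng.choice(cfg.n_metabolites, size=cfg.n_response_metabolites, replace=False))
    directions: dict[str, str] = {}

    def apply_shift(x: np.ndarray, col: int, fid: str) -> None:
        sign = int(rng.choice([-1, 1]))
        directions[fid] = "enriched_baseline" if sign > 0 else "depleted_baseline"
        delta = sign * cfg.effect_size * cfg.noise_sd
        x[patient_base_rows, col] += delta
        x[nonresp_post_rows, col] += delta  # persistence of baseline levels

    for c in resp_taxa:
        apply_shift(x_taxa, c, taxa_ids[c])
    for c in resp_mets:
        apply_shift(x_mets, c, met_ids[c])

    # --- planted correlation edges via shared latent factors ---
    free_taxa = [taxa_ids[i] for i in range(cfg.n_taxa) if i not in set(resp_taxa)]
    free_mets = [met_ids[i] for i in range(cfg.n_metabolites) if i not in set(resp_mets)]
    base_edges, post_edges = _plant_edges(cfg, rng, free_taxa, free_mets)

    # (matrix, column, marginal mean, marginal sd) per node id; edge endpoints
    # are never response features, so the base mean applies
    col_of: dict[str, tuple[np.ndarray, int, float, float]] = {}
    for j, t in enumerate(taxa_ids):
        col_of[t] = (x_taxa, j, mu_taxa[j], cfg.noise_sd)
    for j, m in enumerate(met_ids):
        col_of[m] = (x_mets, j, mu_mets[j], cfg.noise_sd)
    for j, c in enumerate(CLINICAL_MARKERS):
        col_of[c] = (x_clin, j, mu_clin[j], 0.5 * cfg.noise_sd)

    def realize(edges, rows):
        rows = np.asarray(rows)
        ell = cfg.latent_loading
        resid = np.sqrt(1.0 - ell**2)
        for a, b, sign in edges:
            g = rng.normal(size=rows.size)
            for node, s in ((a, 1), (b, sign)):
                x, j, mu, sd = col_of[node]
                e = rng.normal(size=rows.size)
                x[rows, j] = mu + sd * (s * ell * g + resid * e)

    realize(base_edges, baseline_rows)
    realize(post_edges, post_rows)

    # --- dysbiosis dominance skew (patient baseline + non-responder post) ---
    if cfg.dysbiosis_skew > 0:
        skew_rows = np.asarray(patient_base_rows + nonresp_post_rows)
        x_taxa[skew_rows, :] *= 1.0 + cfg.dysbiosis_skew

    # --- closure / exponentiation ---
    logits = x_taxa - x_taxa.max(axis=1, keepdims=True)
    rel = np.exp(logits)
    rel /= rel.sum(axis=1, keepdims=True)

    taxa_tbl = FeatureTable(pd.DataFrame(rel, index=samples, columns=taxa_ids), "taxon")
    met_tbl = FeatureTable(pd.DataFrame(np.exp(x_mets), index=samples, columns=met_ids), "metabolite")
    clin_tbl = FeatureTable(
        pd.DataFrame(np.exp(x_clin), index=samples, columns=list(CLINICAL_MARKERS)), "clinical"
    )

    truth = GroundTruth(
        response_feature_ids={taxa_ids[c] for c in resp_taxa} | {met_ids[c] for c in resp_mets},
        planted_edges_baseline={_edge_key(a, b) for a, b, _ in base_edges},
        planted_edges_post={_edge_key(a, b) for a, b, _ in post_edges},
        edge_signs_baseline={_edge_key(a, b): s for a, b, s in base_edges},
        edge_signs_post={_edge_key(a, b): s for a, b, s in post_edges},
        responder_ids=meta.responder_ids(),
        feature_directions=directions,
    )
    return taxa_tbl, met_tbl, clin_tbl, meta, truth


# ---------------------------------------------------------------------------
# clinical score trajectories
# ---------------------------------------------------------------------------


@dataclass
class ScoreTrajectory:
    """Baseline / week-4 / week-14 activity scores for one patient."""

    patient_id: str
    cohort: str
    responder: bool
    baseline: MayoScore | CDActivity
    week4: MayoScore | CDActivity
    week14: MayoScore | CDActivity
    crp: tuple[float, float, float]  # baseline, w4, w14 (mg/dL)
    calprotectin: tuple[float, float, float]  # baseline, w4, w14 (ug/g)


def generate_trajectories(metadata: SampleMetadata, config: SynthConfig) -> list[ScoreTrajectory]:
    """Sample per-patient score trajectories consistent with responder labels.

    Responders satisfy the week-4 response definition of their cohort and
    reach week-14 clinical remission, with roughly two-thirds also reaching
    endoscopic remission; non-responders violate the response definition and
    show no marker decline.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    patients = sorted(
        set(metadata.table.loc[metadata.table["role"] == ROLE_PATIENT, "subject_id"])
    )
    labels = {
        p: metadata.table.loc[metadata.table["subject_id"] == p, "responder"].iloc[0]
        for p in patients
    }
    out = []
    for p in patients:
        resp = labels[p] == "R"
        crp0 = float(rng.uniform(5, 30))
        cal0 = float(rng.uniform(80, 900))
        if resp:
            crp = (crp0, crp0 * rng.uniform(0.2, 0.6), crp0 * rng.uniform(0.1, 0.5))
            cal = (cal0, cal0 * rng.uniform(0.1, 0.5), cal0 * rng.uniform(0.05, 0.4))
        else:
            crp = (crp0, crp0 * rng.uniform(0.9, 1.6), crp0 * rng.uniform(0.8, 1.5))
            cal = (cal0, cal0 * rng.uniform(0.9, 1.6), cal0 * rng.uniform(0.8, 1.5))
        if config.cohort == "UC":
            base = MayoScore(3, 2, 2, endoscopic=3)
            if resp:
                w4 = MayoScore(1, 1, 1, endoscopic=2)
                endo = 1 if rng.uniform() < 2 / 3 else 2
                w14 = MayoScore(1, 0, 1, endoscopic=endo)
            else:
                w4 = MayoScore(3, 2, 1, endoscopic=3)  # partial drop 1 < 2
                w14 = MayoScore(2, 2, 2, endoscopic=3)
        else:
            cdai0 = float(rng.uniform(280, 400))
            if resp:
                cdai4 = cdai0 - float(rng.uniform(110, 180))
                cdai14 = float(rng.uniform(90, 145))
                ses = float(rng.choice([1, 2]) if rng.uniform() < 2 / 3 else rng.choice([3, 4]))
            else:
                cdai4 = cdai0 - float(rng.uniform(0, 60))
                cdai14 = cdai0 - float(rng.uniform(0, 80))
                ses = float(rng.uniform(6, 12))
            base = CDActivity(cdai0, ses_cd=float(rng.uniform(8, 16)))
            w4 = CDActivity(cdai4)
            w14 = CDActivity(cdai14, ses_cd=ses)
        out.append(ScoreTrajectory(p, config.cohort, resp, base, w4, w14, crp, cal))
    return out


def generate_clinical_scores(metadata: SampleMetadata, config: SynthConfig) -> list[OutcomeRecord]:
    """Derive outcome records by applying the clinical classifiers to sampled
    trajectories, guaranteeing label/score consistency."""
    records = []
    for t in generate_trajectories(metadata, config):
        if config.cohort == "UC":
            r4 = uc_clinical_response(t.baseline, t.week4)
            rem, endo = uc_remission(t.week14)
        else:
            r4 = cd_clinical_response(t.baseline, t.week4)
            rem, endo = cd_remission(t.week14)
        records.append(
            OutcomeRecord(
                patient_id=t.patient_id,
                cohort=config.cohort,
                crp_w4=round(t.crp[1], 2),
                calpro_w4=round(t.calprotectin[1], 1),
                response_w4="R" if r4 else "NR",
                crp_w14=round(t.crp[2], 2),
                calpro_w14=round(t.calprotectin[2], 1),
                remission_w14="R" if rem else "NR",
                endo_remission_w14="R" if endo else "NR",
            )
        )
    return records


def write_cohort(outdir, taxa, mets, clin, meta, truth) -> None:
    """Serialize a generated cohort: TSV feature tables, CSV metadata, JSON truth."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    taxa.to_tsv(outdir / "taxa.tsv")
    mets.to_tsv(outdir / "metabolites.tsv")
    clin.to_tsv(outdir / "clinical.tsv")
    meta.to_csv(outdir / "metadata.csv")
    truth.to_json(outdir / "ground_truth.json")


def config_to_dict(config: SynthConfig) -> dict:
    return asdict(config)
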