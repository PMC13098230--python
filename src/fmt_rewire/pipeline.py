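"""End-to-end pipeline: simulate -> outcomes -> diversity -> screen -> networks.

One :class:`RunConfig` drives a reproducible run; every stage writes its
outputs under the run directory and the whole run is summarized in a JSON
report plus a manifest (inputs, seed, thresholds, version). Thresholds
default to the conventional values used throughout the package: alpha 0.05,
|rho| > 0.6, prevalence >= 60%, VIP > 0.9.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .clinical_outcomes import read_outcomes_csv, summarize_outcomes
from .containers import FeatureTable, SampleMetadata
from .diversity import diversity_table, relative_to_counts
from .networks import build_network, count_class_pairs, edge_persistence, export_network
from .screening import screen_response_features
from .synthetic_cohort import (
    SynthConfig,
    generate_clinical_scores,
    generate_cohort,
    write_cohort,
)
from .clinical_outcomes import write_outcomes_csv

log = logging.getLogger("fmt_rewire")


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str = "fmt_rewire_run"
    seed: int = 0
    synth: SynthConfig | None = None
    taxa_path: str | None = None
    metabolites_path: str | None = None
    clinical_path: str | None = None
    metadata_path: str | None = None
    outcomes_path: str | None = None
    cohort: str = "UC"
    alpha: float = 0.05
    rho_threshold: float = 0.6
    min_prevalence: float = 0.6
    vip_threshold: float = 0.9
    library_size: int = 50_000
    post_responders_only: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth = raw.pop("synth", None)
        cfg = cls(**raw)
        if synth is not None:
            cfg.synth = SynthConfig(**synth)
        return cfg


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run report (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed}

    # --- inputs -----------------------------------------------------------
    stage = "inputs"
    try:
        if config.synth is not None:
            synth = config.synth
            taxa, mets, clin, meta, truth = generate_cohort(synth)
            write_cohort(outdir / "cohort", taxa, mets, clin, meta, truth)
            records = generate_clinical_scores(meta, synth)
            write_outcomes_csv(records, outdir / "cohort" / "outcomes.csv")
            log.info("simulate: %d samples, %d taxa, %d metabolites",
                     len(meta.sample_ids), taxa.n_features, mets.n_features)
        else:
            taxa = FeatureTable.from_tsv(config.taxa_path, "taxon")
            mets = FeatureTable.from_tsv(config.metabolites_path, "metabolite")
            clin = FeatureTable.from_tsv(config.clinical_path, "clinical")
            meta = SampleMetadata.from_csv(config.metadata_path)
            records = read_outcomes_csv(config.outcomes_path) if config.outcomes_path else []
            truth = None
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- outcomes ---------------------------------------------------------
    stage = "outcomes"
    try:
        report["outcomes"] = (
            summarize_outcomes(records, config.cohort) if records else None
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- diversity --------------------------------------------------------
    stage = "diversity"
    try:
        counts = relative_to_counts(taxa, config.library_size)
        div = diversity_table(counts)
        div.to_csv(outdir / "diversity.csv", index_label="sample_id")
        groups = {
            "donor": meta.donor_samples(),
            "baseline": meta.baseline_samples(),
            "post": meta.post_samples(),
        }
        report["diversity"] = {
            g: div.loc[ids].mean().round(4).to_dict() for g, ids in groups.items() if ids
        }
        log.info("diversity: %d samples summarized", len(div))
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- screening --------------------------------------------------------
    stage = "screen"
    try:
        selected: dict[str, list[str]] = {}
        for tbl, name in ((taxa, "taxa"), (mets, "metabolites")):
            res = screen_response_features(tbl, meta, alpha=config.alpha)
            res.to_tsv(outdir / f"screen_{name}.tsv")
            selected[name] = res.selected_ids
            log.info("screen %s: %d/%d selected", name, len(res.selected_ids), tbl.n_features)
        report["selected_features"] = selected
        if truth is not None:
            picked = set(selected["taxa"]) | set(selected["metabolites"])
            tp = picked & truth.response_feature_ids
            report["screen_recovery"] = {
                "sensitivity": len(tp) / max(1, len(truth.response_feature_ids)),
                "n_false_positive": len(picked - truth.response_feature_ids),
            }
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- networks + persistence ------------------------------------------
    stage = "network"
    try:
        base_samples = meta.baseline_samples()
        post_samples = (
            meta.post_samples("R") if config.post_responders_only else meta.post_samples()
        )
        kw = dict(
            rho_threshold=config.rho_threshold,
            alpha=config.alpha,
            min_prevalence=config.min_prevalence,
            cohort=config.cohort,
        )
        net_base = build_network([clin, taxa, mets], base_samples, context="baseline", **kw)
        net_post = build_network([clin, taxa, mets], post_samples, context="post", **kw)
        export_network(net_base, outdir / "net_baseline.graphml")
        export_network(net_post, outdir / "net_post.graphml")
        persistence = edge_persistence(net_base, net_post)
        report["network"] = {
            "baseline_census": count_class_pairs(net_base),
            "post_census": count_class_pairs(net_post),
            "persistence_fraction": persistence.fraction,
            "n_persisting": len(persistence.persisting),
        }
        log.info(
            "network: baseline %d edges, post %d edges, persistence %.3f",
            net_base.graph.number_of_edges(),
            net_post.graph.number_of_edges(),
            persistence.fraction,
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- manifest + report -----------------------------------------------
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            k: (asdict(v) if isinstance(v, SynthConfig) else v)
            for k, v in asdict(config).items()
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    with open(outdir / "report.txt", "w") as fh:
        fh.write(_render_report(report))
    return report


def _render_report(report: dict) -> str:
    lines = [f"fmt-rewire v{report['version']} (seed {report['seed']})", ""]
    if report.get("outcomes"):
        o = report["outcomes"]
        lines += [
            "Clinical outcomes:",
            f"  week-4 response: {o['response_w4']}/{o['total']}",
            f"  week-14 remission: {o['remission_w14']}/{o['total']}",
            f"  week-14 endoscopic remission: {o['endoscopic_remission_w14']}/{o['total']}",
            "",
        ]
    if report.get("selected_features"):
        s = report["selected_features"]
        lines.append(
            f"Response-associated features: {len(s['taxa'])} taxa, "
            f"{len(s['metabolites'])} metabolites"
        )
    if report.get("network"):
        nw = report["network"]
        lines += [
            f"Network edges: baseline {nw['baseline_census']['total']} "
            f"({nw['baseline_census']['total_after_exclusion']} non-metabolite-metabolite), "
            f"post {nw['post_census']['total']} "
            f"({nw['post_census']['total_after_exclusion']})",
            f"Edge persistence: {nw['persistence_fraction']:.3f} "
            f"({nw['n_persisting']} persisting)",
        ]
    return "\n".join(lines) + "\n"
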