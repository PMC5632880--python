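"""End-to-end orchestration: simulate -> DE -> qPCR -> classify -> enrich.

Mirrors the study workflow on synthetic data: sequence pooled mitochondrial
and whole-tissue libraries per condition, call differential expression in
the mitochondrial fraction between condition pairs, validate up-called
candidates by qPCR in both compartments, classify mitochondria-enriched
miRNAs by the cross-compartment rule, and test the enriched set's targets
for pathway enrichment. Every stage writes its artifact through
:mod:`mitomir.io`; a manifest lists everything written.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as mio
from .classify import classify_batch
from .de import cpm_normalize, hierarchical_cluster, pairwise_profile
from .enrich import enrich_mirnas
from .qpcr import qpcr_fold_changes
from .simulate import SimulationConfig, simulate_annotation, simulate_counts, simulate_qpcr

__all__ = ["PipelineConfig", "run_all", "recovery_metrics"]

DEFAULT_PAIRS = [("sham", "tac4w"), ("sham", "tac8w"), ("tac4w", "tac8w")]


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, with the package defaults."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    ct_noise_sd: float = 0.1
    min_count: int = 1
    pseudo_cpm: float = 0.5
    fc_up: float = 2.0
    fc_down: float = 0.5
    alpha: float = 0.05
    use_q: bool = False
    unchanged_tolerance: float = 0.2
    score_threshold: float = 0.9
    verbosity: str = "info"

    def __post_init__(self) -> None:
        if not (0 < self.fc_down < 1 < self.fc_up):
            raise ValueError("thresholds must satisfy 0 < fc_down < 1 < fc_up")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_count < 0 or self.pseudo_cpm < 0 or self.ct_noise_sd < 0:
            raise ValueError("min_count, pseudo_cpm and ct_noise_sd must be >= 0")
        if not 0 <= self.score_threshold <= 1:
            raise ValueError("score_threshold must lie in [0, 1]")

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        payload = dict(payload)
        sim_payload = payload.pop("simulation", {})
        known_sim = set(SimulationConfig.__dataclass_fields__)
        unknown = set(sim_payload) - known_sim
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        known = set(cls.__dataclass_fields__) - {"simulation"}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim_payload = dict(sim_payload)
        for key in ("conditions", "mitomir_indices", "mito_log2_effect", "total_log2_effect"):
            if key in sim_payload and isinstance(sim_payload[key], list):
                sim_payload[key] = tuple(sim_payload[key])
        return cls(simulation=SimulationConfig(**sim_payload), **payload)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        if not isinstance(payload, dict):
            raise ValueError(f"{path}: config root must be a mapping")
        return cls.from_dict(payload)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _manifest(config: PipelineConfig, artifacts: dict[str, dict]) -> dict:
    return {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.simulation.seed,
        "artifacts": artifacts,
    }


def run_all(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the full pipeline into ``out_dir``; returns a summary dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, dict] = {}

    def record(name: str, path: Path, rows: int) -> None:
        artifacts[name] = {"path": path.name, "rows": int(rows)}

    # --- simulate -----------------------------------------------------
    table, truth = simulate_counts(config.simulation)
    target_map, pathway_map, planted_pathway = simulate_annotation(config.simulation)
    truth.planted_pathway_id = planted_pathway
    mio.write_count_table(table, out / "counts.tsv", out / "libraries.tsv")
    mio.write_target_map(target_map, out / "targets.tsv")
    mio.write_gmt(pathway_map, out / "pathways.gmt")
    mio.write_ground_truth(truth, out / "ground_truth.json")
    record("counts", out / "counts.tsv", table.n_mirnas)
    record("libraries", out / "libraries.tsv", len(table.libraries))
    record("targets", out / "targets.tsv", len(target_map))
    record("pathways", out / "pathways.gmt", len(pathway_map.gene_sets))

    # --- differential expression (mitochondrial fraction) -------------
    de_tables = pairwise_profile(
        table, DEFAULT_PAIRS, compartment="mitochondrial",
        min_count=config.min_count, pseudo_cpm=config.pseudo_cpm,
        fc_up=config.fc_up, fc_down=config.fc_down,
        alpha=config.alpha, use_q=config.use_q,
    )
    for (c1, c2), frame in de_tables.items():
        path = out / f"de_{c1}_vs_{c2}.tsv"
        mio.write_table(frame, path)
        record(f"de_{c1}_vs_{c2}", path, len(frame))

    # heatmap matrix in clustered leaf order (log CPM, detected rows)
    cpm = cpm_normalize(table)
    detected = table.counts.max(axis=1) >= max(config.min_count, 1)
    log_cpm = np.log2(cpm.to_numpy()[detected] + config.pseudo_cpm)
    order, _ = hierarchical_cluster(log_cpm)
    heat = cpm.loc[detected].iloc[order]
    mio.write_table(np.log2(heat + config.pseudo_cpm), out / "heatmap.tsv", index=True)
    record("heatmap", out / "heatmap.tsv", len(heat))

    # --- qPCR validation of early-stage candidates ---------------------
    early = de_tables[("sham", "tac4w")]
    candidates = sorted(early.loc[early["call"] == "up", "mirna"])
    summary: dict = {
        "n_candidates": len(candidates),
        "de_counts": {
            f"{c1}_vs_{c2}": frame["call"].value_counts().to_dict()
            for (c1, c2), frame in de_tables.items()
        },
    }
    if candidates:
        ct = simulate_qpcr(config.simulation, truth, candidates, config.ct_noise_sd)
        mio.write_ct_csv(ct, out / "ct.csv")
        record("ct", out / "ct.csv", len(ct))
        qpcr_total = qpcr_fold_changes(ct, "tac4w", "sham", compartment="total")
        qpcr_mito = qpcr_fold_changes(ct, "tac4w", "sham", compartment="mitochondrial")
        mio.write_table(qpcr_total, out / "qpcr_total.tsv")
        mio.write_table(qpcr_mito, out / "qpcr_mitochondrial.tsv")
        record("qpcr_total", out / "qpcr_total.tsv", len(qpcr_total))
        record("qpcr_mitochondrial", out / "qpcr_mitochondrial.tsv", len(qpcr_mito))

        calls = classify_batch(
            early, qpcr_total, candidates, qpcr_mito=qpcr_mito,
            fc_up=config.fc_up, alpha=config.alpha,
            unchanged_tolerance=config.unchanged_tolerance,
        )
        mio.write_table(calls, out / "mitomir_calls.tsv")
        record("mitomir_calls", out / "mitomir_calls.tsv", len(calls))
        enriched = sorted(calls.loc[calls["classification"] == "enriched", "mirna"])
        summary["n_enriched"] = len(enriched)

        if enriched:
            report = enrich_mirnas(
                enriched, target_map, pathway_map,
                score_threshold=config.score_threshold, alpha=config.alpha,
            )
            mio.write_table(report, out / "enrichment.tsv")
            record("enrichment", out / "enrichment.tsv", len(report))
            summary["top_pathway"] = str(report.iloc[0]["pathway_id"])
            summary["planted_pathway"] = planted_pathway
        summary.update(recovery_metrics(calls, truth))

    manifest = _manifest(config, artifacts)
    manifest["summary"] = summary
    mio.write_json(manifest, out / "manifest.json")
    return manifest


def recovery_metrics(calls: pd.DataFrame, truth) -> dict:
    """Sensitivity / false-positive rate of enriched calls vs ground truth.

    Candidates never entering the call table count as negative calls; the
    FPR denominator is all simulated non-planted miRNAs.
    """
    planted = set(truth.mitomir_ids())
    enriched = set(calls.loc[calls["classification"] == "enriched", "mirna"])
    n_nonplanted = len(truth.mirna_ids) - len(planted)
    tp = len(enriched & planted)
    fp = len(enriched - planted)
    return {
        "sensitivity": tp / len(planted) if planted else float("nan"),
        "false_positive_rate": fp / n_nonplanted if n_nonplanted else float("nan"),
    }
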