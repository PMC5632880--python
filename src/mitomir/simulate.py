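"""Synthetic compartment-fractionation small-RNA data with known ground truth.

The generator emulates the study design of pooled-library mitomiR profiling
in pressure-overload heart failure: one pooled sequencing library per
(compartment, condition) group — compartments are the purified mitochondrial
fraction and whole-tissue ("total") RNA; conditions are sham and two
post-surgery stages — with a subset of miRNAs planted as
mitochondria-enriched. The mitochondrial fraction is contaminated by a
configurable share of cytosolic (whole-tissue) RNA, because RNase treatment
of isolated mitochondria never removes co-purifying cytosolic RNA entirely.

Counts are Poisson around pool-proportional means (optionally
negative-binomial for overdispersion stress tests); qPCR Ct triplicates and
toy target/pathway annotations with a planted enriched pathway are generated
from the same ground truth, so the full pipeline can be exercised and scored
against known answers without external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .de import CountTable, CONDITIONS

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_counts",
    "simulate_qpcr",
    "simulate_annotation",
]

# Stream offsets so counts, qPCR and annotation draws are independent
# substreams of the one config seed.
_COUNT_STREAM, _QPCR_STREAM, _ANNOTATION_STREAM = 11, 13, 17

# Ct model intercept: Ct for a transcript at relative abundance 1. With the
# default log-normal baselines, targets land in the mid-20s and the
# reference in the mid-teens, matching routine stem-loop qPCR ranges.
CT_INTERCEPT = 8.0
REFERENCE_ABUNDANCE = 0.01
REFERENCE_ID = "U6"


class SimulationValidationError(ValueError):
    """A simulation parameter is non-finite or out of range."""


@dataclass
class SimulationConfig:
    """Parameters of the compartment-fractionation count simulator.

    Defaults describe the study conditions the package targets: 300 known
    cardiac miRNAs, pooled libraries of 2 million miRNA-assigned reads, 20
    planted mitochondria-enriched miRNAs with a strong early (8-fold) and a
    weaker late (2-fold) mitochondrial effect, no change in whole tissue,
    and 20% cytosolic contamination of the mitochondrial fraction.
    """

    n_mirnas: int = 300
    library_size_per_group: int = 2_000_000
    conditions: tuple[str, ...] = CONDITIONS
    mitomir_indices: tuple[int, ...] = tuple(range(20))
    mito_log2_effect: tuple[float, ...] = (3.0, 1.0)
    total_log2_effect: tuple[float, ...] = (0.0, 0.0)
    contamination_fraction: float = 0.2
    dispersion: float = 0.0
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirnas <= 0:
            raise SimulationValidationError("n_mirnas must be positive")
        if self.library_size_per_group <= 0:
            raise SimulationValidationError("library_size_per_group must be positive")
        if len(self.conditions) < 2:
            raise SimulationValidationError("need a reference plus >= 1 condition")
        n_eff = len(self.conditions) - 1
        if len(self.mito_log2_effect) != n_eff or len(self.total_log2_effect) != n_eff:
            raise SimulationValidationError(
                "effect vectors must have one entry per non-reference condition"
            )
        # phi = 1 is the degenerate full-contamination limit (the fraction
        # is pure cytosol); it stays valid so the limit is testable.
        if not (0.0 <= self.contamination_fraction <= 1.0):
            raise SimulationValidationError(
                "contamination_fraction must lie in [0, 1]"
            )
        if self.dispersion < 0 or not np.isfinite(self.dispersion):
            raise SimulationValidationError("dispersion must be finite and >= 0")
        for name in ("baseline_log_mean", "baseline_log_sd"):
            if not np.isfinite(getattr(self, name)):
                raise SimulationValidationError(f"{name} must be finite")
        if self.baseline_log_sd < 0:
            raise SimulationValidationError("baseline_log_sd must be >= 0")
        bad = [i for i in self.mitomir_indices if not 0 <= i < self.n_mirnas]
        if bad:
            raise SimulationValidationError(
                f"mitomir_indices out of range [0, {self.n_mirnas}): {bad}"
            )
        if len(set(self.mitomir_indices)) != len(self.mitomir_indices):
            raise SimulationValidationError("duplicate mitomir_indices")
        if not all(np.isfinite(self.mito_log2_effect)) or not all(
            np.isfinite(self.total_log2_effect)
        ):
            raise SimulationValidationError("effect sizes must be finite")

    def mirna_ids(self) -> list[str]:
        return [f"mmu-miR-sim{i:04d}" for i in range(self.n_mirnas)]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """True pool compositions and planted effects behind a simulation.

    ``pool_abundance[(compartment, condition)]`` holds the relative
    abundance vector of the *pure* pool (each sums to 1);
    ``measured_abundance`` holds what a probe of the physical fraction sees
    — for the mitochondrial fraction this is the contaminated mixture.
    """

    mirna_ids: list[str]
    is_mitomir: np.ndarray
    pool_abundance: dict[tuple[str, str], np.ndarray]
    measured_abundance: dict[tuple[str, str], np.ndarray]
    planted_pathway_id: str | None = None

    def mitomir_ids(self) -> list[str]:
        return [m for m, f in zip(self.mirna_ids, self.is_mitomir) if f]

    def to_json(self) -> str:
        payload = {
            "mirna_ids": self.mirna_ids,
            "is_mitomir": self.is_mitomir.astype(int).tolist(),
            "pool_abundance": {
                f"{comp}|{cond}": vec.tolist()
                for (comp, cond), vec in self.pool_abundance.items()
            },
            "measured_abundance": {
                f"{comp}|{cond}": vec.tolist()
                for (comp, cond), vec in self.measured_abundance.items()
            },
            "planted_pathway_id": self.planted_pathway_id,
        }
        return json.dumps(payload, indent=1)


def _pool_abundances(config: SimulationConfig) -> GroundTruth:
    rng = np.random.default_rng([config.seed, _COUNT_STREAM])
    baseline = rng.lognormal(
        config.baseline_log_mean, config.baseline_log_sd, config.n_mirnas
    )
    planted = np.zeros(config.n_mirnas, dtype=bool)
    planted[list(config.mitomir_indices)] = True

    phi = config.contamination_fraction
    pools: dict[tuple[str, str], np.ndarray] = {}
    measured: dict[tuple[str, str], np.ndarray] = {}
    for j, cond in enumerate(config.conditions):
        mito_w = baseline.copy()
        total_w = baseline.copy()
        if j > 0:
            mito_w[planted] *= 2.0 ** config.mito_log2_effect[j - 1]
            total_w[planted] *= 2.0 ** config.total_log2_effect[j - 1]
        mito_pool = mito_w / mito_w.sum()
        total_pool = total_w / total_w.sum()
        pools[("mitochondrial", cond)] = mito_pool
        pools[("total", cond)] = total_pool
        measured[("mitochondrial", cond)] = (1 - phi) * mito_pool + phi * total_pool
        measured[("total", cond)] = total_pool
    return GroundTruth(
        mirna_ids=config.mirna_ids(),
        is_mitomir=planted,
        pool_abundance=pools,
        measured_abundance=measured,
    )


def expected_cpm(config: SimulationConfig, truth: GroundTruth) -> pd.DataFrame:
    """Expected CPM per library implied by the ground truth (no sampling)."""
    cols = {}
    for comp in ("mitochondrial", "total"):
        for cond in config.conditions:
            cols[f"{comp[:4]}_{cond}"] = truth.measured_abundance[(comp, cond)] * 1e6
    return pd.DataFrame(cols, index=pd.Index(truth.mirna_ids, name="mirna"))


def _draw_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    if dispersion == 0:
        return rng.poisson(mean)
    # gamma-Poisson mixture: variance = m + dispersion * m^2
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_counts(config: SimulationConfig) -> tuple[CountTable, GroundTruth]:
    """Draw one count library per (compartment, condition) group.

    The mitochondrial library's expected composition is the contaminated
    mixture ``(1 - phi) * mito_pool + phi * total_pool``; expected counts are
    ``library_size * composition``. Identical config (including seed) gives
    bit-identical output.
    """
    truth = _pool_abundances(config)
    rng = np.random.default_rng([config.seed, _COUNT_STREAM, 1])
    records = []
    columns = []
    for comp in ("mitochondrial", "total"):
        for cond in config.conditions:
            mean = truth.measured_abundance[(comp, cond)] * config.library_size_per_group
            counts = _draw_counts(rng, mean, config.dispersion)
            columns.append(counts)
            records.append(
                {
                    "library_id": f"{comp[:4]}_{cond}",
                    "compartment": comp,
                    "condition": cond,
                    "library_size": max(config.library_size_per_group, int(counts.sum())),
                }
            )
    table = CountTable(
        mirna_ids=truth.mirna_ids,
        libraries=pd.DataFrame(records),
        counts=np.column_stack(columns),
    )
    return table, truth


def simulate_qpcr(
    config: SimulationConfig,
    truth: GroundTruth,
    selected: list[str],
    ct_noise_sd: float = 0.1,
    compartments: tuple[str, ...] = ("mitochondrial", "total"),
) -> pd.DataFrame:
    """Triplicate stem-loop qPCR Ct values for selected miRNAs.

    Ct follows the perfect-efficiency model ``Ct = C0 - log2(abundance)``
    plus Gaussian replicate noise; the measured abundance of the
    mitochondrial fraction includes cytosolic contamination, exactly as the
    sequencing libraries do. A U6-style reference record with abundance held
    constant across conditions and compartments is emitted per group.
    """
    if not selected:
        raise SimulationValidationError("selection must not be empty")
    if ct_noise_sd < 0 or not np.isfinite(ct_noise_sd):
        raise SimulationValidationError("ct_noise_sd must be finite and >= 0")
    id_to_idx = {m: i for i, m in enumerate(truth.mirna_ids)}
    unknown = [m for m in selected if m not in id_to_idx]
    if unknown:
        raise SimulationValidationError(f"selected miRNAs not simulated: {unknown}")

    rng = np.random.default_rng([config.seed, _QPCR_STREAM])
    rows = []
    for comp in compartments:
        for cond in config.conditions:
            abundance = truth.measured_abundance[(comp, cond)]
            for mirna in selected:
                true_ct = CT_INTERCEPT - np.log2(abundance[id_to_idx[mirna]])
                for rep in range(1, 4):
                    ct = true_ct + rng.normal(0.0, ct_noise_sd)
                    rows.append((mirna, comp, cond, rep, float(ct), False))
            ref_ct = CT_INTERCEPT - np.log2(REFERENCE_ABUNDANCE)
            for rep in range(1, 4):
                ct = ref_ct + rng.normal(0.0, ct_noise_sd)
                rows.append((REFERENCE_ID, comp, cond, rep, float(ct), True))
    return pd.DataFrame(
        rows,
        columns=["mirna", "compartment", "condition", "replicate", "ct", "is_reference"],
    )


def simulate_annotation(
    config: SimulationConfig,
    n_genes: int = 2000,
    n_pathways: int = 40,
    pathway_size: int = 40,
    targets_per_mirna: int = 25,
    decoys_per_mirna: int = 10,
    in_pathway_fraction: float = 0.8,
) -> tuple[pd.DataFrame, "object", str]:
    """Toy target map and pathway collection with one planted pathway.

    Every miRNA receives ``targets_per_mirna`` high-confidence target edges
    (score above the conventional 0.9 cutoff) plus low-score decoy edges.
    Planted mitomiRs draw ``in_pathway_fraction`` of their targets from the
    planted pathway's gene set; all other targets are uniform over the gene
    universe. ``in_pathway_fraction = 0`` produces a decoy-only map with no
    real signal.

    Returns ``(target_map, pathway_map, planted_pathway_id)``.
    """
    from .enrich import PathwayMap

    if n_genes < pathway_size:
        raise SimulationValidationError("n_genes must cover the largest pathway")
    if not 0.0 <= in_pathway_fraction <= 1.0:
        raise SimulationValidationError("in_pathway_fraction must lie in [0, 1]")
    rng = np.random.default_rng([config.seed, _ANNOTATION_STREAM])
    genes = np.array([f"gene{i:05d}" for i in range(n_genes)])
    pathway_ids = [f"path{i:03d}" for i in range(n_pathways)]
    gene_sets = {
        pid: set(rng.choice(genes, size=pathway_size, replace=False))
        for pid in pathway_ids
    }
    planted_id = pathway_ids[0]
    planted_genes = np.array(sorted(gene_sets[planted_id]))

    mitomir_set = set(config.mitomir_indices)
    edges: dict[tuple[str, str], float] = {}
    for i, mirna in enumerate(config.mirna_ids()):
        n_in = (
            int(round(in_pathway_fraction * targets_per_mirna))
            if i in mitomir_set
            else 0
        )
        chosen: list[str] = list(
            rng.choice(planted_genes, size=min(n_in, planted_genes.size), replace=False)
        )
        pool = np.setdiff1d(genes, np.array(chosen, dtype=genes.dtype))
        chosen += list(
            rng.choice(pool, size=targets_per_mirna - len(chosen), replace=False)
        )
        for g in chosen:
            edges[(mirna, g)] = float(rng.uniform(0.905, 1.0))
        decoy_pool = np.setdiff1d(genes, np.array(chosen, dtype=genes.dtype))
        for g in rng.choice(decoy_pool, size=decoys_per_mirna, replace=False):
            edges[(mirna, g)] = float(rng.uniform(0.05, 0.9))

    target_map = pd.DataFrame(
        [(m, g, s) for (m, g), s in edges.items()],
        columns=["mirna", "gene", "score"],
    )
    pathway_map = PathwayMap(
        gene_sets=gene_sets,
        names={pid: f"synthetic pathway {pid}" for pid in pathway_ids},
        universe=set(genes),
    )
    return target_map, pathway_map, planted_id
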