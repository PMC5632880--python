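"""Hypergeometric pathway enrichment of miRNA target sets.

Given a scored miRNA-target map, targets above the confidence cutoff
(microT-style score > 0.9) for a miRNA list are pooled into one union gene
set and each pathway is tested with the one-sided hypergeometric upper tail
against a gene universe, followed by BH adjustment across pathways. Each
pathway's report carries the number of input miRNAs contributing at least
one target ("miRNA hits") and the number of distinct target genes in the
pathway ("target hits").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom

from .de import bh_fdr

__all__ = [
    "PathwayMap",
    "collect_targets",
    "hypergeom_enrich",
    "enrichment_report",
    "enrich_mirnas",
]

DEFAULT_SCORE_THRESHOLD = 0.9


@dataclass
class PathwayMap:
    """Pathway gene sets plus the background gene universe."""

    gene_sets: dict[str, set[str]]
    names: dict[str, str] = field(default_factory=dict)
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set().union(*self.gene_sets.values()) if self.gene_sets else set()
        stray = {
            pid: sorted(genes - self.universe)[:3]
            for pid, genes in self.gene_sets.items()
            if genes - self.universe
        }
        if stray:
            raise ValueError(f"pathway genes outside the universe: {stray}")

    def name(self, pathway_id: str) -> str:
        return self.names.get(pathway_id, pathway_id)


def collect_targets(
    mirnas: list[str],
    target_map: pd.DataFrame,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> tuple[set[str], dict[str, set[str]]]:
    """Union target-gene set over a miRNA list at a strict score cutoff.

    Only edges with score strictly greater than the threshold count. Returns
    the union set and the per-miRNA sets (needed for miRNA hit counts).
    miRNAs absent from the map contribute an empty set with a warning.
    """
    if not mirnas:
        raise ValueError("miRNA list must not be empty")
    kept = target_map[target_map["score"] > score_threshold]
    by_mirna = {m: set(g["gene"]) for m, g in kept.groupby("mirna")}
    per_mirna: dict[str, set[str]] = {}
    for m in mirnas:
        if m not in set(target_map["mirna"]):
            warnings.warn(f"miRNA {m} absent from the target map", UserWarning,
                          stacklevel=2)
        per_mirna[m] = by_mirna.get(m, set())
    union = set().union(*per_mirna.values()) if per_mirna else set()
    return union, per_mirna


def hypergeom_enrich(
    targets: set[str],
    pathways: PathwayMap,
    per_mirna: dict[str, set[str]] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric test of the target set against each pathway.

    With universe size M, pathway size K, target-set size n and overlap k,
    p = P(X >= k) for X ~ Hypergeom(M, K, n). Target genes outside the
    universe are dropped with a warning. BH-adjusted q-values and a
    significance flag at q < alpha are attached.
    """
    if not pathways.universe:
        raise ValueError("empty gene universe")
    stray = targets - pathways.universe
    if stray:
        warnings.warn(
            f"{len(stray)} target genes outside the universe dropped",
            UserWarning,
            stacklevel=2,
        )
    targets = targets & pathways.universe
    m_univ = len(pathways.universe)
    n_draw = len(targets)

    rows = []
    for pid in sorted(pathways.gene_sets):
        genes = pathways.gene_sets[pid]
        overlap = targets & genes
        k = len(overlap)
        # sf(k-1) = P(X >= k); k = 0 gives the full tail = 1
        p = float(hypergeom.sf(k - 1, m_univ, len(genes), n_draw))
        p = min(max(p, 0.0), 1.0)
        n_mirnas_hit = (
            sum(1 for s in per_mirna.values() if s & genes) if per_mirna else 0
        )
        rows.append(
            {
                "pathway_id": pid,
                "name": pathways.name(pid),
                "p_value": p,
                "n_mirnas_hit": n_mirnas_hit,
                "n_targets_hit": k,
            }
        )
    frame = pd.DataFrame(rows)
    frame["q_value"] = bh_fdr(frame["p_value"].to_numpy())
    frame["significant"] = frame["q_value"] < alpha
    return frame[
        ["pathway_id", "name", "p_value", "q_value",
         "n_mirnas_hit", "n_targets_hit", "significant"]
    ]


def enrichment_report(results: pd.DataFrame, top_n: int | None = None) -> pd.DataFrame:
    """Rank pathways by ascending p, ties broken by pathway id."""
    ranked = results.sort_values(
        ["p_value", "pathway_id"], kind="mergesort"
    ).reset_index(drop=True)
    if top_n is not None:
        ranked = ranked.head(top_n)
    return ranked


def enrich_mirnas(
    mirnas: list[str],
    target_map: pd.DataFrame,
    pathways: PathwayMap,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    alpha: float = 0.05,
    top_n: int | None = None,
) -> pd.DataFrame:
    """collect_targets -> hypergeom_enrich -> ranked report, in one call."""
    targets, per_mirna = collect_targets(mirnas, target_map, score_threshold)
    results = hypergeom_enrich(targets, pathways, per_mirna=per_mirna, alpha=alpha)
    return enrichment_report(results, top_n=top_n)
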