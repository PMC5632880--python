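"""Cross-compartment mitomiR calling.

A miRNA counts as mitochondria-enriched in failing hearts when its level
rises in the mitochondrial fraction (fold > 2 with significance where a
p-value exists) while staying flat or falling in whole-tissue RNA. The
second clause separates genuine mitochondrial enrichment from cytosolic
upregulation leaking into the fraction through contamination.

The rule is a pure function of (mito_fold, mito_p, total_fold, thresholds);
"unchanged" is operationalized as total fold <= 1 + tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import isnan

import numpy as np
import pandas as pd

__all__ = ["MitomirCall", "classify_mitomir", "classify_batch"]

ENRICHED = "enriched"
NOT_ENRICHED = "not_enriched"
INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class MitomirCall:
    mirna_id: str
    mito_fold: float | None
    mito_p: float | None
    total_fold: float | None
    classification: str
    rationale: str


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and isnan(x))


def classify_mitomir(
    mito_fold: float | None,
    mito_p: float | None,
    total_fold: float | None,
    mirna_id: str = "",
    fc_up: float = 2.0,
    alpha: float = 0.05,
    unchanged_tolerance: float = 0.2,
) -> MitomirCall:
    """Classify one miRNA as enriched / not_enriched / indeterminate.

    enriched      : mito_fold > fc_up, significant where mito_p is present,
                    and total_fold <= 1 + unchanged_tolerance ("decreased or
                    unchanged" in whole tissue).
    not_enriched  : all inputs present but the rule fails — either the
                    mitochondrial rise is absent/insignificant, or the miRNA
                    rises in both compartments.
    indeterminate : a required input (mito_fold or total_fold) is missing;
                    a missing mito_p alone is tolerated (qPCR evidence
                    without a sequencing p-value).
    """
    if fc_up <= 1 or not 0 < alpha < 1 or unchanged_tolerance < 0:
        raise ValueError("invalid thresholds")
    for name, fold in (("mito_fold", mito_fold), ("total_fold", total_fold)):
        if not _missing(fold) and fold <= 0:
            raise ValueError(f"{name} must be positive, got {fold}")

    if _missing(mito_fold) or _missing(total_fold):
        return MitomirCall(mirna_id, mito_fold, mito_p, total_fold,
                           INDETERMINATE, "missing_input")

    mito_up = mito_fold > fc_up and (_missing(mito_p) or mito_p < alpha)
    total_flat_or_down = total_fold <= 1.0 + unchanged_tolerance

    if mito_up and total_flat_or_down:
        return MitomirCall(mirna_id, mito_fold, mito_p, total_fold,
                           ENRICHED, "mito_up_total_flat")
    if mito_up:
        return MitomirCall(mirna_id, mito_fold, mito_p, total_fold,
                           NOT_ENRICHED, "up_in_both_compartments")
    return MitomirCall(mirna_id, mito_fold, mito_p, total_fold,
                       NOT_ENRICHED, "no_mito_upregulation")


def classify_batch(
    de_mito: pd.DataFrame,
    qpcr_total: pd.DataFrame,
    candidate_ids: list[str],
    qpcr_mito: pd.DataFrame | None = None,
    fc_up: float = 2.0,
    alpha: float = 0.05,
    unchanged_tolerance: float = 0.2,
) -> pd.DataFrame:
    """Join mitochondrial evidence with whole-tissue fold changes per candidate.

    Mitochondrial evidence defaults to the sequencing DE table (columns
    mirna, log2_fc, p_value); when a mitochondrial-fraction qPCR table is
    supplied its fold changes take precedence (validation instrument) and
    the sequencing p-value is dropped for those miRNAs. Whole-tissue
    evidence is the qPCR fold-change table (columns mirna, fold_change).
    Candidates absent from either side are indeterminate.
    """
    if len(set(candidate_ids)) != len(candidate_ids):
        dupes = sorted({m for m in candidate_ids if candidate_ids.count(m) > 1})
        raise ValueError(f"duplicate candidate ids: {dupes}")
    for frame, name in ((de_mito, "de_mito"), (qpcr_total, "qpcr_total")):
        if not frame.empty and frame["mirna"].duplicated().any():
            raise ValueError(f"duplicate mirna ids in {name}")

    de_idx = de_mito.set_index("mirna") if not de_mito.empty else pd.DataFrame()
    total_idx = qpcr_total.set_index("mirna") if not qpcr_total.empty else pd.DataFrame()
    mito_qpcr_idx = (
        qpcr_mito.set_index("mirna")
        if qpcr_mito is not None and not qpcr_mito.empty
        else pd.DataFrame()
    )

    rows = []
    for mirna in candidate_ids:
        mito_fold = mito_p = total_fold = None
        if mirna in mito_qpcr_idx.index:
            mito_fold = float(mito_qpcr_idx.loc[mirna, "fold_change"])
        elif mirna in de_idx.index:
            lfc = de_idx.loc[mirna, "log2_fc"]
            mito_fold = None if pd.isna(lfc) else float(2.0 ** lfc)
            mito_p = float(de_idx.loc[mirna, "p_value"])
        if mirna in total_idx.index:
            total_fold = float(total_idx.loc[mirna, "fold_change"])
        call = classify_mitomir(
            mito_fold, mito_p, total_fold, mirna_id=mirna,
            fc_up=fc_up, alpha=alpha, unchanged_tolerance=unchanged_tolerance,
        )
        rows.append(
            {
                "mirna": mirna,
                "mito_fold": np.nan if call.mito_fold is None else call.mito_fold,
                "mito_p": np.nan if call.mito_p is None else call.mito_p,
                "total_fold": np.nan if call.total_fold is None else call.total_fold,
                "classification": call.classification,
                "rationale": call.rationale,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["mirna", "mito_fold", "mito_p", "total_fold",
                 "classification", "rationale"],
    )
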