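"""Relative quantification from triplicate qPCR Ct values (ddCt method).

The comparative-Ct workflow: average the triplicate Ct of target and
reference assays, form dCt = AvgCt(target) - AvgCt(reference) per sample,
ddCt = dCt(treatment) - dCt(control), and report fold change = 2^(-ddCt)
under the perfect-doubling assumption. The same arithmetic serves both
miRNA validation against a U6 reference and mRNA markers against GAPDH.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CtRecord", "QpcrResult", "delta_ct", "ddct_fold_change", "qpcr_fold_changes"]

CT_RANGE = (0.0, 45.0)

# Triplicates spreading wider than this many cycles are flagged (warning
# only; no automatic outlier rejection).
DEFAULT_MAX_SPREAD = 0.5


@dataclass(frozen=True)
class CtRecord:
    """Triplicate Ct values for one assay in one sample."""

    target_id: str
    sample_id: str
    condition: str
    replicate_cts: tuple[float, ...]
    is_reference: bool = False
    compartment: str | None = None

    def __post_init__(self) -> None:
        cts = tuple(float(c) for c in self.replicate_cts)
        object.__setattr__(self, "replicate_cts", cts)
        if len(cts) != 3:
            raise ValueError(
                f"{self.target_id}/{self.sample_id}: expected a Ct triplicate, "
                f"got {len(cts)} replicates"
            )
        for c in cts:
            if not CT_RANGE[0] < c < CT_RANGE[1]:
                raise ValueError(
                    f"{self.target_id}/{self.sample_id}: Ct {c} outside {CT_RANGE}"
                )

    @property
    def avg_ct(self) -> float:
        return float(np.mean(self.replicate_cts))

    @property
    def spread(self) -> float:
        return float(max(self.replicate_cts) - min(self.replicate_cts))


@dataclass(frozen=True)
class QpcrResult:
    target_id: str
    delta_ct_treatment: float
    delta_ct_control: float
    ddct: float
    fold_change: float


def delta_ct(
    target: CtRecord,
    reference: CtRecord,
    max_spread: float = DEFAULT_MAX_SPREAD,
) -> float:
    """dCt = mean target Ct minus mean reference Ct, same sample."""
    if target.sample_id != reference.sample_id:
        raise ValueError(
            f"sample mismatch: target from {target.sample_id!r}, "
            f"reference from {reference.sample_id!r}"
        )
    if not reference.is_reference:
        raise ValueError(f"{reference.target_id} is not flagged as a reference assay")
    for rec in (target, reference):
        if rec.spread > max_spread:
            warnings.warn(
                f"{rec.target_id}/{rec.sample_id}: triplicate spread "
                f"{rec.spread:.2f} cycles exceeds {max_spread}",
                UserWarning,
                stacklevel=2,
            )
    return target.avg_ct - reference.avg_ct


def ddct_fold_change(dct_treatment: float, dct_control: float, target_id: str = "") -> QpcrResult:
    """ddCt and fold change 2^(-ddCt) between two normalized samples."""
    if not (np.isfinite(dct_treatment) and np.isfinite(dct_control)):
        raise ValueError("dCt inputs must be finite")
    ddct = dct_treatment - dct_control
    return QpcrResult(
        target_id=target_id,
        delta_ct_treatment=float(dct_treatment),
        delta_ct_control=float(dct_control),
        ddct=float(ddct),
        fold_change=float(2.0 ** (-ddct)),
    )


def _records_from_frame(frame: pd.DataFrame) -> list[CtRecord]:
    keys = ["mirna", "compartment", "condition", "is_reference"]
    records = []
    for (mirna, comp, cond, is_ref), grp in frame.groupby(keys, sort=False):
        records.append(
            CtRecord(
                target_id=str(mirna),
                sample_id=f"{comp}|{cond}",
                condition=str(cond),
                compartment=str(comp),
                replicate_cts=tuple(grp.sort_values("replicate")["ct"]),
                is_reference=bool(is_ref),
            )
        )
    return records


def qpcr_fold_changes(
    ct_table: pd.DataFrame,
    treatment: str,
    control: str,
    compartment: str = "total",
) -> pd.DataFrame:
    """Per-target ddCt fold changes (treatment vs control) from a Ct table.

    ``ct_table`` is the long-format frame written by the simulator / read
    from CSV: columns mirna, compartment, condition, replicate, ct,
    is_reference. Exactly one reference assay per sample is required.
    """
    sub = ct_table[ct_table["compartment"] == compartment]
    records = _records_from_frame(sub)
    by_sample: dict[str, dict[str, CtRecord]] = {}
    refs: dict[str, CtRecord] = {}
    for rec in records:
        if rec.is_reference:
            if rec.sample_id in refs:
                raise ValueError(f"duplicate reference assay in sample {rec.sample_id}")
            refs[rec.sample_id] = rec
        else:
            by_sample.setdefault(rec.sample_id, {})[rec.target_id] = rec

    rows = []
    s_treat, s_ctrl = f"{compartment}|{treatment}", f"{compartment}|{control}"
    for sid in (s_treat, s_ctrl):
        if sid not in refs:
            raise ValueError(f"no reference assay for sample {sid}")
    targets = sorted(
        set(by_sample.get(s_treat, {})) & set(by_sample.get(s_ctrl, {}))
    )
    for target in targets:
        dct_t = delta_ct(by_sample[s_treat][target], refs[s_treat])
        dct_c = delta_ct(by_sample[s_ctrl][target], refs[s_ctrl])
        res = ddct_fold_change(dct_t, dct_c, target_id=target)
        rows.append(
            {
                "mirna": target,
                "condition_pair": f"{control}_vs_{treatment}",
                "delta_ct_treatment": res.delta_ct_treatment,
                "delta_ct_control": res.delta_ct_control,
                "ddct": res.ddct,
                "fold_change": res.fold_change,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mirna",
            "condition_pair",
            "delta_ct_treatment",
            "delta_ct_control",
            "ddct",
            "fold_change",
        ],
    )
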