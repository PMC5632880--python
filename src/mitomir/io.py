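"""Readers and writers for the pipeline's on-disk formats.

All tabular formats are UTF-8 TSV/CSV with a mandatory header row and "."
decimals; gene sets use the GMT dialect (set name, description, then
tab-separated member genes). Writes are atomic (temp file in the target
directory, then rename) so interrupted runs never leave half-written
artifacts.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .de import CountTable
from .enrich import PathwayMap

__all__ = [
    "ParseError",
    "read_count_table",
    "write_count_table",
    "read_ct_csv",
    "write_ct_csv",
    "read_target_map",
    "write_target_map",
    "read_gmt",
    "write_gmt",
    "write_table",
    "atomic_write_text",
]


class ParseError(ValueError):
    """An input file violates its documented dialect."""


def atomic_write_text(path: str | Path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_table(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Atomic TSV write with stable float formatting."""
    atomic_write_text(path, frame.to_csv(sep="\t", index=index, lineterminator="\n"))


def read_count_table(counts_path: str | Path, metadata_path: str | Path) -> CountTable:
    """Read a miRNA x library count TSV plus its library-metadata side-car."""
    try:
        raw = pd.read_csv(counts_path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{counts_path}: cannot parse TSV ({exc})") from exc
    if raw.index.has_duplicates:
        dupes = sorted(raw.index[raw.index.duplicated()].unique())
        raise ParseError(f"{counts_path}: duplicate mirna ids {dupes}")
    counts = np.empty(raw.shape, dtype=np.int64)
    for j, col in enumerate(raw.columns):
        for i, (mirna, cell) in enumerate(raw[col].items()):
            try:
                value = int(cell)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{counts_path}: non-integer cell at row {mirna!r}, "
                    f"column {col!r}: {cell!r}"
                ) from None
            if value < 0:
                raise ParseError(
                    f"{counts_path}: negative count at row {mirna!r}, column {col!r}"
                )
            counts[i, j] = value
    meta = pd.read_csv(metadata_path, sep="\t")
    required = ["library_id", "compartment", "condition", "library_size"]
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise ParseError(f"{metadata_path}: missing columns {missing}")
    meta = meta.set_index("library_id").loc[list(raw.columns)].reset_index()
    return CountTable(
        mirna_ids=list(raw.index), libraries=meta[required], counts=counts
    )


def write_count_table(
    table: CountTable, counts_path: str | Path, metadata_path: str | Path
) -> None:
    frame = table.to_frame()
    frame.index.name = "mirna"
    write_table(frame, counts_path, index=True)
    write_table(
        table.libraries[["library_id", "compartment", "condition", "library_size"]],
        metadata_path,
    )


def read_ct_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = ["mirna", "compartment", "condition", "replicate", "ct", "is_reference"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    frame["is_reference"] = frame["is_reference"].astype(bool)
    return frame[required]


def write_ct_csv(frame: pd.DataFrame, path: str | Path) -> None:
    atomic_write_text(path, frame.to_csv(index=False, lineterminator="\n"))


def read_target_map(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    required = ["mirna", "gene", "score"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if frame.duplicated(["mirna", "gene"]).any():
        dupes = frame[frame.duplicated(["mirna", "gene"])].head(3)
        raise ParseError(
            f"{path}: duplicate (mirna, gene) pairs, e.g. "
            f"{list(map(tuple, dupes[['mirna', 'gene']].to_numpy()))}"
        )
    scores = frame["score"].to_numpy(dtype=float)
    if np.any((scores < 0) | (scores > 1) | ~np.isfinite(scores)):
        raise ParseError(f"{path}: scores must lie in [0, 1]")
    return frame[required]


def write_target_map(frame: pd.DataFrame, path: str | Path) -> None:
    write_table(frame[["mirna", "gene", "score"]], path)


def read_gmt(path: str | Path) -> PathwayMap:
    gene_sets: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f">= 1 gene"
                )
            pid, description, genes = fields[0], fields[1], fields[2:]
            if pid in gene_sets:
                raise ParseError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
            gene_sets[pid] = set(g for g in genes if g)
            names[pid] = description
    return PathwayMap(gene_sets=gene_sets, names=names)


def write_gmt(pathways: PathwayMap, path: str | Path) -> None:
    lines = []
    for pid in sorted(pathways.gene_sets):
        genes = "\t".join(sorted(pathways.gene_sets[pid]))
        lines.append(f"{pid}\t{pathways.name(pid)}\t{genes}")
    atomic_write_text(path, "\n".join(lines) + "\n")


def write_ground_truth(truth, path: str | Path) -> None:
    atomic_write_text(path, truth.to_json())


def write_json(payload: dict, path: str | Path) -> None:
    atomic_write_text(path, json.dumps(payload, indent=1, sort_keys=True) + "\n")
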