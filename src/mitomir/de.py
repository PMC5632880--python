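"""Two-library exact differential expression for small-RNA count data.

Pooled compartment-fractionation designs sequence a single library per
(compartment, condition) group, so replicate-based tests do not apply.
Differential expression between two libraries is assessed with the exact
Poisson test in its conditional-binomial form: under the null of equal
relative abundance, the count in library 1 given the summed count ``n`` is
``Binomial(n, N1 / (N1 + N2))`` where ``N1``, ``N2`` are the library sizes.
The two-sided p-value sums all binomial point masses no larger than the
observed one (minimum-likelihood convention).

Fold changes are reported on the log2 scale of CPM (counts per million)
ratios; multiple testing is adjusted with Benjamini-Hochberg FDR; calls use
the conventional fold-change-plus-significance thresholds (fold > 2 up,
fold < 0.5 down, p < 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountTable",
    "cpm_normalize",
    "exact_poisson_test",
    "log2_fold_change",
    "bh_fdr",
    "call_de",
    "pairwise_profile",
    "hierarchical_cluster",
]

COMPARTMENTS = ("mitochondrial", "total")
CONDITIONS = ("sham", "tac4w", "tac8w")

# Relative tolerance when comparing binomial point masses to the observed
# mass; guards against ties being split by floating-point rounding.
_MINLIKE_RTOL = 1e-12


@dataclass
class CountTable:
    """A miRNA-by-library matrix of raw counts plus library metadata.

    Parameters
    ----------
    mirna_ids : list of str
        Unique miRNA identifiers (rows), miRBase-style names.
    libraries : pandas.DataFrame
        One row per library with columns ``library_id``, ``compartment``
        (``mitochondrial`` or ``total``), ``condition`` and
        ``library_size``. Library size defaults to the column sum of the
        counts and may only be declared larger (unassigned reads).
    counts : numpy.ndarray
        Non-negative integer matrix, shape ``(n_mirnas, n_libraries)``.
    """

    mirna_ids: list[str]
    libraries: pd.DataFrame
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if len(self.mirna_ids) != self.counts.shape[0]:
            raise ValueError("mirna_ids length does not match count rows")
        if len(self.libraries) != self.counts.shape[1]:
            raise ValueError("libraries length does not match count columns")
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            dupes = sorted({m for m in self.mirna_ids if self.mirna_ids.count(m) > 1})
            raise ValueError(f"duplicate mirna_ids: {dupes}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        required = {"library_id", "compartment", "condition", "library_size"}
        missing = required - set(self.libraries.columns)
        if missing:
            raise ValueError(f"libraries metadata missing columns: {sorted(missing)}")
        if self.libraries["library_id"].duplicated().any():
            raise ValueError("duplicate library_id in metadata")
        colsums = self.counts.sum(axis=0)
        sizes = self.libraries["library_size"].to_numpy()
        if np.any(sizes <= 0):
            raise ValueError("library_size must be positive")
        if np.any(sizes < colsums):
            raise ValueError("declared library_size smaller than column sum")
        self.libraries = self.libraries.reset_index(drop=True)

    @property
    def n_mirnas(self) -> int:
        return self.counts.shape[0]

    def library_index(self, compartment: str, condition: str) -> int:
        """Index of the unique library for a (compartment, condition) group."""
        mask = (self.libraries["compartment"] == compartment) & (
            self.libraries["condition"] == condition
        )
        idx = np.flatnonzero(mask.to_numpy())
        if idx.size != 1:
            raise ValueError(
                f"expected exactly one library for ({compartment}, {condition}), "
                f"found {idx.size}"
            )
        return int(idx[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.mirna_ids, name="mirna"),
            columns=self.libraries["library_id"].tolist(),
        )


def cpm_normalize(table: CountTable) -> pd.DataFrame:
    """Counts-per-million normalization: ``count * 1e6 / library_size``.

    Returns a DataFrame indexed by miRNA id with one column per library.
    """
    sizes = table.libraries["library_size"].to_numpy(dtype=float)
    if np.any(sizes <= 0):
        raise ValueError("library_size must be positive")
    cpm = table.counts * 1e6 / sizes[np.newaxis, :]
    return pd.DataFrame(
        cpm,
        index=pd.Index(table.mirna_ids, name="mirna"),
        columns=table.libraries["library_id"].tolist(),
    )


def _validate_pair(x1: int, x2: int, n1: float, n2: float) -> None:
    for x in (x1, x2):
        if x < 0 or x != int(x):
            raise ValueError(f"counts must be non-negative integers, got {x}")
    for n in (n1, n2):
        if not np.isfinite(n) or n <= 0:
            raise ValueError(f"library sizes must be positive, got {n}")


def exact_poisson_test(x1: int, x2: int, n1: float, n2: float) -> float:
    """Exact Poisson test for equal relative abundance in two libraries.

    Conditional on the total ``n = x1 + x2``, the first count is
    ``Binomial(n, pi)`` with ``pi = n1 / (n1 + n2)`` under the null. The
    two-sided p-value is the sum of all point masses not exceeding the
    observed mass (minimum-likelihood method). ``n = 0`` carries no
    information and returns 1.
    """
    _validate_pair(x1, x2, n1, n2)
    x1 = int(x1)
    n = x1 + int(x2)
    if n == 0:
        return 1.0
    pi = n1 / (n1 + n2)
    if n <= 1024:
        k = np.arange(n + 1)
        pmf = binom.pmf(k, n, pi)
        keep = pmf <= pmf[x1] * (1.0 + _MINLIKE_RTOL)
        if keep.all():
            return 1.0
        return min(max(float(pmf[keep].sum()), 0.0), 1.0)
    # Large n: the pmf is unimodal, so the acceptance region {k: pmf(k) <=
    # pmf(x1)} is two tails. Sum the observed side's tail directly and
    # binary-search the far side's boundary on the monotone slope.
    mode = int(np.floor((n + 1) * pi))
    observed = float(binom.pmf(x1, n, pi))
    cutoff = observed * (1.0 + _MINLIKE_RTOL)
    if x1 == mode or float(binom.pmf(mode, n, pi)) <= cutoff:
        # the maximal mass itself is within the cutoff: every k qualifies
        return 1.0
    if x1 < mode:
        p = float(binom.cdf(x1, n, pi))
        # smallest y in (mode, n] with pmf(y) <= cutoff; pmf decreasing there
        lo, hi = mode, n + 1
        while lo + 1 < hi:
            mid = (lo + hi) // 2
            if float(binom.pmf(mid, n, pi)) <= cutoff:
                hi = mid
            else:
                lo = mid
        if hi <= n:
            p += float(binom.sf(hi - 1, n, pi))
    else:
        p = float(binom.sf(x1 - 1, n, pi))
        # largest y in [0, mode) with pmf(y) <= cutoff; pmf increasing there
        lo, hi = -1, mode
        while lo + 1 < hi:
            mid = (lo + hi) // 2
            if float(binom.pmf(mid, n, pi)) <= cutoff:
                lo = mid
            else:
                hi = mid
        if lo >= 0:
            p += float(binom.cdf(lo, n, pi))
    return min(max(p, 0.0), 1.0)


def exact_poisson_test_doubled(x1: int, x2: int, n1: float, n2: float) -> float:
    """Alternative two-sided convention: twice the smaller tail, capped at 1."""
    _validate_pair(x1, x2, n1, n2)
    n = int(x1) + int(x2)
    if n == 0:
        return 1.0
    pi = n1 / (n1 + n2)
    lower = float(binom.cdf(x1, n, pi))
    upper = float(binom.sf(x1 - 1, n, pi))
    return min(1.0, 2.0 * min(lower, upper))


def log2_fold_change(
    x1: int, x2: int, n1: float, n2: float, pseudo_cpm: float = 0.5
) -> float:
    """log2 of the CPM ratio (library 2 over library 1) with a pseudocount.

    ``pseudo_cpm`` is added to both CPM values to keep zero counts finite.
    With ``pseudo_cpm = 0`` and both counts zero the ratio is undefined and
    NaN is returned (reported as missing downstream, never +/-inf).
    """
    _validate_pair(x1, x2, n1, n2)
    if pseudo_cpm < 0:
        raise ValueError("pseudo_cpm must be non-negative")
    cpm1 = x1 * 1e6 / n1 + pseudo_cpm
    cpm2 = x2 * 1e6 / n2 + pseudo_cpm
    if cpm1 == 0.0 or cpm2 == 0.0:
        return float("nan")
    return float(np.log2(cpm2 / cpm1))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def call_de(
    results: pd.DataFrame,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    alpha: float = 0.05,
    use_q: bool = False,
) -> pd.DataFrame:
    """Fill the ``call`` column of a DE result table.

    ``up`` requires ``log2_fc > log2(fc_up)`` and significance; ``down``
    requires ``log2_fc < log2(fc_down)``; everything else (including missing
    fold changes) is ``ns``. Inequalities are strict. Significance uses the
    raw p-value by default; ``use_q=True`` switches to the BH q-value.
    """
    if not (0 < fc_down < 1 < fc_up):
        raise ValueError("thresholds must satisfy 0 < fc_down < 1 < fc_up")
    out = results.copy()
    stat = out["q_value"] if use_q else out["p_value"]
    sig = stat < alpha
    lfc = out["log2_fc"]
    up = sig & (lfc > np.log2(fc_up))
    down = sig & (lfc < np.log2(fc_down))
    call = np.where(up, "up", np.where(down, "down", "ns"))
    call[lfc.isna().to_numpy()] = "ns"
    out["call"] = call
    return out


def de_table(
    x1: np.ndarray,
    x2: np.ndarray,
    n1: float,
    n2: float,
    mirna_ids,
    pseudo_cpm: float = 0.5,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    alpha: float = 0.05,
    use_q: bool = False,
) -> pd.DataFrame:
    """Run the full test -> BH -> call pipeline on two count vectors."""
    x1 = np.asarray(x1)
    x2 = np.asarray(x2)
    p = np.array([exact_poisson_test(a, b, n1, n2) for a, b in zip(x1, x2)])
    lfc = np.array(
        [log2_fold_change(a, b, n1, n2, pseudo_cpm) for a, b in zip(x1, x2)]
    )
    frame = pd.DataFrame(
        {
            "mirna": list(mirna_ids),
            "log2_fc": lfc,
            "p_value": p,
            "q_value": bh_fdr(p),
        }
    )
    return call_de(frame, fc_up=fc_up, fc_down=fc_down, alpha=alpha, use_q=use_q)


def pairwise_profile(
    table: CountTable,
    pairs: list[tuple[str, str]],
    compartment: str = "mitochondrial",
    min_count: int = 1,
    pseudo_cpm: float = 0.5,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    alpha: float = 0.05,
    use_q: bool = False,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Per-pair DE tables for condition pairs within one compartment.

    A miRNA enters a pair's table iff it is detected (count >= ``min_count``)
    in at least one of the two libraries; the exact test, BH adjustment and
    threshold calls are then applied to the retained rows.
    """
    out: dict[tuple[str, str], pd.DataFrame] = {}
    for cond1, cond2 in pairs:
        i1 = table.library_index(compartment, cond1)
        i2 = table.library_index(compartment, cond2)
        x1 = table.counts[:, i1]
        x2 = table.counts[:, i2]
        n1 = float(table.libraries.loc[i1, "library_size"])
        n2 = float(table.libraries.loc[i2, "library_size"])
        keep = (x1 >= min_count) | (x2 >= min_count)
        ids = [m for m, k in zip(table.mirna_ids, keep) if k]
        out[(cond1, cond2)] = de_table(
            x1[keep], x2[keep], n1, n2, ids,
            pseudo_cpm=pseudo_cpm, fc_up=fc_up, fc_down=fc_down,
            alpha=alpha, use_q=use_q,
        )
    return out


def _correlation_distance(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Condensed 1 - Pearson distance; zero-variance rows get maximal distance."""
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    sd = matrix.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            "rows with zero variance assigned maximal correlation distance",
            UserWarning,
            stacklevel=3,
        )
    centered = matrix - matrix.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(centered, axis=1)
    safe = np.where(norm == 0, 1.0, norm)
    unit = centered / safe[:, np.newaxis]
    corr = unit @ unit.T
    dist = 1.0 - corr
    dist[degenerate, :] = 2.0
    dist[:, degenerate] = 2.0
    np.fill_diagonal(dist, 0.0)
    iu = np.triu_indices(n, k=1)
    return np.maximum(dist[iu], 0.0), degenerate


def hierarchical_cluster(log_cpm: np.ndarray) -> tuple[list[int], np.ndarray]:
    """Average-linkage clustering of rows under 1 - Pearson distance.

    Returns ``(leaf_order, linkage_matrix)``. Ties are broken by input order
    (scipy's deterministic condensed-distance processing); zero-variance rows
    are maximally distant from all others and end up placed last among leaves
    with equal merge heights.
    """
    log_cpm = np.asarray(log_cpm, dtype=float)
    if log_cpm.ndim != 2 or log_cpm.shape[0] < 2:
        raise ValueError("need a matrix with at least 2 rows")
    condensed, degenerate = _correlation_distance(log_cpm)
    link = linkage(condensed, method="average")
    order = [int(i) for i in leaves_list(link)]
    if degenerate.any():
        order = [i for i in order if not degenerate[i]] + list(
            np.flatnonzero(degenerate)
        )
        order = [int(i) for i in order]
    return order, link
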