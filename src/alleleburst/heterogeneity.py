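"""Observed-to-expected biallelic expression as a cell-population homogeneity metric.

If the two alleles of a gene burst independently and all cells share the same
kinetics, the fraction of cells expressing both alleles factorizes into the
product of the per-allele expressed fractions:

    E_biallelic(g) = (1/C^2) * sum_k I(n_k,C57) * sum_k I(n_k,CAST)
    O_biallelic(g) = (1/C)   * sum_k I(n_k,C57) I(n_k,CAST)

with I(n) = 1 when n > 0. In a homogeneous population O/E ~ 1 per gene; when a
gene is active only in a subpopulation comprising a fraction w of the cells,
both alleles light up in the same cells and the ratio converges to 1/w. The
median O/E over genes therefore quantifies cluster heterogeneity, calibrated
here by permutation tests over random gene sets or random same-size cell sets,
by expression-matched gene controls, and by cluster-mixing experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counts import AllelicCountMatrix
from .errors import InsufficientDataError, InvalidParameterError, SchemaError

__all__ = [
    "oe_biallelic",
    "median_oe",
    "PermutationResult",
    "gene_permutation_test",
    "cell_permutation_test",
    "expression_matched_control",
    "mixing_experiment",
]


def _indicators(
    m_cast: AllelicCountMatrix, m_c57: AllelicCountMatrix, cells
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    from .states import _check_aligned

    _check_aligned(m_cast, m_c57)
    if cells is None:
        idx = np.arange(m_cast.n_cells)
    else:
        from .counts import _cell_indexer

        idx = _cell_indexer(m_cast.cell_ids, cells)
    usable = ~(m_cast.missing_mask | m_c57.missing_mask)[:, idx]
    i_c57 = (m_c57.values[:, idx] > 0) & usable
    i_cast = (m_cast.values[:, idx] > 0) & usable
    return i_c57, i_cast, usable


def oe_biallelic(
    m_cast: AllelicCountMatrix,
    m_c57: AllelicCountMatrix,
    cells=None,
) -> pd.DataFrame:
    """Observed and expected biallelic fractions per gene over a cell subset.

    Both quantities are fractions over the gene's non-missing cells in the
    subset; ``ratio`` is NaN when the expected fraction is zero (flagged via
    the ``defined`` column).

    Returns a DataFrame indexed by gene: ``observed, expected, ratio,
    n_cells_used, defined``.
    """
    i_c57, i_cast, usable = _indicators(m_cast, m_c57, cells)
    if usable.shape[1] < 2:
        raise InsufficientDataError("need >= 2 cells in the subset")
    n_used = usable.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.where(n_used > 0, n_used, np.nan).astype(float)
        f_c57 = i_c57.sum(axis=1) / denom
        f_cast = i_cast.sum(axis=1) / denom
        observed = (i_c57 & i_cast).sum(axis=1) / denom
        expected = f_c57 * f_cast
        ratio = np.where(expected > 0, observed / np.where(expected > 0, expected, 1.0), np.nan)
    return pd.DataFrame(
        {
            "observed": observed,
            "expected": expected,
            "ratio": ratio,
            "n_cells_used": n_used,
            "defined": np.isfinite(ratio),
        },
        index=pd.Index(m_cast.gene_ids, name="gene_id"),
    )


def median_oe(records: pd.DataFrame, genes=None) -> float:
    """Median O/E ratio over genes with a defined ratio."""
    ratios = records["ratio"]
    if genes is not None:
        ratios = ratios.loc[[g for g in genes if g in ratios.index]]
    ratios = ratios[np.isfinite(ratios)]
    if len(ratios) == 0:
        raise InsufficientDataError("no gene with a defined O/E ratio")
    return float(np.median(ratios))


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of a permutation test on the median O/E ratio."""

    p_value: float
    observed: float
    null_medians: np.ndarray
    alternative: str

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def _perm_pvalue(observed: float, null: np.ndarray, alternative: str) -> float:
    # add-one permutation p-value estimator
    if alternative == "lower":
        extreme = int(np.sum(null <= observed))
    elif alternative == "upper":
        extreme = int(np.sum(null >= observed))
    else:
        raise InvalidParameterError(f"alternative must be 'lower' or 'upper', got {alternative!r}")
    return (1.0 + extreme) / (null.size + 1.0)


def gene_permutation_test(
    records: pd.DataFrame,
    focal_genes,
    n_perm: int = 100_000,
    seed: int | None = None,
    *,
    alternative: str = "lower",
) -> PermutationResult:
    """Compare a gene set's median O/E against random same-size gene sets.

    The null statistic is the median O/E of ``len(focal_genes)`` genes drawn
    without replacement from the genes with defined ratios. ``alternative``
    'lower' tests for a median below random (homogeneity of the focal set,
    e.g. ubiquitously expressed genes), 'upper' for above.
    """
    if n_perm < 1:
        raise InvalidParameterError(f"n_perm must be >= 1, got {n_perm}")
    defined = records.loc[records["defined"].astype(bool)]
    universe = defined.index
    focal = [g for g in focal_genes if g in universe]
    if len(focal) == 0:
        raise InsufficientDataError("no focal gene has a defined O/E ratio")
    observed = float(np.median(defined.loc[focal, "ratio"]))
    ratios = defined["ratio"].to_numpy(dtype=float)
    k = len(focal)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    chunk = max(1, min(n_perm, int(5e7) // max(k, 1)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        picks = np.argsort(rng.random((m, ratios.size)), axis=1)[:, :k]
        null[done : done + m] = np.median(ratios[picks], axis=1)
        done += m
    return PermutationResult(_perm_pvalue(observed, null, alternative), observed, null, alternative)


def cell_permutation_test(
    m_cast: AllelicCountMatrix,
    m_c57: AllelicCountMatrix,
    cluster_cells,
    n_perm: int = 1000,
    seed: int | None = None,
    *,
    alternative: str = "lower",
) -> PermutationResult:
    """Compare a cell cluster's median O/E against random same-size cell sets.

    The null draws ``len(cluster_cells)`` cells without replacement from all
    cells and recomputes the per-gene O/E and its median. A cluster purer than
    a random mix of the dataset has a lower median O/E ('lower' alternative).
    """
    if n_perm < 1:
        raise InvalidParameterError(f"n_perm must be >= 1, got {n_perm}")
    from .counts import _cell_indexer

    idx = _cell_indexer(m_cast.cell_ids, cluster_cells)
    if idx.size < 2:
        raise InsufficientDataError("cluster must contain >= 2 cells")
    observed = median_oe(oe_biallelic(m_cast, m_c57, cells=idx))
    rng = np.random.default_rng(seed)
    n_cells = m_cast.n_cells
    null = np.empty(n_perm)
    for i in range(n_perm):
        sub = rng.choice(n_cells, size=idx.size, replace=False)
        null[i] = median_oe(oe_biallelic(m_cast, m_c57, cells=sub))
    return PermutationResult(_perm_pvalue(observed, null, alternative), observed, null, alternative)


def expression_matched_control(
    records: pd.DataFrame,
    focal_genes,
    mean_expression: pd.Series,
    seed: int | None = None,
    *,
    n_controls: int = 1000,
    n_bins: int = 50,
) -> np.ndarray:
    """Null medians from random gene sets matched on expression level.

    Genes are stratified into ``n_bins`` quantile bins of ``mean_expression``;
    each control set draws, per bin, as many non-focal genes as the focal set
    has in that bin (without replacement). Returns the control medians.

    Raises an error naming the first bin whose non-focal candidate pool is
    smaller than the focal gene count in that bin.
    """
    defined = records.loc[records["defined"].astype(bool)]
    expr = mean_expression.reindex(defined.index)
    if expr.isna().any():
        raise SchemaError("mean_expression missing for some scored genes")
    focal = [g for g in focal_genes if g in defined.index]
    if len(focal) == 0:
        raise InsufficientDataError("no focal gene has a defined O/E ratio")
    bins = pd.qcut(expr.rank(method="first"), q=min(n_bins, len(expr)), labels=False)
    focal_set = set(focal)
    pool_by_bin: dict[int, np.ndarray] = {}
    need_by_bin: dict[int, int] = {}
    for b in np.unique(bins):
        members = defined.index[bins == b]
        need = sum(1 for g in members if g in focal_set)
        if need == 0:
            continue
        pool = np.array([g for g in members if g not in focal_set], dtype=object)
        if pool.size < need:
            raise InsufficientDataError(
                f"expression bin {int(b)} has {pool.size} candidate genes but needs {need}"
            )
        pool_by_bin[int(b)] = pool
        need_by_bin[int(b)] = need
    rng = np.random.default_rng(seed)
    ratios = defined["ratio"]
    medians = np.empty(n_controls)
    for i in range(n_controls):
        chosen: list = []
        for b, pool in pool_by_bin.items():
            chosen.extend(rng.choice(pool, size=need_by_bin[b], replace=False))
        medians[i] = float(np.median(ratios.loc[chosen]))
    return medians


def mixing_experiment(
    m_cast: AllelicCountMatrix,
    m_c57: AllelicCountMatrix,
    source_cells,
    target_cells,
    added_counts,
    n_boot: int = 20,
    seed: int | None = None,
) -> pd.DataFrame:
    """Median O/E of a target cluster as contaminating cells are added.

    For each ``n`` in ``added_counts``, ``n`` source-cluster cells are drawn
    without replacement, appended to the target cluster, and the median O/E
    recomputed; the draw is repeated ``n_boot`` times. ``n = 0`` reproduces
    the target cluster's own median exactly.

    Returns a tidy DataFrame ``(n_added, replicate, median_oe)`` plus a
    ``mean``/``sd`` summary accessible via ``groupby``.
    """
    from .counts import _cell_indexer

    src = _cell_indexer(m_cast.cell_ids, source_cells)
    tgt = _cell_indexer(m_cast.cell_ids, target_cells)
    if np.intersect1d(src, tgt).size:
        raise InvalidParameterError("source and target clusters must be disjoint")
    rng = np.random.default_rng(seed)
    rows = []
    for n in added_counts:
        n = int(n)
        if n < 0 or n > src.size:
            raise InvalidParameterError(f"cannot add {n} cells from a source of {src.size}")
        reps = 1 if n == 0 else n_boot
        for r in range(reps):
            extra = rng.choice(src, size=n, replace=False) if n > 0 else np.array([], dtype=int)
            cells = np.concatenate([tgt, extra])
            rows.append(
                {
                    "n_added": n,
                    "replicate": r,
                    "median_oe": median_oe(oe_biallelic(m_cast, m_c57, cells=cells)),
                }
            )
    return pd.DataFrame(rows)
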