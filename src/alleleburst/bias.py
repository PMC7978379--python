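"""Allelic bias: the probability that one allele outnumbers the other.

For two independently bursting alleles with transcript counts a1 (C57) and
a2 (CAST), the bias probabilities are

    P(a1 > a2) = sum_k P(a1 = k) * P(a2 < k)
    P(a1 = a2) = sum_k P(a1 = k) * P(a2 = k)

with both pmfs truncated where their cumulative mass reaches 1 - 1e-10. Genes
with near-identical allelic kinetics have P(C57 > CAST) ~ P(CAST > C57); for
low-expressed genes P(equal) is dominated by joint silence.

The dependence of bias on allele-specific kinetics differences is summarized
by ordinary least squares of the log10 bias-probability ratio on the log10
fold-changes of burst frequency and burst size and their interaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counts import AllelicCountMatrix
from .errors import CollinearityError, InsufficientDataError
from .two_state import TwoStateKinetics, pmf

__all__ = [
    "BiasProbabilities",
    "bias_probabilities",
    "observed_bias_fractions",
    "bias_regression",
    "BiasRegressionResult",
]


@dataclass(frozen=True)
class BiasProbabilities:
    """Analytic probabilities of allelic inequality for one gene."""

    p_c57_gt: float
    p_cast_gt: float
    p_equal: float
    truncation_n: int

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_c57_gt, self.p_cast_gt, self.p_equal)


def bias_probabilities(
    kin_c57: TwoStateKinetics,
    kin_cast: TwoStateKinetics,
    *,
    tail_tol: float = 1e-10,
) -> BiasProbabilities:
    """P(C57 > CAST), P(CAST > C57) and P(C57 = CAST) under independence."""
    d1 = pmf(kin_c57, tail_tol=tail_tol)
    d2 = pmf(kin_cast, tail_tol=tail_tol)
    n = max(d1.n_max, d2.n_max)
    p1 = np.zeros(n + 1)
    p2 = np.zeros(n + 1)
    p1[: d1.n_max + 1] = d1.probabilities
    p2[: d2.n_max + 1] = d2.probabilities
    cdf1 = np.cumsum(p1)
    cdf2 = np.cumsum(p2)
    # P(a > b) = sum_{k>=1} P(a=k) * CDF_b(k-1)
    p_c57_gt = float(np.dot(p1[1:], cdf2[:-1]))
    p_cast_gt = float(np.dot(p2[1:], cdf1[:-1]))
    p_equal = float(np.dot(p1, p2))
    return BiasProbabilities(
        p_c57_gt=p_c57_gt, p_cast_gt=p_cast_gt, p_equal=p_equal, truncation_n=n
    )


def observed_bias_fractions(
    m_cast: AllelicCountMatrix, m_c57: AllelicCountMatrix
) -> pd.DataFrame:
    """Per-gene fractions of cells with C57 > CAST, CAST > C57, and equal counts.

    Missing cells are excluded per gene; genes without usable cells get NaN.
    Returns columns ``f_c57_gt, f_cast_gt, f_equal, n_cells_used``.
    """
    from .states import _check_aligned

    _check_aligned(m_cast, m_c57)
    usable = ~(m_cast.missing_mask | m_c57.missing_mask)
    n_used = usable.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.where(n_used > 0, n_used, np.nan).astype(float)
        f_c57 = ((m_c57.values > m_cast.values) & usable).sum(axis=1) / denom
        f_cast = ((m_cast.values > m_c57.values) & usable).sum(axis=1) / denom
        f_eq = ((m_cast.values == m_c57.values) & usable).sum(axis=1) / denom
    return pd.DataFrame(
        {
            "f_c57_gt": f_c57,
            "f_cast_gt": f_cast,
            "f_equal": f_eq,
            "n_cells_used": n_used,
        },
        index=pd.Index(m_cast.gene_ids, name="gene_id"),
    )


@dataclass(frozen=True)
class BiasRegressionResult:
    """OLS fit of allelic bias on kinetics fold-changes.

    ``params`` etc. are indexed by term: intercept, log10 burst-frequency
    fold-change, log10 burst-size fold-change, and their interaction.
    ``n_genes`` counts genes entering the fit; ``n_excluded`` counts genes
    dropped for a zero probability on either side of the bias ratio.
    """

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    rsquared: float
    n_genes: int
    n_excluded: int

    def summary_frame(self) -> pd.DataFrame:
        """Coefficient table: coef, std err, t, p, CI bounds."""
        return pd.DataFrame(
            {
                "coef": self.params,
                "std_err": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
                "ci_lower": self.conf_int[0],
                "ci_upper": self.conf_int[1],
            }
        )


def bias_regression(table: pd.DataFrame, *, min_genes: int = 10) -> BiasRegressionResult:
    """OLS of log10(P(C57>CAST)/P(CAST>C57)) on kinetics fold-changes.

    ``table`` needs per-gene columns ``bf_c57, bf_cast, bs_c57, bs_cast,
    p_c57_gt, p_cast_gt``. The design is x1 = log10(bf_C57/bf_CAST),
    x2 = log10(bs_C57/bs_CAST), x3 = x1 * x2, with intercept. Genes with zero
    probability on either side of the ratio are excluded and counted.
    """
    import statsmodels.api as sm

    req = {"bf_c57", "bf_cast", "bs_c57", "bs_cast", "p_c57_gt", "p_cast_gt"}
    if not req <= set(table.columns):
        from .errors import SchemaError

        raise SchemaError(f"bias regression table needs columns {sorted(req)}")
    finite = (
        (table["p_c57_gt"] > 0)
        & (table["p_cast_gt"] > 0)
        & np.isfinite(table[["bf_c57", "bf_cast", "bs_c57", "bs_cast"]]).all(axis=1)
        & (table[["bf_c57", "bf_cast", "bs_c57", "bs_cast"]] > 0).all(axis=1)
    )
    df = table.loc[finite]
    n_excluded = int(len(table) - len(df))
    if len(df) < min_genes:
        raise InsufficientDataError(
            f"need >= {min_genes} genes with finite bias ratio, got {len(df)}"
        )
    y = np.log10(df["p_c57_gt"] / df["p_cast_gt"])
    x1 = np.log10(df["bf_c57"] / df["bf_cast"])
    x2 = np.log10(df["bs_c57"] / df["bs_cast"])
    X = pd.DataFrame(
        {
            "log10_bf_ratio": x1,
            "log10_bs_ratio": x2,
            "log10_bf_ratio:log10_bs_ratio": x1 * x2,
        }
    )
    X = sm.add_constant(X, prepend=True)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise CollinearityError(
            "design matrix is rank-deficient (constant or proportional fold-changes)"
        )
    fit = sm.OLS(y.to_numpy(), X).fit()
    ci = fit.conf_int()
    ci.columns = [0, 1]
    return BiasRegressionResult(
        params=fit.params,
        bse=fit.bse,
        tvalues=fit.tvalues,
        pvalues=fit.pvalues,
        conf_int=ci,
        rsquared=float(fit.rsquared),
        n_genes=int(len(df)),
        n_excluded=n_excluded,
    )
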