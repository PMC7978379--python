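"""Predicted and observed allelic expression states of single cells.

With independently bursting alleles, each cell falls into one of four states
for a given gene — silent, monoallelic C57, monoallelic CAST, or biallelic —
and the state probabilities factorize through the per-allele silence
probabilities P0:

    P(silent)    = P0_C57 * P0_CAST
    P(mono C57)  = (1 - P0_C57) * P0_CAST
    P(mono CAST) = (1 - P0_CAST) * P0_C57
    P(biallelic) = (1 - P0_C57) * (1 - P0_CAST)

Observed fractions are the per-gene averages of the corresponding indicator
conditions over cells with allele information; agreement between the two is
summarized by Spearman rank correlation across genes, optionally on held-out
cells (train/test cross-validation).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .counts import AllelicCountMatrix
from .errors import InsufficientDataError, SchemaError
from .inference import infer_kinetics, round_half_up
from .two_state import TwoStateKinetics, prob_zero

__all__ = [
    "STATES",
    "state_probabilities",
    "observed_state_fractions",
    "state_table",
    "compare_predicted_observed",
    "cross_validate",
    "poisson_state_comparison",
]

STATES = ("silent", "mono_c57", "mono_cast", "biallelic")


def state_probabilities(kin_c57: TwoStateKinetics, kin_cast: TwoStateKinetics) -> np.ndarray:
    """Probabilities of (silent, mono C57, mono CAST, biallelic) for one gene."""
    p0_c57 = prob_zero(kin_c57)
    p0_cast = prob_zero(kin_cast)
    return _probs_from_p0(p0_c57, p0_cast)


def _probs_from_p0(p0_c57: float, p0_cast: float) -> np.ndarray:
    return np.array(
        [
            p0_c57 * p0_cast,
            (1.0 - p0_c57) * p0_cast,
            (1.0 - p0_cast) * p0_c57,
            (1.0 - p0_c57) * (1.0 - p0_cast),
        ]
    )


def observed_state_fractions(
    m_cast: AllelicCountMatrix, m_c57: AllelicCountMatrix
) -> pd.DataFrame:
    """Per-gene observed fractions of the four allelic states.

    Cells flagged missing on either allele are excluded from that gene's
    denominator. Genes with no usable cells get NaN fractions and
    ``n_cells_used`` 0.

    Returns a DataFrame indexed by gene with columns ``f_silent, f_mono_c57,
    f_mono_cast, f_biallelic, n_cells_used, mean_c57, mean_cast``.
    """
    _check_aligned(m_cast, m_c57)
    missing = m_cast.missing_mask | m_c57.missing_mask
    usable = ~missing
    n_used = usable.sum(axis=1)

    c57_on = (m_c57.values > 0) & usable
    cast_on = (m_cast.values > 0) & usable
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.where(n_used > 0, n_used, np.nan).astype(float)
        f_bi = (c57_on & cast_on).sum(axis=1) / denom
        f_mono_c57 = (c57_on & ~cast_on & usable).sum(axis=1) / denom
        f_mono_cast = (cast_on & ~c57_on & usable).sum(axis=1) / denom
        f_silent = (~c57_on & ~cast_on & usable).sum(axis=1) / denom
        mean_c57 = np.where(
            n_used > 0, np.where(usable, m_c57.values, 0.0).sum(axis=1) / denom, np.nan
        )
        mean_cast = np.where(
            n_used > 0, np.where(usable, m_cast.values, 0.0).sum(axis=1) / denom, np.nan
        )
    return pd.DataFrame(
        {
            "f_silent": f_silent,
            "f_mono_c57": f_mono_c57,
            "f_mono_cast": f_mono_cast,
            "f_biallelic": f_bi,
            "n_cells_used": n_used,
            "mean_c57": mean_c57,
            "mean_cast": mean_cast,
        },
        index=pd.Index(m_cast.gene_ids, name="gene_id"),
    )


def state_table(
    kinetics: pd.DataFrame,
    m_cast: AllelicCountMatrix,
    m_c57: AllelicCountMatrix,
) -> pd.DataFrame:
    """Combine predicted probabilities and observed fractions per gene.

    ``kinetics`` is a long table with columns ``gene_id, allele, k_on, k_off,
    k_syn`` carrying one row per allele (labels ``C57`` and ``CAST``). Only
    genes present with both alleles and nonzero usable cells are returned.

    The output follows the state-table schema: ``p_silent, p_mono_c57,
    p_mono_cast, p_biallelic, f_silent, f_mono_c57, f_mono_cast, f_biallelic,
    n_cells_used, mean_expression`` (mean over non-missing cells, both alleles
    summed).
    """
    obs = observed_state_fractions(m_cast, m_c57)
    wide = _kinetics_wide(kinetics)
    rows = {}
    for gene, row in wide.iterrows():
        if gene not in obs.index or obs.loc[gene, "n_cells_used"] == 0:
            continue
        probs = state_probabilities(
            TwoStateKinetics(row["k_on_C57"], row["k_off_C57"], row["k_syn_C57"]),
            TwoStateKinetics(row["k_on_CAST"], row["k_off_CAST"], row["k_syn_CAST"]),
        )
        o = obs.loc[gene]
        rows[gene] = {
            "p_silent": probs[0],
            "p_mono_c57": probs[1],
            "p_mono_cast": probs[2],
            "p_biallelic": probs[3],
            "f_silent": o["f_silent"],
            "f_mono_c57": o["f_mono_c57"],
            "f_mono_cast": o["f_mono_cast"],
            "f_biallelic": o["f_biallelic"],
            "n_cells_used": int(o["n_cells_used"]),
            "mean_expression": o["mean_c57"] + o["mean_cast"],
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    if out.empty:
        only_kin = [g for g in wide.index if g not in obs.index]
        raise SchemaError(
            "no overlapping genes between kinetics table and count matrices"
            + (f"; kinetics-only genes e.g. {only_kin[:5]}" if only_kin else "")
        )
    out.index.name = "gene_id"
    return out


def _kinetics_wide(kinetics: pd.DataFrame) -> pd.DataFrame:
    req = {"gene_id", "allele", "k_on", "k_off", "k_syn"}
    if not req <= set(kinetics.columns):
        raise SchemaError(f"kinetics table needs columns {sorted(req)}")
    alleles = set(kinetics["allele"].unique())
    if not {"C57", "CAST"} <= alleles:
        raise SchemaError(f"kinetics table must carry alleles C57 and CAST, got {sorted(alleles)}")
    wide = kinetics.pivot_table(
        index="gene_id", columns="allele", values=["k_on", "k_off", "k_syn"], sort=False
    )
    wide.columns = [f"{p}_{a}" for p, a in wide.columns]
    return wide.dropna(
        subset=[f"{p}_{a}" for p in ("k_on", "k_off", "k_syn") for a in ("C57", "CAST")]
    )


def compare_predicted_observed(table: pd.DataFrame) -> dict[str, float]:
    """Spearman correlation between predicted and observed values per state.

    Ties receive average ranks. A state whose predicted or observed vector is
    constant has an undefined rank correlation and is reported as NaN.
    """
    if len(table) < 3:
        raise InsufficientDataError(f"need >= 3 genes, got {len(table)}")
    out = {}
    for state in STATES:
        p = table[f"p_{state}"].to_numpy(dtype=float)
        f = table[f"f_{state}"].to_numpy(dtype=float)
        keep = np.isfinite(p) & np.isfinite(f)
        if keep.sum() < 3 or np.ptp(p[keep]) == 0 or np.ptp(f[keep]) == 0:
            out[state] = float("nan")
            continue
        rho = stats.spearmanr(p[keep], f[keep]).statistic
        out[state] = float(rho)
    return out


def cross_validate(
    m_cast: AllelicCountMatrix,
    m_c57: AllelicCountMatrix,
    seed: int | None = None,
    *,
    min_cells: int = 20,
    max_fev: int = 2000,
) -> dict[str, float]:
    """Train/test validation of the state predictions.

    Cells are split into two random halves (train gets the extra cell when the
    count is odd). Kinetics are inferred per gene and allele on the training
    half; state probabilities predicted from those fits are correlated against
    the observed state fractions in the held-out half. Genes failing inference
    on either allele are dropped.
    """
    _check_aligned(m_cast, m_c57)
    n_cells = m_cast.n_cells
    if n_cells < 40:
        raise InsufficientDataError(f"need >= 40 cells for cross-validation, got {n_cells}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_cells)
    n_train = n_cells - n_cells // 2
    train, test = perm[:n_train], perm[n_train:]

    missing = m_cast.missing_mask | m_c57.missing_mask
    rows = []
    for gi, gene in enumerate(m_cast.gene_ids):
        usable_train = train[~missing[gi, train]]
        fits = {}
        try:
            for label, m in (("C57", m_c57), ("CAST", m_cast)):
                fit = infer_kinetics(
                    round_half_up(m.values[gi, usable_train]),
                    min_cells=min_cells,
                    max_fev=max_fev,
                )
                fits[label] = fit.kinetics
        except Exception:
            continue
        rows.extend(
            {
                "gene_id": gene,
                "allele": lab,
                "k_on": k.k_on,
                "k_off": k.k_off,
                "k_syn": k.k_syn,
            }
            for lab, k in fits.items()
        )
    kin = pd.DataFrame(rows)
    if kin.empty:
        raise InsufficientDataError("no gene passed inference on the training half")
    table = state_table(kin, m_cast.subset_cells(test), m_c57.subset_cells(test))
    return compare_predicted_observed(table)


def poisson_state_comparison(
    m_cast: AllelicCountMatrix, m_c57: AllelicCountMatrix
) -> pd.DataFrame:
    """State probabilities under the Poisson (non-bursting) baseline.

    The Poisson model sets each allele's silence probability to
    ``exp(-mean)`` with the allele's mean count over non-missing cells as the
    rate. Bursty genes have far more zeros than a Poisson with the same mean,
    so this baseline overestimates biallelic expression and underestimates
    silence.
    """
    obs = observed_state_fractions(m_cast, m_c57)
    p0_c57 = np.exp(-obs["mean_c57"].to_numpy(dtype=float))
    p0_cast = np.exp(-obs["mean_cast"].to_numpy(dtype=float))
    out = pd.DataFrame(
        np.column_stack([_probs_from_p0(a, b) for a, b in zip(p0_c57, p0_cast)]).T,
        columns=[f"p_{s}" for s in STATES],
        index=obs.index,
    )
    return pd.concat([out, obs], axis=1)


def _check_aligned(m_cast: AllelicCountMatrix, m_c57: AllelicCountMatrix) -> None:
    if m_cast.gene_ids != m_c57.gene_ids or m_cast.cell_ids != m_c57.cell_ids:
        raise SchemaError("CAST and C57 matrices must share gene and cell ids")
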