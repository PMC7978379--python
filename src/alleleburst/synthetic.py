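"""Synthetic allele-resolved count matrices with known ground-truth kinetics.

The generator emulates the structure of allele-resolved UMI matrices from an
F1 hybrid experiment: per-gene two-state kinetics, two independently bursting
alleles, optional allele-specific fold-changes in burst frequency and size,
optional mixtures of subpopulations with shifted kinetics, and a missing-data
mask marking cells with molecules but no allele-informative reads. Because the
truth is known per gene, allele and subpopulation, every downstream stage —
state prediction, bias probabilities, O/E heterogeneity, kinetics inference —
can be validated end to end without sequencing data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts import AllelicCountMatrix
from .errors import InvalidParameterError, SchemaError
from .two_state import TwoStateKinetics, sample

__all__ = ["Subpopulation", "PopulationSpec", "sample_kinetics_cloud", "generate_population"]


@dataclass(frozen=True)
class Subpopulation:
    """One mixture component of a synthetic cell population.

    ``multiplier`` rescales the kinetics of the genes in ``genes`` (integer
    row indices; None = all genes) for cells in this subpopulation.
    ``target`` selects the rescaled rate: ``k_on`` shifts burst frequency
    (the default, mimicking frequency-driven cell-type differences) and
    ``k_syn`` shifts burst size; a multiplier of 0 on ``k_syn`` silences the
    gene in this subpopulation.
    """

    weight: float
    multiplier: float = 1.0
    genes: tuple | None = None
    target: str = "k_on"

    def __post_init__(self) -> None:
        if not (self.weight > 0):
            raise InvalidParameterError(f"subpopulation weight must be > 0, got {self.weight}")
        if self.target not in ("k_on", "k_syn"):
            raise InvalidParameterError(f"target must be 'k_on' or 'k_syn', got {self.target!r}")
        if self.multiplier < 0 or (self.target == "k_on" and self.multiplier == 0):
            raise InvalidParameterError("multiplier must be positive (k_on) or >= 0 (k_syn)")


@dataclass(frozen=True)
class PopulationSpec:
    """Recipe for one synthetic dataset.

    Kinetics come either from ``kinetics`` (long table: gene_id, allele,
    k_on, k_off, k_syn) or are drawn from the log-uniform burst-parameter
    cloud spanned by ``bf_range`` / ``bs_range`` with synthesis rate capped at
    ``k_syn_cap``, identical on both alleles. ``bf_log2_fc`` / ``bs_log2_fc``
    apply per-gene allelic fold-changes to the C57 allele (burst-size changes
    act through ``k_off`` at fixed ``k_syn``). ``missingness`` is the
    probability that a cell with molecules lacks allele-informative reads.
    """

    n_genes: int
    n_cells: int
    seed: int = 0
    kinetics: pd.DataFrame | None = None
    bf_range: tuple[float, float] = (0.05, 5.0)
    bs_range: tuple[float, float] = (2.0, 100.0)
    k_syn_cap: float = 300.0
    bf_log2_fc: np.ndarray | None = None
    bs_log2_fc: np.ndarray | None = None
    subpopulations: tuple[Subpopulation, ...] = field(default_factory=tuple)
    missingness: float = 0.0

    def __post_init__(self) -> None:
        if self.n_genes < 0 or self.n_cells < 1:
            raise InvalidParameterError("need n_genes >= 0 and n_cells >= 1")
        if not (0.0 <= self.missingness < 1.0):
            raise InvalidParameterError(f"missingness must be in [0, 1), got {self.missingness}")
        if self.subpopulations:
            w = sum(s.weight for s in self.subpopulations)
            if abs(w - 1.0) > 1e-9:
                raise InvalidParameterError(f"subpopulation weights must sum to 1, got {w}")
        for name in ("bf_log2_fc", "bs_log2_fc"):
            v = getattr(self, name)
            if v is not None and len(v) != self.n_genes:
                raise InvalidParameterError(f"{name} must have length n_genes")


def sample_kinetics_cloud(
    n_genes: int,
    bf_range: tuple[float, float] = (0.05, 5.0),
    bs_range: tuple[float, float] = (2.0, 100.0),
    k_syn_cap: float = 300.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw per-gene kinetics spanning the bursty regime of real genes.

    Burst frequency and size are log-uniform over their ranges; ``k_syn`` is
    log-uniform between 1 and the cap (clamped so that ``k_off = k_syn / bs``
    stays inside [1e-3, 1e3]). Returns columns ``gene_id, k_on, k_off, k_syn,
    bf, bs, mean``.
    """
    if n_genes < 0:
        raise InvalidParameterError("n_genes must be >= 0")
    for lo, hi in (bf_range, bs_range):
        if not (0 < lo <= hi):
            raise InvalidParameterError("ranges must be positive and ordered")
    rng = np.random.default_rng(seed)
    bf = np.exp(rng.uniform(np.log(bf_range[0]), np.log(bf_range[1]), size=n_genes))
    bs = np.exp(rng.uniform(np.log(bs_range[0]), np.log(bs_range[1]), size=n_genes))
    s_lo = np.maximum(1.0, 1e-3 * bs)
    s_hi = np.maximum(s_lo, np.minimum(float(k_syn_cap), 1e3 * bs))
    k_syn = np.exp(rng.uniform(np.log(s_lo), np.log(s_hi)))
    k_off = k_syn / bs
    return pd.DataFrame(
        {
            "gene_id": [f"g{i:04d}" for i in range(n_genes)],
            "k_on": bf,
            "k_off": k_off,
            "k_syn": k_syn,
            "bf": bf,
            "bs": bs,
            "mean": k_syn * bf / (bf + k_off),
        }
    )


def _base_kinetics(spec: PopulationSpec) -> dict[str, list[TwoStateKinetics]]:
    """Per-allele baseline kinetics (before subpopulation multipliers)."""
    if spec.kinetics is not None:
        req = {"gene_id", "allele", "k_on", "k_off", "k_syn"}
        if not req <= set(spec.kinetics.columns):
            raise SchemaError(f"kinetics table needs columns {sorted(req)}")
        out: dict[str, list[TwoStateKinetics]] = {"C57": [], "CAST": []}
        by = spec.kinetics.set_index(["gene_id", "allele"])
        genes = spec.kinetics["gene_id"].unique()[: spec.n_genes]
        for g in genes:
            for allele in ("C57", "CAST"):
                row = by.loc[(g, allele)]
                out[allele].append(
                    TwoStateKinetics(float(row["k_on"]), float(row["k_off"]), float(row["k_syn"]))
                )
        return out
    cloud = sample_kinetics_cloud(
        spec.n_genes, spec.bf_range, spec.bs_range, spec.k_syn_cap, seed=spec.seed
    )
    cast = [
        TwoStateKinetics(r.k_on, r.k_off, r.k_syn) for r in cloud.itertuples(index=False)
    ]
    c57 = []
    for gi, kin in enumerate(cast):
        k_on, k_off, k_syn = kin.k_on, kin.k_off, kin.k_syn
        if spec.bf_log2_fc is not None:
            k_on = k_on * 2.0 ** float(spec.bf_log2_fc[gi])
        if spec.bs_log2_fc is not None:
            k_off = k_off / 2.0 ** float(spec.bs_log2_fc[gi])  # bs = k_syn/k_off
        c57.append(TwoStateKinetics(k_on, k_off, k_syn))
    return {"C57": c57, "CAST": cast}


def _apply_subpop(kin: TwoStateKinetics, sub: Subpopulation, gi: int) -> TwoStateKinetics:
    if sub.genes is not None and gi not in sub.genes:
        return kin
    if sub.target == "k_on":
        return TwoStateKinetics(kin.k_on * sub.multiplier, kin.k_off, kin.k_syn)
    return TwoStateKinetics(kin.k_on, kin.k_off, kin.k_syn * sub.multiplier)


def generate_population(
    spec: PopulationSpec,
) -> tuple[AllelicCountMatrix, AllelicCountMatrix, dict[str, pd.DataFrame]]:
    """Simulate allele-resolved count matrices from a population recipe.

    Each cell is assigned to a subpopulation by its weight; each gene-allele
    count is then drawn from the steady-state two-state sampler under that
    subpopulation's kinetics, with the two alleles independent. Missingness is
    applied only to cells with a positive total count for the gene, matching
    how real data loses allele information (UMIs without informative reads).

    Per-gene random streams are derived from ``(seed, gene index)``, so the
    output is invariant to gene iteration order.

    Returns ``(m_cast, m_c57, truth)`` where ``truth`` holds two tables:
    ``"kinetics"`` (generating kinetics per gene, allele and subpopulation)
    and ``"cells"`` (cell id and its subpopulation index).
    """
    base = _base_kinetics(spec)
    n_genes = len(base["CAST"])
    n_cells = spec.n_cells
    gene_ids = (
        list(spec.kinetics["gene_id"].unique()[:n_genes])
        if spec.kinetics is not None
        else [f"g{i:04d}" for i in range(n_genes)]
    )
    cell_ids = [f"cell{j:04d}" for j in range(n_cells)]

    subs = spec.subpopulations or (Subpopulation(weight=1.0),)
    rng_assign = np.random.default_rng([spec.seed, 0])
    weights = np.array([s.weight for s in subs])
    assignment = rng_assign.choice(len(subs), size=n_cells, p=weights / weights.sum())

    values = {a: np.zeros((n_genes, n_cells)) for a in ("C57", "CAST")}
    truth_rows = []
    for gi in range(n_genes):
        rng = np.random.default_rng([spec.seed, 1 + gi])
        for allele in ("C57", "CAST"):
            for si, sub in enumerate(subs):
                kin = _apply_subpop(base[allele][gi], sub, gi)
                cells = np.nonzero(assignment == si)[0]
                if cells.size:
                    values[allele][gi, cells] = sample(kin, cells.size, rng)
                truth_rows.append(
                    {
                        "gene_id": gene_ids[gi],
                        "allele": allele,
                        "subpopulation": si,
                        "weight": sub.weight,
                        "k_on": kin.k_on,
                        "k_off": kin.k_off,
                        "k_syn": kin.k_syn,
                    }
                )

    total = values["C57"] + values["CAST"]
    mask = np.zeros((n_genes, n_cells), dtype=bool)
    if spec.missingness > 0:
        rng_miss = np.random.default_rng([spec.seed, 1 + n_genes])
        mask = (rng_miss.random((n_genes, n_cells)) < spec.missingness) & (total > 0)
    vals_masked = {a: np.where(mask, 0.0, values[a]) for a in values}

    m_c57 = AllelicCountMatrix(vals_masked["C57"], gene_ids, cell_ids, "C57", mask.copy())
    m_cast = AllelicCountMatrix(vals_masked["CAST"], gene_ids, cell_ids, "CAST", mask.copy())
    truth = {
        "kinetics": pd.DataFrame(truth_rows),
        "cells": pd.DataFrame({"cell_id": cell_ids, "subpopulation": assignment}),
    }
    return m_cast, m_c57, truth
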