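"""Allele-resolved UMI count matrices and their construction from read fractions.

UMI counting protocols count molecules per gene and cell but do not genotype
each UMI. Allelic molecule counts are therefore derived by multiplying the
total UMI count of a gene in a cell by the fraction of reads supporting the
CAST allele; the remaining fraction is assigned to C57. Cells with UMIs for a
gene but no allele-informative reads carry no allelic information at all and
are flagged missing — they are excluded from observed-state fractions and from
kinetics inference for that gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .errors import SchemaError

__all__ = ["AllelicCountMatrix", "assign_allelic_counts", "read_matrix", "write_matrix"]


@dataclass
class AllelicCountMatrix:
    """Gene x cell molecule counts for one allele, with a shared missing mask.

    ``values`` are non-negative reals (the read-fraction rule produces
    fractional molecule counts). ``missing_mask`` is True where the cell had
    UMIs for the gene but no allele-informative reads; such entries are
    uninformative and the stored value there is 0 by convention.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    allele: str = "unknown"
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise SchemaError("values must be a 2-D gene x cell matrix")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise SchemaError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise SchemaError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise SchemaError("duplicate cell ids")
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.values.shape:
                raise SchemaError("missing_mask shape does not match values")
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise SchemaError("values must be finite and non-negative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Dense DataFrame view (genes as rows); missing entries become NaN."""
        vals = self.values.copy()
        vals[self.missing_mask] = np.nan
        return pd.DataFrame(vals, index=self.gene_ids, columns=self.cell_ids)

    def subset_cells(self, cells: np.ndarray | list) -> "AllelicCountMatrix":
        """Column subset by integer positions or cell ids (order preserved)."""
        idx = _cell_indexer(self.cell_ids, cells)
        return replace(
            self,
            values=self.values[:, idx],
            cell_ids=[self.cell_ids[i] for i in idx],
            missing_mask=self.missing_mask[:, idx],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AllelicCountMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.cell_ids == other.cell_ids
            and self.allele == other.allele
            and np.array_equal(self.values, other.values)
            and np.array_equal(self.missing_mask, other.missing_mask)
        )


def _cell_indexer(cell_ids: list[str], cells) -> np.ndarray:
    cells = list(cells)
    if len(cells) == 0:
        return np.array([], dtype=int)
    if all(isinstance(c, (int, np.integer)) for c in cells):
        return np.asarray(cells, dtype=int)
    pos = {c: i for i, c in enumerate(cell_ids)}
    missing = [c for c in cells if c not in pos]
    if missing:
        raise SchemaError(f"unknown cell ids: {missing[:5]}")
    return np.array([pos[c] for c in cells], dtype=int)


def assign_allelic_counts(
    total_umis: np.ndarray,
    cast_read_fraction: np.ndarray,
    gene_ids: list[str] | None = None,
    cell_ids: list[str] | None = None,
) -> tuple[AllelicCountMatrix, AllelicCountMatrix]:
    """Split total UMI counts into CAST and C57 allelic counts.

    ``CAST = fraction * total`` and ``C57 = total - CAST``. Entries with a
    positive total but an undefined (NaN) fraction are flagged missing on both
    alleles; entries with zero total are genuine (0, 0) observations.

    Returns ``(cast, c57)`` matrices sharing gene ids, cell ids and mask.
    """
    total = np.asarray(total_umis, dtype=float)
    frac = np.asarray(cast_read_fraction, dtype=float)
    if total.shape != frac.shape:
        raise SchemaError(f"shape mismatch: totals {total.shape} vs fractions {frac.shape}")
    if np.any(total < 0) or np.any(~np.isfinite(total)):
        raise SchemaError("total_umis must be finite and non-negative")
    defined = np.isfinite(frac)
    if np.any((frac[defined] < 0) | (frac[defined] > 1)):
        raise SchemaError("cast_read_fraction must lie in [0, 1] where defined")
    n_genes, n_cells = total.shape
    gene_ids = gene_ids if gene_ids is not None else [f"g{i}" for i in range(n_genes)]
    cell_ids = cell_ids if cell_ids is not None else [f"c{j}" for j in range(n_cells)]

    missing = (total > 0) & ~defined
    frac_filled = np.where(defined, frac, 0.0)
    cast_vals = np.where(missing, 0.0, frac_filled * total)
    c57_vals = np.where(missing, 0.0, total - frac_filled * total)
    cast = AllelicCountMatrix(cast_vals, gene_ids, cell_ids, "CAST", missing.copy())
    c57 = AllelicCountMatrix(c57_vals, gene_ids, cell_ids, "C57", missing.copy())
    return cast, c57


def write_matrix(m: AllelicCountMatrix, path: str, format: str = "tsv") -> None:
    """Serialize a count matrix as TSV or MatrixMarket.

    TSV: genes as rows, header of cell ids, first column gene ids; missing
    entries written as ``NA``. MTX: ``<prefix>.mtx`` with ``.genes.txt`` /
    ``.cells.txt`` sidecars and ``<prefix>.missing.mtx`` when any entry is
    missing.
    """
    if format == "tsv":
        m.to_frame().to_csv(path, sep="\t", index_label="gene_id", na_rep="NA")
    elif format == "mtx":
        prefix = _strip_mtx_suffix(path)
        spio.mmwrite(f"{prefix}.mtx", sparse.coo_matrix(m.values))
        with open(f"{prefix}.genes.txt", "w") as fh:
            fh.write("\n".join(m.gene_ids) + "\n")
        with open(f"{prefix}.cells.txt", "w") as fh:
            fh.write("\n".join(m.cell_ids) + "\n")
        if m.missing_mask.any():
            spio.mmwrite(f"{prefix}.missing.mtx", sparse.coo_matrix(m.missing_mask.astype(np.int8)))
    else:
        raise SchemaError(f"unknown format {format!r}; expected 'tsv' or 'mtx'")


def read_matrix(path: str, format: str = "tsv", allele: str = "unknown") -> AllelicCountMatrix:
    """Read a count matrix written by :func:`write_matrix` (exact round trip)."""
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        except Exception as exc:  # malformed file
            raise SchemaError(f"cannot parse TSV matrix {path}: {exc}") from exc
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate gene ids in {path}: {dupes[:5]}")
        if df.columns.has_duplicates:
            raise SchemaError(f"duplicate cell ids in {path}")
        vals = df.to_numpy(dtype=float)  # non-numeric entries raise here
        mask = np.isnan(vals)
        vals = np.nan_to_num(vals, nan=0.0)
        if np.any(vals < 0):
            raise SchemaError(f"negative counts in {path}")
        return AllelicCountMatrix(vals, list(df.index), [str(c) for c in df.columns], allele, mask)
    elif format == "mtx":
        prefix = _strip_mtx_suffix(path)
        vals = np.asarray(spio.mmread(f"{prefix}.mtx").todense(), dtype=float)
        gene_ids = _read_lines(f"{prefix}.genes.txt")
        cell_ids = _read_lines(f"{prefix}.cells.txt")
        import os

        mask = None
        if os.path.exists(f"{prefix}.missing.mtx"):
            mask = np.asarray(spio.mmread(f"{prefix}.missing.mtx").todense()).astype(bool)
        return AllelicCountMatrix(vals, gene_ids, cell_ids, allele, mask)
    raise SchemaError(f"unknown format {format!r}; expected 'tsv' or 'mtx'")


def _strip_mtx_suffix(path: str) -> str:
    return path[:-4] if path.endswith(".mtx") else path


def _read_lines(path: str) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]
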