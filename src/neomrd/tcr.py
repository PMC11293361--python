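"""Clonotype construction and clonal-expansion statistics from single-cell TCR data.

A clonotype is a set of T cells sharing an identical paired alpha/beta chain
(same V gene, J gene, and CDR3 nucleotide sequence on each chain).  Contigs
enter the analysis only if productive, high-confidence and full-length with
a valid barcode and an unambiguous chain.  Clone size is counted over the
whole table; a cell contributes to its own subtype's statistics, so a clone
spanning two subtypes counts toward both — this is what makes cross-subtype
expansion correlation informative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ClonotypeTable",
    "ExpansionStats",
    "build_clonotypes",
    "expanded_ratio",
    "expanded_clones",
    "expansion_correlation",
]

_REQUIRED = ["barcode", "chain", "cdr3_nt", "v_gene", "j_gene",
             "productive", "high_confidence", "full_length"]


@dataclass(frozen=True)
class ClonotypeTable:
    """Cell-level clonotype assignments.

    ``cells`` has one row per retained cell: barcode, clonotype_id, and
    (if annotations were provided) subtype.  ``n_ambiguous_dropped`` counts
    cells discarded for conflicting duplicate beta chains.
    """

    cells: pd.DataFrame
    n_ambiguous_dropped: int

    def clone_sizes(self) -> pd.Series:
        return self.cells.groupby("clonotype_id").size()

    def __len__(self) -> int:
        return len(self.cells)


@dataclass(frozen=True)
class ExpansionStats:
    subtype: str
    threshold: int
    expanded_ratio: float
    n_expanded_clones: int
    n_cells: int


def _truthy(col: pd.Series) -> pd.Series:
    if col.dtype == bool:
        return col
    return col.astype(str).str.lower().isin({"true", "t", "yes", "1"})


def build_clonotypes(
    contigs: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
    aa_level: bool = False,
) -> ClonotypeTable:
    """Group cells into clonotypes by identical paired alpha/beta chains.

    Filters to productive, high-confidence, full-length contigs with a valid
    barcode and chain in {TRA, TRB}; cells lacking a productive pair are
    excluded.  Cells with multiple productive alphas keep the highest-UMI
    alpha (10x convention); cells with conflicting duplicate betas are
    dropped as ambiguous, with the count reported.  ``aa_level=True`` keys
    clonotypes on the amino-acid CDR3 (column ``cdr3``) instead of the
    nucleotide sequence.
    """
    missing = [c for c in _REQUIRED if c not in contigs.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    cdr_col = "cdr3" if aa_level else "cdr3_nt"
    if cdr_col not in contigs.columns:
        raise ValueError(f"missing required column: {cdr_col}")
    keep = (
        _truthy(contigs["productive"])
        & _truthy(contigs["high_confidence"])
        & _truthy(contigs["full_length"])
        & contigs["barcode"].notna()
        & (contigs["barcode"].astype(str) != "")
        & contigs["chain"].isin(["TRA", "TRB"])
        & contigs[cdr_col].notna()
        & (contigs[cdr_col].astype(str) != "")
    )
    good = contigs.loc[keep].copy()
    if "umis" not in good.columns:
        good["umis"] = 1

    rows = []
    n_ambiguous = 0
    for bc, cell in good.groupby("barcode", sort=True):
        alphas = cell[cell["chain"] == "TRA"]
        betas = cell[cell["chain"] == "TRB"]
        if alphas.empty or betas.empty:
            continue  # no productive pair
        if betas[cdr_col].nunique() > 1:
            n_ambiguous += 1  # conflicting duplicate beta: likely doublet
            continue
        alpha = alphas.sort_values(["umis", cdr_col], ascending=[False, True]).iloc[0]
        beta = betas.sort_values(["umis", cdr_col], ascending=[False, True]).iloc[0]
        key = (
            ("TRA", alpha["v_gene"], alpha["j_gene"], alpha[cdr_col]),
            ("TRB", beta["v_gene"], beta["j_gene"], beta[cdr_col]),
        )
        rows.append({"barcode": bc, "clonotype_key": key})
    cells = pd.DataFrame(rows, columns=["barcode", "clonotype_key"])
    if len(cells) > 0 and cells["barcode"].duplicated().any():
        raise ValueError("duplicate barcodes after grouping")  # defensive

    # stable ids in order of first appearance
    ids: dict[tuple, str] = {}
    for key in cells["clonotype_key"]:
        if key not in ids:
            ids[key] = f"ct{len(ids) + 1:05d}"
    cells["clonotype_id"] = cells["clonotype_key"].map(ids)
    cells = cells.drop(columns=["clonotype_key"])

    if annotations is not None:
        ann = annotations[["barcode", "subtype"]].drop_duplicates("barcode")
        cells = cells.merge(ann, on="barcode", how="left")
    return ClonotypeTable(cells=cells, n_ambiguous_dropped=n_ambiguous)


def expanded_ratio(
    table: ClonotypeTable, subtype: str, threshold: int = 3
) -> ExpansionStats:
    """Fraction of a subtype's cells in clonotypes of size >= threshold.

    Clone size is counted across the whole table (a clone may span
    subtypes); each cell is attributed to its own subtype.
    """
    if "subtype" not in table.cells.columns:
        raise ValueError("table has no subtype annotations")
    cells = table.cells
    if subtype not in set(cells["subtype"].dropna()):
        raise ValueError(f"unknown subtype: {subtype!r}")
    sizes = table.clone_sizes()
    sub = cells[cells["subtype"] == subtype]
    in_expanded = sub["clonotype_id"].map(sizes) >= threshold
    expanded_ids = set(sub.loc[in_expanded, "clonotype_id"])
    return ExpansionStats(
        subtype=subtype,
        threshold=threshold,
        expanded_ratio=float(in_expanded.mean()) if len(sub) else 0.0,
        n_expanded_clones=len(expanded_ids),
        n_cells=len(sub),
    )


def expanded_clones(
    table: ClonotypeTable, subtype: str, min_size: int = 3
) -> list[str]:
    """Clonotypes containing >= 1 cell of ``subtype`` with total size >= min_size.

    Thresholds in practice differ by lineage: exhausted CD8 T clones are
    called expanded at >= 10 cells, regulatory T clones at >= 3 (Tregs
    expand less).
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if "subtype" not in table.cells.columns:
        raise ValueError("table has no subtype annotations")
    sizes = table.clone_sizes()
    cells = table.cells
    with_subtype = cells.loc[cells["subtype"] == subtype, "clonotype_id"].unique()
    return sorted(cid for cid in with_subtype if sizes[cid] >= min_size)


def expansion_correlation(
    table: ClonotypeTable, subtypes: list[str] | None = None
) -> pd.DataFrame:
    """Pairwise Pearson correlation of clonal expansion between subtypes.

    For each clonotype, the per-subtype cell counts are log1p-transformed;
    the correlation for a subtype pair is Pearson's r of those vectors
    across clonotypes.  Diagonal is 1; subtypes with zero cells give NaN
    rows (explicitly undefined).
    """
    if "subtype" not in table.cells.columns:
        raise ValueError("table has no subtype annotations")
    if subtypes is None:
        subtypes = sorted(table.cells["subtype"].dropna().unique())
    if len(subtypes) < 2:
        raise ValueError("need at least 2 subtypes")
    counts = (
        table.cells.pivot_table(
            index="clonotype_id", columns="subtype", values="barcode",
            aggfunc="count", fill_value=0,
        )
        .reindex(columns=subtypes, fill_value=0)
    )
    logged = np.log1p(counts.to_numpy(dtype=float))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(logged, rowvar=False)
    r = np.atleast_2d(r)
    np.fill_diagonal(r, 1.0)
    zero = counts.sum(axis=0).to_numpy() == 0
    r[zero, :] = np.nan
    r[:, zero] = np.nan
    return pd.DataFrame(r, index=subtypes, columns=subtypes)
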