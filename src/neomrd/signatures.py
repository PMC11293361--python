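"""Marker-signature scoring of expression data and survival stratification.

Two marker sets define the immune phenotype of interest: an activated
regulatory T cell signature (FOXP3, IL2RA, CCR8) and an exhausted T cell
signature (HAVCR2, PDCD1, LAG3, CXCL13, TIGIT, CTLA4, ENTPD1, LAYN).  Bulk
samples are scored per sample with a rank-based single-sample enrichment
statistic (ssGSEA), split at the cohort median into high/low strata, and the
strata compared on survival (log-rank) and response (Fisher).  For cell-level
matrices a binned-control module score (Seurat-style AddModuleScore) and the
standard cell/gene QC filters are provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as cstats

__all__ = [
    "GeneSet",
    "CellQcThresholds",
    "SignatureScore",
    "CCR8_TREG",
    "CXCL13_TEX",
    "qc_filter_cells",
    "ssgsea_score",
    "module_score",
    "median_split",
    "stratify_and_test",
    "phenotype_quadrants",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError("gene set must be nonempty")

    def present_in(self, universe) -> tuple[str, ...]:
        u = set(universe)
        return tuple(g for g in self.genes if g in u)


CCR8_TREG = GeneSet("CCR8_Treg", ("FOXP3", "IL2RA", "CCR8"))
CXCL13_TEX = GeneSet(
    "CXCL13_Tex",
    ("HAVCR2", "PDCD1", "LAG3", "CXCL13", "TIGIT", "CTLA4", "ENTPD1", "LAYN"),
)


@dataclass(frozen=True)
class CellQcThresholds:
    """Cell and gene quality-control bounds for droplet scRNA data."""

    umi_min: int = 1000
    umi_max: int = 40000
    genes_min: int = 600
    genes_max: int = 5000
    mito_max: float = 0.10  # strict: fraction must be < this
    min_cells_per_gene: int = 200
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if self.umi_min >= self.umi_max or self.genes_min >= self.genes_max:
            raise ValueError("lower QC bounds must be below upper bounds")


@dataclass(frozen=True)
class SignatureScore:
    sample_id: str
    set_name: str
    score: float
    stratum: str  # "high" | "low"


def qc_filter_cells(
    matrix: pd.DataFrame, thresholds: CellQcThresholds | None = None
) -> tuple[pd.DataFrame, dict]:
    """Apply cell-level then gene-level QC to a genes x cells count matrix.

    Cells are kept iff total UMI is within [umi_min, umi_max], detected gene
    count within [genes_min, genes_max], and mitochondrial fraction strictly
    below mito_max; afterwards genes detected in fewer than
    ``min_cells_per_gene`` of the surviving cells are removed.  Returns the
    filtered matrix and a report dict of what was removed.
    """
    th = thresholds or CellQcThresholds()
    counts = matrix.to_numpy(dtype=float)
    umi = counts.sum(axis=0)
    n_genes = (counts > 0).sum(axis=0)
    mito_mask = matrix.index.astype(str).str.upper().str.startswith(
        th.mito_prefix.upper()
    )
    with np.errstate(invalid="ignore"):
        mito_frac = np.where(umi > 0, counts[mito_mask].sum(axis=0) / umi, 0.0)
    keep_cells = (
        (umi >= th.umi_min) & (umi <= th.umi_max)
        & (n_genes >= th.genes_min) & (n_genes <= th.genes_max)
        & (mito_frac < th.mito_max)
    )
    filtered = matrix.loc[:, keep_cells]
    detected_in = (filtered.to_numpy() > 0).sum(axis=1)
    keep_genes = detected_in >= th.min_cells_per_gene
    filtered = filtered.loc[keep_genes]
    if filtered.shape[0] == 0 or filtered.shape[1] == 0:
        raise ValueError("QC removed every cell or every gene")
    report = {
        "n_cells_in": matrix.shape[1],
        "n_cells_kept": int(keep_cells.sum()),
        "n_genes_in": matrix.shape[0],
        "n_genes_kept": int(keep_genes.sum()),
    }
    return filtered, report


def _ssgsea_single(values: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    # order genes by expression, descending; stable so ties keep input order
    order = np.argsort(-values, kind="stable")
    in_sorted = in_set[order]
    n = len(values)
    ranks = np.arange(n, 0, -1, dtype=float)  # n for the top gene, 1 for bottom
    w = np.where(in_sorted, ranks**alpha, 0.0)
    sum_in = w.sum()
    n_out = n - int(in_set.sum())
    p_in = np.cumsum(w) / sum_in
    p_out = np.cumsum(~in_sorted) / n_out
    return float(np.sum(p_in - p_out))


def ssgsea_score(
    expression: pd.DataFrame | pd.Series,
    gene_set: GeneSet,
    alpha: float = 0.25,
    normalize: bool = False,
) -> pd.Series:
    """Single-sample gene-set enrichment score (rank-based running sum).

    Genes are ranked by expression within each sample (descending); the
    score is the sum over ranks of the difference between the weighted
    cumulative fraction of set members (weight = rank^alpha) and the
    unweighted cumulative fraction of non-members.  Depends only on gene
    ranks, hence invariant under strictly monotone transforms of expression.
    ``normalize=True`` min-max rescales scores across samples.
    """
    if isinstance(expression, pd.Series):
        expression = expression.to_frame("sample")
    universe = expression.index
    present = gene_set.present_in(universe)
    if len(present) == 0:
        raise ValueError(f"gene set {gene_set.name!r} shares no genes with the matrix")
    if len(present) >= len(universe):
        raise ValueError("gene set equals the whole gene universe")
    if len(universe) < 2:
        raise ValueError("need at least 2 genes")
    in_set = np.asarray(universe.isin(present))
    x = expression.to_numpy(dtype=float)
    scores = np.array(
        [_ssgsea_single(x[:, j], in_set, alpha) for j in range(x.shape[1])]
    )
    if normalize and len(scores) > 1:
        lo, hi = scores.min(), scores.max()
        if hi > lo:
            scores = (scores - lo) / (hi - lo)
    return pd.Series(scores, index=expression.columns, name=gene_set.name)


def module_score(
    matrix: pd.DataFrame,
    gene_set: GeneSet,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    bin_means: pd.Series | None = None,
) -> pd.Series:
    """Binned-control module score per cell (Seurat AddModuleScore style).

    Genes are binned by average expression; for each set gene, ``n_ctrl``
    control genes are sampled (with replacement) from its bin, excluding the
    set genes themselves.  The score is mean(set genes) - mean(control
    genes) per cell.  ``bin_means`` optionally supplies the per-gene
    averages used for binning (e.g. from a reference condition); by default
    the matrix's own means are used.  Set genes absent from the matrix are
    skipped with a warning.
    """
    import warnings

    present = gene_set.present_in(matrix.index)
    absent = set(gene_set.genes) - set(present)
    if absent:
        warnings.warn(f"genes absent from matrix, skipped: {sorted(absent)}")
    if not present:
        raise ValueError("no set genes present in the matrix")
    rng = np.random.default_rng(seed)
    means = matrix.mean(axis=1) if bin_means is None else bin_means.loc[matrix.index]
    # rank-based equal-frequency bins, as many as distinct values allow
    bins = pd.qcut(means.rank(method="first"), q=min(n_bins, len(means)),
                   labels=False)
    bins = pd.Series(bins, index=matrix.index)
    in_set = bins.index.isin(present)
    ctrl_genes: list[str] = []
    for g in present:
        pool = bins.index[(bins == bins[g]).to_numpy() & ~in_set]
        if len(pool) == 0:
            pool = bins.index[(bins == bins[g]).to_numpy()]
        ctrl_genes.extend(rng.choice(pool, size=n_ctrl, replace=True))
    set_mean = matrix.loc[list(present)].mean(axis=0)
    ctrl_mean = matrix.loc[ctrl_genes].mean(axis=0)
    return (set_mean - ctrl_mean).rename(f"{gene_set.name}_module")


def median_split(scores: pd.Series) -> pd.Series:
    """High/low strata at the cohort median; ties at the median go to low."""
    med = scores.median()
    return pd.Series(
        np.where(scores > med, "high", "low"), index=scores.index, name="stratum"
    )


def stratify_and_test(
    scores: pd.Series,
    survival: pd.DataFrame | None = None,
    response: pd.Series | None = None,
    id_col: str = "id",
):
    """Median-split strata with survival and/or response comparisons.

    Returns a dict with the strata, the log-rank (chi2, p) against the
    survival table if given, and the 2x2 Fisher p for response if given.
    Degenerate strata (all scores equal) skip the tests with a note.
    """
    strata = median_split(scores)
    out: dict = {"strata": strata, "skipped": []}
    if strata.nunique() < 2 or strata.value_counts().min() < 2:
        out["skipped"].append("degenerate strata: tests skipped")
        return out
    if survival is not None:
        surv = survival.set_index(id_col).loc[strata.index].reset_index()
        surv = surv.assign(group=strata.to_numpy())
        curves, chi2, p = cstats.km_logrank(surv)
        out["km_curves"] = curves
        out["logrank_chi2"] = chi2
        out["logrank_p"] = p
    if response is not None:
        resp = response.loc[strata.index].astype(bool)
        table = pd.crosstab(strata, resp)
        if table.shape == (2, 2):
            out["response_fisher_p"] = cstats.fisher_exact_2x2(table.to_numpy())
        else:
            out["skipped"].append("response constant within a stratum")
    return out


def phenotype_quadrants(scores: pd.DataFrame) -> pd.Series:
    """Joint high/low quadrant labels from two signature score columns.

    E.g. columns (CCR8_Treg, CXCL13_Tex) yield labels like
    "CCR8_Treg^hi/CXCL13_Tex^lo".
    """
    if scores.shape[1] != 2:
        raise ValueError("exactly two signature columns required")
    a, b = scores.columns
    sa, sb = median_split(scores[a]), median_split(scores[b])
    lab = {"high": "hi", "low": "lo"}
    return pd.Series(
        [f"{a}^{lab[x]}/{b}^{lab[y]}" for x, y in zip(sa, sb)],
        index=scores.index,
        name="phenotype",
    )
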