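"""Single-cell RNA-seq quality control, marker statistics and enrichment.

Implements the rule-based stages of a droplet scRNA-seq analysis:

* gene/cell QC filtering (ribosomal-gene exclusion, minimum cells per gene,
  minimum unique features per cell, a mean + 3 SD transcript-count cap, and
  a mitochondrial-fraction ceiling);
* per-cell library-size normalization with log1p;
* two-group Wilcoxon rank-sum marker detection gated on |logFC| > 0.25 with
  Benjamini-Hochberg adjustment over the tested genes;
* cluster-proportion accounting per treatment group;
* hypergeometric overrepresentation of a query gene list against annotation
  sets.

Dimensionality reduction, graph clustering and cell-type annotation are out
of scope; cluster labels are inputs here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "QCParams",
    "QCReport",
    "MarkerParams",
    "qc_filter",
    "log_normalize",
    "ranksum_test",
    "wilcoxon_markers",
    "cluster_proportions",
    "hypergeometric_enrichment",
]


@dataclass
class CountMatrix:
    """Genes x cells integer count matrix with symbols and cell labels.

    ``counts`` may be dense or scipy.sparse; ``cell_group`` (treatment) and
    ``cell_cluster`` are optional per-cell categorical labels.
    """

    counts: np.ndarray | sparse.spmatrix
    gene_symbols: np.ndarray
    cell_ids: np.ndarray
    cell_group: np.ndarray | None = None
    cell_cluster: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gene_symbols = np.asarray(self.gene_symbols, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        n_genes, n_cells = self.counts.shape
        if len(self.gene_symbols) != n_genes:
            raise ValueError("gene_symbols length must match the gene axis")
        if len(self.cell_ids) != n_cells:
            raise ValueError("cell_ids length must match the cell axis")
        if len(set(self.gene_symbols)) != n_genes:
            raise ValueError("gene symbols must be unique")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("cell ids must be unique")
        for name in ("cell_group", "cell_cluster"):
            val = getattr(self, name)
            if val is not None:
                val = np.asarray(val, dtype=object)
                if len(val) != n_cells:
                    raise ValueError(f"{name} length must match the cell axis")
                setattr(self, name, val)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def dense(self) -> np.ndarray:
        c = self.counts
        return c.toarray() if sparse.issparse(c) else np.asarray(c)

    def subset(self, gene_idx: np.ndarray, cell_idx: np.ndarray) -> "CountMatrix":
        counts = self.counts
        if sparse.issparse(counts):
            counts = counts.tocsr()[gene_idx][:, cell_idx]
        else:
            counts = counts[np.ix_(gene_idx, cell_idx)]
        return CountMatrix(
            counts=counts,
            gene_symbols=self.gene_symbols[gene_idx],
            cell_ids=self.cell_ids[cell_idx],
            cell_group=None if self.cell_group is None else self.cell_group[cell_idx],
            cell_cluster=None if self.cell_cluster is None else self.cell_cluster[cell_idx],
        )


@dataclass(frozen=True)
class QCParams:
    """Thresholds of the QC filter.

    Defaults: genes detected in < 3 cells and ribosomal genes (Rps/Rpl
    prefixes) are dropped; cells with < 200 unique features, more than
    mean + 3 SD total transcripts, or > 5% mitochondrial counts (mt- prefix)
    are dropped. ``count_cap_scope`` selects whether the mean/SD of the
    transcript cap is computed per sample group or pooled over all cells.
    """

    min_cells_per_gene: int = 3
    min_features_per_cell: int = 200
    max_counts_sd_mult: float = 3.0
    max_mito_fraction: float = 0.05
    mito_prefix: str = "mt-"
    ribo_prefixes: tuple[str, ...] = ("Rps", "Rpl")
    count_cap_scope: str = "per_group"  # or "pooled"

    def __post_init__(self) -> None:
        if self.min_cells_per_gene <= 0 or self.min_features_per_cell <= 0:
            raise ValueError("gene/feature thresholds must be > 0")
        if self.max_counts_sd_mult <= 0:
            raise ValueError("max_counts_sd_mult must be > 0")
        if not 0 < self.max_mito_fraction < 1:
            raise ValueError("max_mito_fraction must lie in (0, 1)")
        if self.count_cap_scope not in ("per_group", "pooled"):
            raise ValueError("count_cap_scope must be 'per_group' or 'pooled'")


@dataclass
class QCReport:
    """Bookkeeping of what the QC filter removed and why."""

    n_genes_in: int = 0
    n_cells_in: int = 0
    genes_removed_ribosomal: int = 0
    genes_removed_low_cells: int = 0
    cells_removed_low_features: int = 0
    cells_removed_high_counts: int = 0
    cells_removed_high_mito: int = 0
    n_genes_out: int = 0
    n_cells_out: int = 0
    mito_criterion_skipped: bool = False
    count_caps: dict = field(default_factory=dict)  # group -> mean + k*SD cap

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("genes_in", self.n_genes_in),
            ("cells_in", self.n_cells_in),
            ("genes_removed_ribosomal", self.genes_removed_ribosomal),
            ("genes_removed_low_cells", self.genes_removed_low_cells),
            ("cells_removed_low_features", self.cells_removed_low_features),
            ("cells_removed_high_counts", self.cells_removed_high_counts),
            ("cells_removed_high_mito", self.cells_removed_high_mito),
            ("genes_out", self.n_genes_out),
            ("cells_out", self.n_cells_out),
            ("mito_criterion_skipped", int(self.mito_criterion_skipped)),
        ]
        return pd.DataFrame(rows, columns=["quantity", "value"])


@dataclass(frozen=True)
class MarkerParams:
    """Gates and conventions of marker detection.

    ``min_abs_logfc`` and ``padj_threshold`` are the reporting gates; the
    fold change is computed in natural-log units on means of de-logged
    normalized expression with a pseudocount of 1, after per-cell scaling to
    ``scale_factor`` total counts.
    """

    min_abs_logfc: float = 0.25
    padj_threshold: float = 0.05
    scale_factor: float = 1e4
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.min_abs_logfc < 0:
            raise ValueError("min_abs_logfc must be >= 0")
        if not 0 < self.padj_threshold < 1:
            raise ValueError("padj_threshold must lie in (0, 1)")


def _starts_with_any(symbols: np.ndarray, prefixes: tuple[str, ...]) -> np.ndarray:
    lowered = np.array([str(s).lower() for s in symbols])
    out = np.zeros(len(symbols), dtype=bool)
    for p in prefixes:
        out |= np.char.startswith(lowered, p.lower())
    return out


def qc_filter(matrix: CountMatrix, params: QCParams = QCParams()) -> tuple[CountMatrix, QCReport]:
    """Apply the gene-level then cell-level QC rules.

    Gene stage: drop ribosomal genes and genes detected (count > 0) in fewer
    than ``min_cells_per_gene`` cells. Cell stage, computed on the
    gene-filtered matrix (mitochondrial genes survive the gene stage): drop
    cells with fewer than ``min_features_per_cell`` detected genes, total
    counts above mean + ``max_counts_sd_mult`` SD (mean/SD over cells that
    pass the other two criteria, per group by default), or mitochondrial
    fraction above ``max_mito_fraction``.

    Raises ``ValueError`` if no genes or no cells survive. If no gene
    matches the mitochondrial prefix, that criterion is skipped with a
    warning and recorded in the report.
    """
    report = QCReport(n_genes_in=matrix.n_genes, n_cells_in=matrix.n_cells)
    counts = matrix.counts.tocsr() if sparse.issparse(matrix.counts) else np.asarray(matrix.counts)

    detected = (counts > 0).sum(axis=1)
    detected = np.asarray(detected).ravel()
    ribo = _starts_with_any(matrix.gene_symbols, params.ribo_prefixes)
    low_cells = detected < params.min_cells_per_gene
    report.genes_removed_ribosomal = int(ribo.sum())
    report.genes_removed_low_cells = int((low_cells & ~ribo).sum())
    keep_genes = np.flatnonzero(~(ribo | low_cells))
    if keep_genes.size == 0:
        raise ValueError("no genes survive the gene-level QC filters")

    gm = matrix.subset(keep_genes, np.arange(matrix.n_cells))
    gcounts = gm.counts.tocsr() if sparse.issparse(gm.counts) else np.asarray(gm.counts)
    totals = np.asarray(gcounts.sum(axis=0)).ravel().astype(float)
    features = np.asarray((gcounts > 0).sum(axis=0)).ravel()
    mito = _starts_with_any(gm.gene_symbols, (params.mito_prefix,))
    if mito.any():
        mito_counts = np.asarray(gcounts[mito].sum(axis=0)).ravel().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(totals > 0, mito_counts / totals, 0.0)
        fail_mito = mito_frac > params.max_mito_fraction
    else:
        warnings.warn(
            f"no gene symbol starts with {params.mito_prefix!r}; the mitochondrial "
            "criterion is skipped",
            UserWarning,
            stacklevel=2,
        )
        report.mito_criterion_skipped = True
        fail_mito = np.zeros(gm.n_cells, dtype=bool)

    fail_features = features < params.min_features_per_cell

    # mean + k*SD cap computed over cells passing the other criteria
    eligible = ~(fail_features | fail_mito)
    fail_counts = np.zeros(gm.n_cells, dtype=bool)
    if gm.cell_group is not None and params.count_cap_scope == "per_group":
        groups = pd.unique(gm.cell_group)
    else:
        groups = [None]
    for g in groups:
        in_g = np.ones(gm.n_cells, dtype=bool) if g is None else (gm.cell_group == g)
        base = totals[in_g & eligible]
        if base.size == 0:
            continue
        cap = base.mean() + params.max_counts_sd_mult * base.std(ddof=0)
        report.count_caps[str(g)] = float(cap)
        fail_counts |= in_g & (totals > cap)

    report.cells_removed_low_features = int(fail_features.sum())
    report.cells_removed_high_counts = int(fail_counts.sum())
    report.cells_removed_high_mito = int(fail_mito.sum())
    keep_cells = np.flatnonzero(~(fail_features | fail_counts | fail_mito))
    if keep_cells.size == 0:
        raise ValueError("no cells survive the cell-level QC filters")

    out = gm.subset(np.arange(gm.n_genes), keep_cells)
    report.n_genes_out = out.n_genes
    report.n_cells_out = out.n_cells
    return out, report


def log_normalize(matrix: CountMatrix, scale_factor: float = 1e4) -> np.ndarray:
    """Library-size normalization: per cell, counts / total * scale_factor,
    then natural log1p. Returns a dense genes x cells float array. Cells
    with zero total counts map to all-zero columns."""
    counts = matrix.dense().astype(float)
    totals = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(totals > 0, counts / totals * scale_factor, 0.0)
    return np.log1p(scaled)


def ranksum_test(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sided rank-sum test per gene (rows).

    Returns (W, p) where W is the sum of group-A ranks (midranks under ties)
    in the pooled sample and p the two-sided normal-approximation p-value
    with tie-corrected variance. Constant genes get p = 1.
    """
    n1, n2 = a.shape[1], b.shape[1]
    n = n1 + n2
    data = np.concatenate([a, b], axis=1)
    ranks = stats.rankdata(data, axis=1)
    r1 = ranks[:, :n1].sum(axis=1)
    mu = n1 * (n + 1) / 2.0
    # tie correction: sum of (t^3 - t) over tie groups, per gene
    sorted_rows = np.sort(data, axis=1)
    new_group = np.ones_like(sorted_rows, dtype=bool)
    new_group[:, 1:] = sorted_rows[:, 1:] != sorted_rows[:, :-1]
    tie_term = np.empty(data.shape[0])
    for i in range(data.shape[0]):  # per-gene tie-group sizes
        sizes = np.diff(np.append(np.flatnonzero(new_group[i]), n))
        tie_term[i] = np.sum(sizes**3 - sizes)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    p = np.ones(data.shape[0])
    ok = var > 0
    z = np.zeros_like(p)
    z[ok] = (r1[ok] - mu) / np.sqrt(var[ok])
    p[ok] = 2.0 * stats.norm.sf(np.abs(z[ok]))
    return r1, np.minimum(p, 1.0)


def wilcoxon_markers(
    norm_expr: np.ndarray,
    group_a: np.ndarray,
    group_b: np.ndarray,
    gene_symbols: np.ndarray,
    params: MarkerParams = MarkerParams(),
) -> pd.DataFrame:
    """Two-group marker table: logFC gate, rank-sum test, BH adjustment.

    ``norm_expr`` is the log-normalized genes x cells matrix; ``group_a``
    and ``group_b`` are cell index arrays (or boolean masks). The log fold
    change is ln(mean(expm1(a)) + pseudocount) - ln(mean(expm1(b)) +
    pseudocount); genes with |logFC| <= ``min_abs_logfc`` are not tested
    (p and padj are NaN). BH adjustment runs over the tested genes only,
    and ``significant`` marks padj < ``padj_threshold``.
    """
    group_a = np.asarray(group_a)
    group_b = np.asarray(group_b)
    if group_a.dtype == bool:
        group_a = np.flatnonzero(group_a)
    if group_b.dtype == bool:
        group_b = np.flatnonzero(group_b)
    if group_a.size == 0 or group_b.size == 0:
        raise ValueError("both groups must be non-empty")
    if min(group_a.size, group_b.size) < 3:
        warnings.warn("a group has fewer than 3 cells; p-values are unreliable",
                      UserWarning, stacklevel=2)
    a = norm_expr[:, group_a]
    b = norm_expr[:, group_b]
    mean_a = np.expm1(a).mean(axis=1)
    mean_b = np.expm1(b).mean(axis=1)
    logfc = np.log(mean_a + params.pseudocount) - np.log(mean_b + params.pseudocount)

    tested = np.abs(logfc) > params.min_abs_logfc
    pvals = np.full(norm_expr.shape[0], np.nan)
    padj = np.full(norm_expr.shape[0], np.nan)
    if tested.any():
        pvals[tested] = ranksum_test(a[tested], b[tested])[1]
        padj[tested] = multipletests(pvals[tested], method="fdr_bh")[1]
    significant = np.where(tested, padj < params.padj_threshold, False)
    return pd.DataFrame(
        {
            "gene": np.asarray(gene_symbols, dtype=object),
            "mean_a": mean_a,
            "mean_b": mean_b,
            "logfc": logfc,
            "pvalue": pvals,
            "padj": padj,
            "significant": significant,
        }
    )


def cluster_proportions(
    cell_cluster: np.ndarray, cell_group: np.ndarray
) -> pd.DataFrame:
    """Per-group cluster composition: rows are groups, columns clusters,
    entries are cell fractions summing to 1 within each row."""
    df = pd.DataFrame({"cluster": cell_cluster, "group": cell_group})
    counts = pd.crosstab(df["group"], df["cluster"])
    return counts.div(counts.sum(axis=1), axis=0)


def hypergeometric_enrichment(
    query: set | list,
    universe: set | list,
    annotation_sets: dict[str, set | list],
) -> pd.DataFrame:
    """Overrepresentation of a query gene list in annotation sets.

    For each set, the upper-tail hypergeometric probability of observing at
    least the seen overlap when drawing |query| genes from the universe; BH
    adjustment across sets. Raises ``ValueError`` listing offenders when the
    query is not a subset of the universe.
    """
    query = set(query)
    universe = set(universe)
    stray = sorted(query - universe)
    if stray:
        raise ValueError(f"query genes missing from the universe: {stray}")
    M, N = len(universe), len(query)
    rows = []
    for name, genes in annotation_sets.items():
        in_universe = set(genes) & universe
        k = len(query & in_universe)
        K = len(in_universe)
        p = float(stats.hypergeom.sf(k - 1, M, K, N)) if K else 1.0
        rows.append({"set": name, "overlap": k, "set_size": K, "pvalue": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if len(out):
        out["padj"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    else:
        out["padj"] = pd.Series(dtype=float)
    return out
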