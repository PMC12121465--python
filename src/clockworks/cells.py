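"""Cell-type-resolved transcriptome analytics.

Operates on a cells x genes count matrix with per-cell type (or cluster)
labels and optional day/night harvest labels: marker-based cluster
annotation, cluster-defining gene ranking, two-gene co-expression
partitioning, interactor expression profiles across cell types, day/night
differential expression within a type, and the intersection of a circadian
protein set with a cell-type-enriched transcript set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_MARKERS: dict[str, list[str]] = {
    "astrocyte": ["Gfap", "Aldh1l1", "Aqp4", "Sox9"],
    "scn_neuron": ["Slc32a1", "Nms", "Avp", "Vip"],
    "extra_scn_neuron": ["Slc17a6", "Th", "Sst", "Agrp"],
    "ependymocyte": ["Tmem212", "Tctex1d4"],
    "oligodendrocyte": ["Mog", "Plp1"],
    "ng2_cell": ["Pdgfra"],
    "radial_glia": ["Ccnb1", "Ube2c"],
    "tanycyte": ["Col23a1"],
    "microglia": ["Ly86", "C1qa", "Hexb"],
    "endothelial": ["Lum", "Dcn"],
}


@dataclass
class CellGeneMatrix:
    """Cells x genes counts with cell-type and optional day/night labels."""

    counts: pd.DataFrame
    cell_type: pd.Series
    time_label: pd.Series | None = None
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.cell_type.index.equals(self.counts.index):
            raise ValueError("cell_type labels must cover all cells")
        if self.time_label is not None and not self.time_label.index.equals(
            self.counts.index
        ):
            raise ValueError("time_label must cover all cells")

    @property
    def n_cells(self) -> int:
        return len(self.counts)

    @property
    def genes(self) -> pd.Index:
        return self.counts.columns

    def subset_type(self, cell_type: str) -> "CellGeneMatrix":
        mask = self.cell_type == cell_type
        return CellGeneMatrix(
            counts=self.counts.loc[mask],
            cell_type=self.cell_type.loc[mask],
            time_label=None if self.time_label is None else self.time_label.loc[mask],
        )

    # -- I/O (dense TSV; suits desk-scale fixtures) ------------------------
    def to_tsv(self, counts_path, labels_path) -> None:
        self.counts.to_csv(counts_path, sep="\t")
        labels = pd.DataFrame({"cell_type": self.cell_type})
        if self.time_label is not None:
            labels["time_label"] = self.time_label
        labels.to_csv(labels_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path, labels_path) -> "CellGeneMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        labels = pd.read_csv(labels_path, sep="\t", index_col=0)
        return cls(
            counts=counts,
            cell_type=labels["cell_type"],
            time_label=labels["time_label"] if "time_label" in labels else None,
        )

    @classmethod
    def from_mtx(cls, mtx_path, barcodes_path, genes_path, labels_path) -> "CellGeneMatrix":
        from scipy.io import mmread

        counts = np.asarray(mmread(mtx_path).todense())
        barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0]
        genes = pd.read_csv(genes_path, sep="\t", header=None)[0]
        labels = pd.read_csv(labels_path, sep="\t", index_col=0)
        df = pd.DataFrame(counts, index=pd.Index(barcodes, name="cell_id"),
                          columns=genes)
        return cls(
            counts=df,
            cell_type=labels["cell_type"].reindex(df.index),
            time_label=labels["time_label"].reindex(df.index)
            if "time_label" in labels
            else None,
        )


@dataclass
class CoexpressionPartition:
    """Joint expression partition of two genes, overall and per cell type."""

    gene_a: str
    gene_b: str
    overall: pd.Series  # n_neither, n_a_only, n_b_only, n_both
    per_type: pd.DataFrame  # same columns per type + pct_both

    @property
    def total_cells(self) -> int:
        return int(self.overall.sum())


# ---------------------------------------------------------------------------
# cluster annotation and marker ranking
# ---------------------------------------------------------------------------

def annotate_clusters(
    matrix: CellGeneMatrix,
    cluster_ids: pd.Series,
    markers: dict[str, list[str]] | None = None,
) -> dict:
    """Assign a cell-type label to each cluster from marker expression.

    Per-gene mean expression is computed per cluster and z-scored across
    clusters; a type's score for a cluster is the mean z over its markers
    present in the matrix.  The argmax type is assigned unless the top score
    is <= 0 or tied, in which case the cluster is ``"unclassified"``.
    """
    markers = DEFAULT_MARKERS if markers is None else markers
    if (cluster_ids.value_counts() == 0).any():
        raise ValueError("every cluster must be non-empty")
    means = matrix.counts.groupby(cluster_ids).mean()
    sd = means.std(axis=0, ddof=0)
    z = (means - means.mean(axis=0)) / sd.replace(0, np.nan)
    z = z.fillna(0.0)

    any_present = False
    scores = {}
    for ctype, genes in markers.items():
        present = [g for g in genes if g in z.columns]
        for g in genes:
            if g not in z.columns:
                warnings.warn(f"marker {g!r} absent from matrix; skipped", UserWarning,
                              stacklevel=2)
        if not present:
            scores[ctype] = pd.Series(-np.inf, index=z.index)
            continue
        any_present = True
        scores[ctype] = z[present].mean(axis=1)
    if not any_present:
        raise ValueError("no marker of any type is present in the matrix")

    score_df = pd.DataFrame(scores)
    out = {}
    for cluster in score_df.index:
        row = score_df.loc[cluster]
        top = row.max()
        winners = row[np.isclose(row, top)].index
        if top <= 0 or len(winners) > 1:
            out[cluster] = "unclassified"
        else:
            out[cluster] = winners[0]
    return out


def rank_cluster_markers(
    matrix: CellGeneMatrix,
    cluster_ids: pd.Series,
    top_n: int = 250,
    alpha: float = 0.05,
) -> dict:
    """Rank cluster-defining genes by one-sided rank-sum against the rest.

    Per cluster, each gene is tested cluster-vs-rest (Mann-Whitney,
    alternative 'greater' so only positively enriched genes qualify),
    BH-adjusted within the cluster; genes with adjusted p < ``alpha`` are
    ordered by (adjusted p, raw p, symbol) and truncated to ``top_n``.
    """
    clusters = pd.unique(cluster_ids)
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")
    counts = matrix.counts
    out = {}
    for cl in clusters:
        mask = (cluster_ids == cl).to_numpy()
        a = counts.to_numpy()[mask]
        b = counts.to_numpy()[~mask]
        res = stats.mannwhitneyu(a, b, axis=0, alternative="greater")
        padj = multipletests(res.pvalue, method="fdr_bh")[1]
        table = pd.DataFrame(
            {"p": res.pvalue, "p_adj": padj}, index=counts.columns
        )
        table = table[table["p_adj"] < alpha]
        # deterministic ordering: adjusted p, then raw p, then symbol
        table = table.iloc[
            np.lexsort((table.index.astype(str), table["p"], table["p_adj"]))
        ]
        out[cl] = list(table.index[:top_n])
    return out


# ---------------------------------------------------------------------------
# co-expression, interactor profiles, differential expression
# ---------------------------------------------------------------------------

def coexpression_partition(
    matrix: CellGeneMatrix, gene_a: str, gene_b: str, min_count: int = 1
) -> CoexpressionPartition:
    """Partition cells by joint expression of two genes.

    A cell expresses a gene iff its raw count >= ``min_count`` (default: any
    nonzero count).  Categories (neither / A only / B only / both) are
    mutually exclusive and exhaustive; counts are reported overall and per
    cell type along with the per-type percentage co-expressing both.
    """
    for g in (gene_a, gene_b):
        if g not in matrix.counts.columns:
            raise ValueError(f"gene {g!r} not present in the matrix")
    a_on = matrix.counts[gene_a] >= min_count
    b_on = matrix.counts[gene_b] >= min_count
    cat = pd.Series("neither", index=matrix.counts.index)
    cat[a_on & ~b_on] = "a_only"
    cat[~a_on & b_on] = "b_only"
    cat[a_on & b_on] = "both"

    order = ["n_neither", "n_a_only", "n_b_only", "n_both"]

    def _tally(series: pd.Series) -> pd.Series:
        c = series.value_counts()
        return pd.Series(
            [c.get("neither", 0), c.get("a_only", 0), c.get("b_only", 0),
             c.get("both", 0)],
            index=order,
        )

    overall = _tally(cat)
    rows = {}
    for ctype, sub in cat.groupby(matrix.cell_type):
        rows[ctype] = _tally(sub)
    per_type = pd.DataFrame(rows).T
    per_type["pct_both"] = 100.0 * per_type["n_both"] / per_type[order].sum(axis=1)
    return CoexpressionPartition(gene_a, gene_b, overall, per_type)


def interactor_profile(matrix: CellGeneMatrix, gene_list: list[str]) -> pd.DataFrame:
    """Cell-type expression profile of a list of interactor genes.

    Raw counts are summed per (gene, cell type) and each gene's row is
    min-max normalized across types to [0, 1] (constant rows map to 0.5);
    genes absent from the matrix are dropped with a warning.
    """
    present = [g for g in gene_list if g in matrix.counts.columns]
    for g in gene_list:
        if g not in matrix.counts.columns:
            warnings.warn(f"gene {g!r} absent from matrix; skipped", UserWarning,
                          stacklevel=2)
    if not present:
        raise ValueError("none of the listed genes are present in the matrix")
    sums = matrix.counts[present].groupby(matrix.cell_type).sum().T
    lo = sums.min(axis=1)
    hi = sums.max(axis=1)
    span = hi - lo
    norm = sums.sub(lo, axis=0).div(span.replace(0, np.nan), axis=0)
    return norm.where(span != 0, 0.5, axis=0)


def day_night_de(
    matrix: CellGeneMatrix,
    day_label: str = "day",
    night_label: str = "night",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Day-vs-night differential expression within one cell population.

    Per gene: log2 fold change of day over night mean counts (with a
    pseudocount for stability on sparse data), a two-sided rank-sum p-value
    and its BH adjustment.  Intended for a matrix already subset to one cell
    type (see :meth:`CellGeneMatrix.subset_type`).
    """
    if matrix.time_label is None:
        raise ValueError("matrix has no day/night labels")
    day = matrix.time_label == day_label
    night = matrix.time_label == night_label
    if day.sum() < 3 or night.sum() < 3:
        raise ValueError("each label needs at least 3 cells")
    a = matrix.counts.to_numpy()[day.to_numpy()]
    b = matrix.counts.to_numpy()[night.to_numpy()]
    lfc = np.log2((a.mean(axis=0) + pseudocount) / (b.mean(axis=0) + pseudocount))
    res = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided")
    padj = multipletests(res.pvalue, method="fdr_bh")[1]
    return pd.DataFrame(
        {"log2fc": lfc, "p": res.pvalue, "p_adj": padj}, index=matrix.counts.columns
    )


def intersect_circadian_astrocytic(
    circadian_features: list[str],
    astrocyte_genes: list[str],
    id_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Intersect a circadian protein set with a cell-type-enriched gene set.

    Protein identifiers are first translated through ``id_map`` (when given)
    and then matched case-insensitively against gene symbols.  Returns one
    row per match with both source identifiers and the canonical symbol.
    """
    if not circadian_features or not astrocyte_genes:
        raise ValueError("both input sets must be non-empty")
    id_map = id_map or {}
    gene_lookup = {}
    for g in astrocyte_genes:
        gene_lookup.setdefault(str(g).casefold(), str(g))
    rows = []
    seen = set()
    for feat in circadian_features:
        symbol = id_map.get(feat, feat)
        key = str(symbol).casefold()
        if key in gene_lookup and key not in seen:
            seen.add(key)
            rows.append(
                {"circadian_id": feat, "astrocyte_id": gene_lookup[key],
                 "symbol": gene_lookup[key]}
            )
    return pd.DataFrame(rows, columns=["circadian_id", "astrocyte_id", "symbol"])
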