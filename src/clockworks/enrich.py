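"""Gene-set over-representation analysis (ORA) and term-gene networks.

Generic hypergeometric enrichment over user-supplied gene sets (GMT files),
with BH adjustment across sets, a per-cluster comparison that reports the
deduplicated union of each cluster's top terms, and a bipartite term-gene
edge list for category-network plots (genes shared between terms act as
nexus nodes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


def _norm(symbol: str) -> str:
    return str(symbol).strip().casefold()


@dataclass
class GeneSetCollection:
    """Named gene sets plus an optional background universe.

    Symbols are matched case-insensitively; within a set genes are unique.
    """

    sets: dict[str, list[str]]
    universe: list[str] | None = None
    _norm_sets: dict[str, set] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.sets) != len({n for n in self.sets}):
            raise ValueError("set names must be unique")
        self._norm_sets = {}
        for name, genes in self.sets.items():
            normed = [_norm(g) for g in genes]
            if len(normed) != len(set(normed)):
                raise ValueError(f"set {name!r} contains duplicate genes")
            self._norm_sets[name] = set(normed)

    @classmethod
    def from_gmt(cls, path, universe: list[str] | None = None) -> "GeneSetCollection":
        sets = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                name, _description, *genes = line.split("\t")
                sets[name] = [g for g in genes if g]
        return cls(sets=sets, universe=universe)

    def to_gmt(self, path, descriptions: dict[str, str] | None = None) -> None:
        descriptions = descriptions or {}
        with open(path, "w") as fh:
            for name, genes in self.sets.items():
                fh.write("\t".join([name, descriptions.get(name, "na"), *genes]) + "\n")


def ora(
    query: list[str],
    sets: GeneSetCollection,
    universe: list[str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query list in each gene set.

    For a universe of N genes, a set of K, a query of n and an overlap of k
    the upper-tail p is P(X >= k) for X ~ Hypergeom(N, K, n).  When no
    universe is supplied it defaults to the union of all set genes and the
    query.  Rows are BH-adjusted across sets and sorted by adjusted p,
    raw p, then term name.
    """
    if not query:
        raise ValueError("empty query")
    query_n = {_norm(g): str(g) for g in query}
    universe = universe if universe is not None else sets.universe
    if universe is None:
        uni = set().union(*sets._norm_sets.values()) | set(query_n)
    else:
        if not universe:
            raise ValueError("empty universe")
        uni = {_norm(g) for g in universe}
        stray = set(query_n) - uni
        if stray:
            raise ValueError(
                f"query genes outside the universe: {sorted(stray)[:5]}"
            )
    n = len(query_n)
    big_n = len(uni)
    rows = []
    for name, members in sets._norm_sets.items():
        members_u = members & uni
        big_k = len(members_u)
        overlap = sorted(set(query_n) & members_u)
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, big_n, big_k, n)) if k > 0 else 1.0
        rows.append(
            {
                "term": name,
                "k": k,
                "n": n,
                "K": big_k,
                "N": big_n,
                "gene_ratio": k / n,
                "p": min(p, 1.0),
                "genes": [query_n[g] for g in overlap],
            }
        )
    table = pd.DataFrame(rows)
    table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    table = table.sort_values(
        by=["p_adj", "p", "term"], kind="mergesort"
    ).reset_index(drop=True)
    return table[["term", "k", "n", "K", "N", "gene_ratio", "p", "p_adj", "genes"]]


def compare_clusters(
    per_cluster_gene_lists: dict[str, list[str]],
    sets: GeneSetCollection,
    universe: list[str] | None = None,
    top_terms: int = 2,
) -> tuple[dict[str, pd.DataFrame], list[str]]:
    """Run ORA per cluster and collect the deduplicated top-term union.

    Closely related clusters often share their top terms, so the union can
    be smaller than ``top_terms`` x the number of clusters.  Returns the
    per-cluster tables and the union list (first-appearance order).
    """
    if not per_cluster_gene_lists:
        raise ValueError("need at least one cluster gene list")
    tables = {
        cl: ora(genes, sets, universe) for cl, genes in per_cluster_gene_lists.items()
    }
    union: list[str] = []
    for cl, table in tables.items():
        for term in table["term"].head(top_terms):
            if term not in union:
                union.append(term)
    return tables, union


def term_gene_network(table: pd.DataFrame, top_k: int = 10) -> pd.DataFrame:
    """Bipartite term-gene edge list over the ``top_k`` most significant terms.

    Each edge links a term to one of its overlapping query genes; a gene
    contributing to several terms appears in several edges, so its degree
    counts the terms it bridges.
    """
    if table.empty:
        raise ValueError("empty enrichment table")
    edges = []
    for _, row in table.head(top_k).iterrows():
        for gene in row["genes"]:
            edges.append({"term": row["term"], "gene": gene})
    return pd.DataFrame(edges, columns=["term", "gene"])


def gene_degrees(edges: pd.DataFrame) -> pd.Series:
    """Number of terms each gene connects to in a term-gene edge list."""
    if edges.empty:
        return pd.Series(dtype=int)
    return edges.groupby("gene")["term"].nunique().sort_values(ascending=False)
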