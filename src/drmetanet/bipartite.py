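"""Gene-metabolite-phenotype bipartite network assembly and export.

Nodes are genes, metabolites and a single phenotype node ("rLS", the
lifespan-response trait).  Edges connect a metabolite to the phenotype
when its rLS association passes the FDR cutoff, and a gene to a metabolite
(or directly to the phenotype) when its permutation gene score passes the
score cutoff.  Gene-gene and metabolite-metabolite edges never occur.
Edge weight is -log10 of the defining statistic.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd

PHENOTYPE_NODE = "rLS"
GENE_CUTOFF_DEFAULT = 10 ** -4.5


def build_network(
    assoc_table: pd.DataFrame,
    gene_scores: pd.DataFrame | None,
    alpha: float = 0.01,
    gene_cutoff: float = GENE_CUTOFF_DEFAULT,
    diet: str = "AL",
    rls_gene_scores: pd.DataFrame | None = None,
) -> nx.Graph:
    """Assemble the network for one diet context.

    ``assoc_table`` is the tidy per-metabolite association table (must
    contain rLS rows for ``diet``); ``gene_scores`` has one row per
    (gene, metabolite) pair with a ``metabolite_id`` column and the
    permutation ``score``; ``rls_gene_scores`` optionally holds gene
    scores computed against rLS itself (gene-phenotype edges).

    Metabolites correlated with rLS but without any passing gene are
    retained as phenotype-connected orphans.
    """
    if assoc_table is None or len(assoc_table) == 0:
        raise ValueError("empty association table")
    if not (0 < gene_cutoff <= 1):
        raise ValueError(f"gene_cutoff must be in (0, 1], got {gene_cutoff}")

    sel = assoc_table[(assoc_table["trait_name"] == "rLS")
                      & (assoc_table["diet_of_measurement"] == diet)]
    if len(sel) == 0:
        raise ValueError(f"no rLS association rows for diet {diet!r}")
    sig = sel[sel["q"] <= alpha]

    G = nx.Graph(diet=diet, alpha=alpha, gene_cutoff=gene_cutoff)
    G.add_node(PHENOTYPE_NODE, kind="phenotype")
    for row in sig.itertuples(index=False):
        met = row.metabolite_id
        G.add_node(met, kind="metabolite")
        G.add_edge(met, PHENOTYPE_NODE, kind="metabolite-phenotype",
                   weight=float(-np.log10(max(row.q, 1e-300))),
                   provenance=f"assoc:{diet}:{met}")

    if gene_scores is not None and len(gene_scores):
        passing = gene_scores[gene_scores["score"] <= gene_cutoff]
        for row in passing.itertuples(index=False):
            met = row.metabolite_id
            if met not in G:
                # gene scores are computed against the rLS-associated set;
                # anything else would be inconsistent provenance
                continue
            G.add_node(row.gene_id, kind="gene")
            G.add_edge(row.gene_id, met, kind="gene-metabolite",
                       weight=float(-np.log10(max(row.score, 1e-300))),
                       provenance=f"genescore:{met}:{row.gene_id}")

    if rls_gene_scores is not None and len(rls_gene_scores):
        passing = rls_gene_scores[rls_gene_scores["score"] <= gene_cutoff]
        for row in passing.itertuples(index=False):
            G.add_node(row.gene_id, kind="gene")
            G.add_edge(row.gene_id, PHENOTYPE_NODE, kind="gene-phenotype",
                       weight=float(-np.log10(max(row.score, 1e-300))),
                       provenance=f"genescore:rLS:{row.gene_id}")

    _check_bipartite(G)
    return G


def _check_bipartite(G: nx.Graph) -> None:
    for u, v in G.edges:
        ku, kv = G.nodes[u]["kind"], G.nodes[v]["kind"]
        if ku == kv:
            raise ValueError(f"forbidden {ku}-{kv} edge: {u} -- {v}")


def gene_degree_report(G: nx.Graph) -> pd.Series:
    """Gene degrees, descending (ties broken lexicographically)."""
    rows = [(n, G.degree(n)) for n, d in G.nodes(data=True)
            if d.get("kind") == "gene"]
    df = pd.DataFrame(rows, columns=["gene_id", "degree"])
    df = df.sort_values(["degree", "gene_id"], ascending=[False, True],
                        kind="stable")
    return df.set_index("gene_id")["degree"]


def export_network(G: nx.Graph, path, fmt: str = "graphml") -> None:
    """Write the network as GraphML, SIF or an edge TSV.

    GraphML round-trips node/edge attributes; SIF is one
    ``source<TAB>edge-kind<TAB>target`` line per edge (Cytoscape-readable).
    """
    fmt = fmt.lower()
    if fmt == "graphml":
        H = G.copy()
        for n in H.nodes:
            H.nodes[n]["degree"] = H.degree(n)
        nx.write_graphml(H, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v, d in G.edges(data=True):
                fh.write(f"{u}\t{d.get('kind', 'edge')}\t{v}\n")
    elif fmt == "tsv":
        rows = [{"source": u, "target": v, **d}
                for u, v, d in G.edges(data=True)]
        pd.DataFrame(rows, columns=["source", "target", "kind", "weight",
                                    "provenance"]).to_csv(
            path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown export format {fmt!r}")
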