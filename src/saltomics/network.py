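"""Candidate PPI network construction, hubs and term enrichment.

Candidates are mapped to ortholog identifiers through a user-supplied
two-column table; edges come from a user-supplied scored table in the
STRING style, and only edges with a combined score strictly above the
cutoff (default 160) that touch at least one candidate ortholog are
kept.  Hubs are the top-degree nodes (ties broken by identifier), used
as proxies for the functional cluster centres of the network.

Term enrichment is the generic hypergeometric over-representation test
with Benjamini-Hochberg correction across terms.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import benjamini_hochberg

__all__ = [
    "map_orthologs",
    "build_network",
    "find_hubs",
    "enrich_terms",
    "write_sif",
]


def map_orthologs(ids, ortholog_map: pd.DataFrame) -> tuple[dict, list]:
    """Map candidate ids to ortholog ids.

    ``ortholog_map`` has columns ``id`` and ``ortholog``.  Returns the
    mapping for resolvable ids and the list of unmapped ids (dropped).
    """
    lookup = dict(zip(ortholog_map["id"], ortholog_map["ortholog"]))
    mapped, unmapped = {}, []
    for ident in ids:
        if ident in lookup:
            mapped[ident] = lookup[ident]
        else:
            unmapped.append(ident)
    return mapped, unmapped


def build_network(
    candidate_ids,
    ortholog_map: pd.DataFrame,
    edges: pd.DataFrame,
    score_min: float = 160.0,
) -> nx.Graph:
    """Undirected network over candidate orthologs and their direct
    interactors.

    Edges must have columns node_a, node_b, combined_score.  Edges with a
    score strictly above ``score_min`` and at least one candidate
    endpoint are kept; duplicates collapse to the maximum score;
    self-loops are discarded.
    """
    for col in ("node_a", "node_b", "combined_score"):
        if col not in edges.columns:
            raise ValueError(f"edge table is missing column {col!r}")
    scores = pd.to_numeric(edges["combined_score"], errors="coerce")
    bad = scores.isna()
    if bad.any():
        raise ValueError(
            f"malformed combined_score in edge row {int(np.flatnonzero(bad)[0])}"
        )
    mapped, _ = map_orthologs(candidate_ids, ortholog_map)
    cand_nodes = set(mapped.values())
    g = nx.Graph()
    g.add_nodes_from(sorted(cand_nodes), candidate=True)
    for (a, b), score in zip(
        zip(edges["node_a"], edges["node_b"]), scores.to_numpy(dtype=float)
    ):
        if a == b or score <= score_min:
            continue
        if a not in cand_nodes and b not in cand_nodes:
            continue
        if g.has_edge(a, b):
            g[a][b]["combined_score"] = max(g[a][b]["combined_score"], score)
        else:
            g.add_edge(a, b, combined_score=score)
            for node in (a, b):
                g.nodes[node].setdefault("candidate", node in cand_nodes)
    return g


def find_hubs(graph: nx.Graph, k: int = 2) -> tuple[list[tuple[str, int]], list[set]]:
    """Top-``k`` nodes by degree plus the connected components.

    Ties are broken by node identifier.  An empty graph yields empty
    results without error.
    """
    if graph.number_of_nodes() == 0:
        return [], []
    ranked = sorted(graph.degree, key=lambda kv: (-kv[1], kv[0]))
    components = sorted(nx.connected_components(graph), key=len, reverse=True)
    return ranked[:k], components


def enrich_terms(
    foreground: set,
    background: set,
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Hypergeometric over-representation of terms in a foreground set.

    ``annotation`` has columns ``id`` and ``term``.  For each term with
    K annotated genes in the background of size M and k of them among
    the n foreground genes, p = P(X >= k) for X ~ Hypergeom(M, K, n).
    Returns term, overlap, term_size, p, q (BH across terms).
    """
    foreground, background = set(foreground), set(background)
    if not foreground <= background:
        raise ValueError("foreground must be a subset of the background")
    ann = annotation[annotation["id"].isin(background)]
    M, n = len(background), len(foreground)
    rows = []
    for term, grp in ann.groupby("term"):
        members = set(grp["id"])
        K = len(members)
        k = len(members & foreground)
        p = float(stats.hypergeom.sf(k - 1, M, K, n))
        rows.append({"term": term, "overlap": k, "term_size": K, "p": p})
    out = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "p"])
    if len(out):
        out = out.sort_values("term", kind="stable").reset_index(drop=True)
        out["q"] = benjamini_hochberg(out["p"].to_numpy())
    else:
        out["q"] = pd.Series(dtype=float)
    return out


def write_sif(graph: nx.Graph, path) -> None:
    """Write the network as a SIF interaction file (``a pp b`` lines)."""
    with open(path, "w") as fh:
        for a, b in sorted(graph.edges):
            fh.write(f"{a}\tpp\t{b}\n")
        for node in sorted(nx.isolates(graph)):
            fh.write(f"{node}\n")
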