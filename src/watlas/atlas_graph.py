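"""Cross-study cluster-similarity network from marker-gene overlap.

Each (study, cluster) pair is a node carrying its within-study size fraction.
Candidate edges require the directed marker overlap fractions to exceed 15%
in at least one direction and 5% in both; each node then contributes its
top-5 candidate edges by Jaccard similarity (union over nodes, so an edge
survives if either endpoint ranks it), which keeps the graph symmetric
without orphaning small clusters.  Consensus cell classes are the connected
components of the retained edge set, ordered by total size fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .markers import MarkerSet

Node = tuple[str, str]  # (study, cluster)


def overlap_fractions(set_a, set_b) -> tuple[float, float]:
    """Directed overlap fractions (|A∩B|/|A|, |A∩B|/|B|)."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ValueError("overlap fractions undefined for an empty set")
    inter = len(a & b)
    return inter / len(a), inter / len(b)


def jaccard(set_a, set_b) -> float:
    """Jaccard similarity |A∩B|/|A∪B|; two empty sets give 0 (flagged)."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        warnings.warn("Jaccard of two empty sets: 0 by convention",
                      stacklevel=2)
        return 0.0
    return len(a & b) / len(union)


@dataclass
class ClusterGraph:
    """Marker-overlap network over (study, cluster) nodes."""

    graph: nx.Graph
    classes: dict[Node, str] | None = None

    @property
    def nodes(self):
        return list(self.graph.nodes)

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for u, v, d in self.graph.edges(data=True):
            rows.append({
                "study_a": u[0], "cluster_a": u[1],
                "study_b": v[0], "cluster_b": v[1],
                "frac_a_in_b": d["frac_a_in_b"],
                "frac_b_in_a": d["frac_b_in_a"],
                "jaccard": d["jaccard"],
                "kept_by": d["kept_by"],
                "within_study": u[0] == v[0],
            })
        return pd.DataFrame(rows)


def build_network(marker_sets: dict[Node, MarkerSet],
                  size_fractions: dict[Node, float] | None = None,
                  min_frac_one: float = 0.15, min_frac_both: float = 0.05,
                  top_k: int = 5,
                  top_k_scope: str = "node") -> ClusterGraph:
    """Build the cluster-similarity graph from per-node marker sets.

    A pair is a candidate iff max(fractions) > ``min_frac_one`` and
    min(fractions) > ``min_frac_both`` (strict, as printed).  With
    ``top_k_scope="node"`` (default) each node keeps its ``top_k`` candidates
    by Jaccard and the final edge set is the union over nodes; with
    ``"global"`` the ``top_k`` highest-Jaccard candidates overall are kept.
    Ties at the boundary break by larger minimum overlap fraction, then by
    node id.  Nodes with empty marker sets stay isolated (warned).
    """
    nodes = sorted(marker_sets)
    studies = {s for s, _ in nodes}
    if len(nodes) < 2 or len(studies) < 2:
        raise ValueError("need >= 2 nodes from >= 2 studies")
    if top_k_scope not in ("node", "global"):
        raise ValueError("top_k_scope must be 'node' or 'global'")
    g = nx.Graph()
    for node in nodes:
        frac = (size_fractions or {}).get(node, np.nan)
        g.add_node(node, size_fraction=frac,
                   n_markers=len(marker_sets[node].genes))
        if not marker_sets[node].genes:
            warnings.warn(f"node {node} has an empty marker set; isolated",
                          stacklevel=2)

    candidates = []  # (u, v, fa, fb, jac)
    for i, u in enumerate(nodes):
        gu = marker_sets[u].genes
        if not gu:
            continue
        for v in nodes[i + 1:]:
            gv = marker_sets[v].genes
            if not gv:
                continue
            fa, fb = overlap_fractions(gu, gv)
            if max(fa, fb) > min_frac_one and min(fa, fb) > min_frac_both:
                candidates.append((u, v, fa, fb, jaccard(gu, gv)))

    def sort_key(c):
        u, v, fa, fb, jac = c
        return (-jac, -min(fa, fb), u, v)

    kept: dict[tuple[Node, Node], str] = {}
    if top_k_scope == "global":
        for u, v, fa, fb, jac in sorted(candidates, key=sort_key)[:top_k]:
            kept[(u, v)] = "global"
    else:
        per_node: dict[Node, list] = {n: [] for n in nodes}
        for c in candidates:
            per_node[c[0]].append(c)
            per_node[c[1]].append(c)
        for node in nodes:
            for u, v, *_ in sorted(per_node[node], key=sort_key)[:top_k]:
                key = (u, v)
                tag = f"{node[0]}:{node[1]}"
                kept[key] = tag if key not in kept else kept[key] + "|" + tag

    cand_by_pair = {(u, v): (fa, fb, jac)
                    for u, v, fa, fb, jac in candidates}
    for (u, v), kept_by in kept.items():
        fa, fb, jac = cand_by_pair[(u, v)]
        g.add_edge(u, v, frac_a_in_b=fa, frac_b_in_a=fb, jaccard=jac,
                   kept_by=kept_by)
    return ClusterGraph(graph=g)


def class_partition(cg: ClusterGraph) -> dict[Node, str]:
    """Consensus classes = connected components, ordered by size fraction.

    Components are labelled ``class_1, class_2, ...`` by decreasing total
    node size fraction (node count, then smallest node id, break ties).
    The labelling is stored on the ClusterGraph and returned.
    """
    comps = list(nx.connected_components(cg.graph))

    def comp_key(comp):
        total = sum(cg.graph.nodes[n].get("size_fraction", 0) or 0
                    for n in comp)
        total = 0.0 if np.isnan(total) else total
        return (-total, -len(comp), min(comp))

    classes: dict[Node, str] = {}
    for rank, comp in enumerate(sorted(comps, key=comp_key), start=1):
        for node in comp:
            classes[node] = f"class_{rank}"
    cg.classes = classes
    return classes


def jaccard_heatmap(sets_a: dict[str, MarkerSet],
                    sets_b: dict[str, MarkerSet]) -> pd.DataFrame:
    """Pairwise Jaccard matrix between two marker-set collections."""
    if not sets_a or not sets_b:
        raise ValueError("both collections must be nonempty")
    rows = sorted(sets_a)
    cols = sorted(sets_b)
    mat = np.zeros((len(rows), len(cols)))
    for i, ra in enumerate(rows):
        ga = sets_a[ra].genes
        for j, cb in enumerate(cols):
            gb = sets_b[cb].genes
            if not ga or not gb:
                continue  # empty member set -> zeros, flagged below
            mat[i, j] = jaccard(ga, gb)
    empties = [k for k, s in {**sets_a, **sets_b}.items() if not s.genes]
    if empties:
        warnings.warn(f"empty marker sets give zero rows/columns: {empties}",
                      stacklevel=2)
    return pd.DataFrame(mat, index=rows, columns=cols)
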