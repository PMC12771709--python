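"""Signed-network sign propagation, perturbagen scoring, and topological roles.

Perturbing a node up or down propagates through the signed directed graph: the
predicted sign at a downstream node is the perturbation sign times the product
of edge signs along a simple path.  When distinct simple paths disagree the
node is "ambiguous".  A node's perturbagen score in a given direction is the
number of observed-change nodes whose predicted sign is opposite to their
observed sign — the genes the perturbation would revert.  Cycles are handled
by restricting to simple paths (no node revisited).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

_DIRECTION_SIGN = {"up": 1, "down": -1}


def load_edge_list(path) -> nx.DiGraph:
    """Three-column TSV (source, target, sign); sign as +1/-1 or activates/inhibits.

    The SIF-style column order (source, sign, target) is also accepted.
    Duplicate edges with conflicting signs are an error.
    """
    words_to_sign = {"+1": 1, "1": 1, "-1": -1, "activates": 1, "activation": 1,
                     "inhibits": -1, "inhibition": -1}
    g = nx.DiGraph()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"line {ln}: expected 3 tab-separated fields")
            if parts[1].lower() in words_to_sign:  # SIF dialect: src, relation, tgt
                src, raw, tgt = parts
            else:
                src, tgt, raw = parts
            sign = words_to_sign.get(raw.lower())
            if sign is None:
                raise ValueError(f"line {ln}: unrecognized edge sign {raw!r}")
            if g.has_edge(src, tgt) and g[src][tgt]["sign"] != sign:
                raise ValueError(f"conflicting signs for edge {src}->{tgt}")
            g.add_edge(src, tgt, sign=sign)
    return g


def write_edge_list(graph: nx.DiGraph, path) -> None:
    with open(path, "w") as fh:
        for u, v, d in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{d['sign']:+d}\n")


def propagate_sign(graph: nx.DiGraph, source, direction: str) -> dict:
    """Predicted change sign for every node reachable from ``source``.

    Returns node -> +1 / -1 / "ambiguous"; the source itself is excluded.
    Signs multiply along simple paths; conflicting products across distinct
    simple paths make a node ambiguous.
    """
    if source not in graph:
        raise ValueError(f"source node {source!r} not in graph")
    if direction not in _DIRECTION_SIGN:
        raise ValueError("direction must be 'up' or 'down'")
    seen_signs: dict = {}
    if nx.is_directed_acyclic_graph(graph):
        # every walk in a DAG is a simple path, so the achievable sign products
        # follow an exact recurrence in topological order
        seen_signs[source] = {1}
        for node in nx.topological_sort(graph):
            if node not in seen_signs:
                continue
            for _, nxt, data in graph.out_edges(node, data=True):
                prods = {p * data["sign"] for p in seen_signs[node]}
                seen_signs.setdefault(nxt, set()).update(prods)
        del seen_signs[source]
    else:
        # cyclic graph: enumerate simple paths by DFS
        stack = [(source, 1, frozenset({source}))]
        while stack:
            node, prod, on_path = stack.pop()
            for _, nxt, data in graph.out_edges(node, data=True):
                if nxt in on_path:
                    continue  # simple paths only
                p = prod * data["sign"]
                seen_signs.setdefault(nxt, set()).add(p)
                stack.append((nxt, p, on_path | {nxt}))
    d = _DIRECTION_SIGN[direction]
    out = {}
    for node, signs in seen_signs.items():
        out[node] = "ambiguous" if len(signs) > 1 else d * next(iter(signs))
    return out


@dataclass
class PerturbagenResult:
    node: str
    direction: str        # best perturbation direction
    score: int            # number of reverted observed-change genes
    reverted: list
    ambiguous: list


def perturbagen_score(graph: nx.DiGraph, observed: dict) -> list:
    """Rank every node by the number of observed DEGs its modulation reverts.

    ``observed`` maps nodes to their observed change sign (+1/-1).  For each
    node and both directions, reverted nodes are the reachable observed nodes
    whose predicted sign is opposite to the observed one; ambiguous nodes are
    excluded from the score.  Ranking is by score descending, ties by node
    name; per node the best direction is reported ("down" on a direction tie).
    """
    if not observed:
        raise ValueError("observed sign map is empty")
    bad = [n for n, s in observed.items() if s not in (-1, 1)]
    if bad:
        raise ValueError(f"observed signs must be +1/-1; offending nodes: {bad[:5]}")
    results = []
    for node in graph.nodes:
        pred_up = propagate_sign(graph, node, "up")
        ambiguous = sorted(n for n, s in pred_up.items()
                           if s == "ambiguous" and n in observed)
        rev = {}
        for direction in ("up", "down"):
            flip = 1 if direction == "up" else -1
            rev[direction] = sorted(
                n for n, s in pred_up.items()
                if s != "ambiguous" and n in observed and flip * s == -observed[n])
        direction = max(("down", "up"), key=lambda d: len(rev[d]))
        results.append(PerturbagenResult(
            node=node, direction=direction, score=len(rev[direction]),
            reverted=rev[direction], ambiguous=ambiguous))
    results.sort(key=lambda r: (-r.score, r.node))
    return results


def topology_roles(graph: nx.DiGraph, hub_quantile: float = 0.9) -> pd.DataFrame:
    """Hub / central / attractor role flags per node.

    Hubs have total degree at or above the ``hub_quantile`` quantile of
    degrees; central nodes have normalized directed betweenness (edge signs
    ignored, normalization by (n-1)(n-2)) at or above the same quantile of
    betweenness values; attractors have no parents (in-degree 0).
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    if not 0.0 <= hub_quantile <= 1.0:
        raise ValueError("hub_quantile must be in [0, 1]")
    nodes = sorted(graph.nodes)
    degree = np.array([graph.degree(n) for n in nodes], dtype=float)
    btw_map = nx.betweenness_centrality(graph, normalized=True)
    btw = np.array([btw_map[n] for n in nodes])
    deg_cut = np.quantile(degree, hub_quantile)
    btw_cut = np.quantile(btw, hub_quantile)
    return pd.DataFrame({
        "degree": degree.astype(int),
        "betweenness": btw,
        "hub": degree >= deg_cut,
        "central": btw >= btw_cut,
        "attractor": [graph.in_degree(n) == 0 for n in nodes],
    }, index=pd.Index(nodes, name="node"))
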