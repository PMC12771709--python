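"""Hypergeometric over-representation analysis against GMT gene-set collections.

The enrichment p-value of a query gene set against an annotated set is the
upper tail P(X >= x) of the hypergeometric distribution with population size
N = |universe|, K = |set within the universe| successes, and n = |query|
draws.  Sets mapping fewer than ``min_mapped`` query genes are dropped before
Benjamini-Hochberg adjustment across the collection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneSetCollection:
    """Named collection of gene sets (GMT semantics); symbols uppercase, sets non-empty."""

    name: str
    sets: dict  # set name -> gene list
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self):
        cleaned = {}
        for sname, genes in self.sets.items():
            genes = [str(g).upper() for g in genes]
            if not genes:
                raise ValueError(f"gene set {sname!r} is empty")
            cleaned[sname] = sorted(set(genes))
        self.sets = cleaned

    def __len__(self):
        return len(self.sets)


def read_gmt(path, name: str | None = None) -> GeneSetCollection:
    """Tab-separated GMT: set name, description, member genes."""
    sets, descs = {}, {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line (need >= 3 fields): {line[:80]!r}")
            sets[parts[0]] = [g for g in parts[2:] if g]
            descs[parts[0]] = parts[1]
    return GeneSetCollection(name=name or str(path), sets=sets, descriptions=descs)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for sname in collection.sets:
            desc = collection.descriptions.get(sname, "")
            fh.write("\t".join([sname, desc] + collection.sets[sname]) + "\n")


ENRICHMENT_COLUMNS = ["overlap", "set_size", "query_size", "universe_size",
                      "p", "p_adj", "genes", "mean_direction"]


def ora(
    query,
    universe,
    collection: GeneSetCollection,
    min_mapped: int = 3,
    alpha: float = 0.05,
    log2fc: pd.Series | None = None,
    direction_threshold: float = 0.1,
) -> pd.DataFrame:
    """Over-representation of ``query`` within ``universe`` against every set.

    Rows are sorted by (p_adj, p, set name).  When per-gene ``log2fc`` values
    are supplied, ``mean_direction`` summarizes the overlapping genes' mean
    fold change as "up"/"down", or "mixed" when its magnitude stays below
    ``direction_threshold``.  The returned table keeps all tested sets; the
    ``significant`` column applies the alpha cut.
    """
    query = {str(g).upper() for g in query}
    universe = {str(g).upper() for g in universe}
    if not query:
        raise ValueError("query set is empty")
    stray = sorted(query - universe)
    if stray:
        raise ValueError(f"query genes outside the universe: {stray[:10]}"
                         + (" ..." if len(stray) > 10 else ""))
    N, n = len(universe), len(query)
    rows = []
    for sname, genes in collection.sets.items():
        inset = set(genes) & universe
        overlap = sorted(query & inset)
        x, K = len(overlap), len(inset)
        if x < min_mapped or K == 0:
            continue
        p = float(hypergeom.sf(x - 1, N, K, n))
        direction = ""
        if log2fc is not None:
            vals = log2fc.reindex(overlap).dropna()
            if len(vals):
                m = float(vals.mean())
                direction = ("mixed" if abs(m) < direction_threshold
                             else ("up" if m > 0 else "down"))
        rows.append((sname, x, K, n, N, p, overlap, direction))
    table = pd.DataFrame(rows, columns=["set_name", "overlap", "set_size",
                                        "query_size", "universe_size", "p",
                                        "genes", "mean_direction"])
    if table.empty:
        table["p_adj"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
        return table.set_index("set_name")
    table["p_adj"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    table["significant"] = table["p_adj"] < alpha
    table = (table.sort_values(["p_adj", "p", "set_name"])
             .set_index("set_name"))
    return table[["overlap", "set_size", "query_size", "universe_size",
                  "p", "p_adj", "significant", "genes", "mean_direction"]]


def top_pathways(table: pd.DataFrame, n: int) -> pd.DataFrame:
    """First ``n`` rows by (p_adj, p, set name); n beyond the table returns all rows."""
    if n < 0:
        raise ValueError("n must be >= 0")
    ordered = table.reset_index().sort_values(
        ["p_adj", "p", "set_name"], kind="stable").set_index("set_name")
    return ordered.head(n)
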