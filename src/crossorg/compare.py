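"""Cross-study DEG categorization: shared / contrasting / study-specific genes.

A gene significant in both studies (adjusted p below alpha and |log2FC| above
lfc_min in each) is "shared" when the fold-change signs agree and
"contrasting" when they oppose.  A gene significant in exactly one study is
that study's "specific" DEG only if the other study's nominal p exceeds the
non-significance threshold (default 0.5) — i.e. it does not even approach
significance there.  Everything else, including genes tested in only one
study, is "unclassified".
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CATEGORY_COLUMNS = ["category", "log2FC_A", "log2FC_B", "p_adj_A", "p_adj_B",
                    "p_nominal_A", "p_nominal_B", "developmental"]


def categorize_degs(
    table_A: pd.DataFrame,
    table_B: pd.DataFrame,
    alpha: float = 0.05,
    lfc_min: float = 0.1,
    ns_threshold: float = 0.5,
) -> pd.DataFrame:
    """Partition the union of tested genes into the five cross-study categories.

    Genes with a zero fold change in a study have an undefined sign there and
    fall into "unclassified" whenever the sign would matter.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if not 0.0 <= ns_threshold <= 1.0:
        raise ValueError("ns_threshold must be in [0, 1]")
    common = table_A.index.intersection(table_B.index)
    if common.empty:
        raise ValueError("empty intersection of tested genes between studies")
    only_one = table_A.index.symmetric_difference(table_B.index)
    if len(only_one):
        log.info("categorize_degs: %d genes tested in only one study -> unclassified",
                 len(only_one))

    union = table_A.index.union(table_B.index)
    A = table_A.reindex(union)
    B = table_B.reindex(union)
    out = pd.DataFrame(index=union.rename("gene"))
    out["log2FC_A"], out["log2FC_B"] = A["log2FC"], B["log2FC"]
    out["p_adj_A"], out["p_adj_B"] = A["p_adj"], B["p_adj"]
    out["p_nominal_A"], out["p_nominal_B"] = A["p_nominal"], B["p_nominal"]

    sig_A = (A["p_adj"] < alpha) & (A["log2FC"].abs() > lfc_min)
    sig_B = (B["p_adj"] < alpha) & (B["log2FC"].abs() > lfc_min)
    sig_A, sig_B = sig_A.fillna(False), sig_B.fillna(False)
    sgn_A = np.sign(A["log2FC"].fillna(0.0))
    sgn_B = np.sign(B["log2FC"].fillna(0.0))
    signs_ok = (sgn_A != 0) & (sgn_B != 0)

    cat = pd.Series("unclassified", index=union, name="category")
    both = sig_A & sig_B & signs_ok
    cat[both & (sgn_A == sgn_B)] = "shared"
    cat[both & (sgn_A != sgn_B)] = "contrasting"
    cat[sig_A & ~sig_B & (B["p_nominal"] > ns_threshold)] = "specific_A"
    cat[sig_B & ~sig_A & (A["p_nominal"] > ns_threshold)] = "specific_B"
    out.insert(0, "category", cat)
    out["developmental"] = False
    return out


def flag_developmental(table: pd.DataFrame, dev_genes) -> pd.DataFrame:
    """Mark genes on the developmental list (exact uppercase symbol match).

    Categories are left untouched; in human-readable output flagged genes are
    rendered with an asterisk.
    """
    dev = {str(g).upper() for g in dev_genes}
    if not dev:
        raise ValueError("dev_genes must be non-empty")
    out = table.copy()
    out["developmental"] = out.index.str.upper().isin(dev)
    return out


def render_with_asterisks(table: pd.DataFrame) -> pd.DataFrame:
    """Human-readable view: developmental genes get a trailing asterisk."""
    out = table.copy()
    starred = [g + "*" if d else g
               for g, d in zip(out.index, out["developmental"])]
    out.insert(0, "gene_display", starred)
    return out
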