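"""Integration of upstream cell-cell-communication tables.

Ligand-activity tables (ligand, activity score, target genes) and
ligand-receptor pair tables (ligand, receptor, pathway, significance flag) are
consumed as TSV input — the upstream prediction models are not recomputed
here.  The module filters genes by detection fraction, intersects the targets
of the top-activity ligands with the genes of significantly altered
ligand-receptor pairs, and extracts pathways enriched for that intersection in
both studies.
"""

from __future__ import annotations

import logging
import warnings

import anndata as ad
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def read_ligand_table(path) -> pd.DataFrame:
    """TSV with columns ligand, activity, targets (comma-separated)."""
    tab = pd.read_csv(path, sep="\t", comment="#")
    missing = {"ligand", "activity", "targets"} - set(tab.columns)
    if missing:
        raise ValueError(f"ligand table missing columns: {sorted(missing)}")
    if tab["ligand"].duplicated().any():
        raise ValueError("duplicate ligands in ligand table")
    if (tab["targets"].fillna("") == "").any():
        raise ValueError("empty target list in ligand table")
    return tab


def read_pair_table(path) -> pd.DataFrame:
    """TSV with columns ligand, receptor, pathway, significant (0/1)."""
    tab = pd.read_csv(path, sep="\t", comment="#")
    missing = {"ligand", "receptor", "pathway", "significant"} - set(tab.columns)
    if missing:
        raise ValueError(f"pair table missing columns: {sorted(missing)}")
    return tab


def target_sets(ligand_table: pd.DataFrame) -> dict:
    return {row.ligand: set(str(row.targets).split(","))
            for row in ligand_table.itertuples()}


def expression_filter(data: ad.AnnData, min_fraction: float = 0.10) -> set:
    """Genes detected (count > 0) in strictly more than ``min_fraction`` of cells."""
    if not 0.0 <= min_fraction < 1.0:
        raise ValueError("min_fraction must be in [0, 1)")
    from scipy import sparse
    X = data.X
    frac = (np.asarray((X > 0).sum(axis=0)).ravel() if sparse.issparse(X)
            else (np.asarray(X) > 0).sum(axis=0)) / data.n_obs
    return set(np.asarray(data.var_names)[frac > min_fraction])


def intersect_targets(
    ligands: pd.DataFrame,
    pairs: pd.DataFrame,
    top_n_ligands: int = 20,
    mode: str = "strict",
) -> set:
    """Targets of the top ligands intersected with significant-pair genes.

    T is the union of target genes of the ``top_n_ligands`` by activity score
    (ties broken by ligand name).  In "strict" mode the result is T
    intersected with the ligand and receptor genes of significant pairs; in
    "augmented" mode the pair-gene set is widened by the targets of ligands
    that appear in a significant pair.  The selection is logged.
    """
    if mode not in ("strict", "augmented"):
        raise ValueError("mode must be 'strict' or 'augmented'")
    ranked = ligands.sort_values(["activity", "ligand"], ascending=[False, True])
    top = ranked.head(top_n_ligands)
    tsets = target_sets(top)
    T = set().union(*tsets.values()) if tsets else set()
    sig = pairs[pairs["significant"].astype(bool)]
    if sig.empty:
        warnings.warn("no significant ligand-receptor pairs; intersection is empty",
                      stacklevel=2)
        return set()
    L = set(sig["ligand"]) | set(sig["receptor"])
    if mode == "augmented":
        all_targets = target_sets(ligands)
        for lig in set(sig["ligand"]):
            L |= all_targets.get(lig, set())
    result = T & L
    log.info("intersect_targets[%s]: %d top-ligand targets, %d pair genes -> %d genes",
             mode, len(T), len(L), len(result))
    return result


def shared_significant_pathways(
    enrich_A: pd.DataFrame,
    enrich_B: pd.DataFrame,
    alpha: float = 0.05,
    top_n: int = 5,
) -> pd.DataFrame:
    """Pathways adjusted-significant in both studies, ranked by the worse p_adj.

    Returns the ``top_n`` rows ordered by max(p_adj_A, p_adj_B) ascending,
    ties by pathway name, with both adjusted p-values and overlap gene counts.
    """
    sig_A = enrich_A[enrich_A["p_adj"] < alpha]
    sig_B = enrich_B[enrich_B["p_adj"] < alpha]
    common = sig_A.index.intersection(sig_B.index)
    if common.empty:
        log.info("shared_significant_pathways: no pathway significant in both studies")
    out = pd.DataFrame({
        "p_adj_A": sig_A.loc[common, "p_adj"],
        "p_adj_B": sig_B.loc[common, "p_adj"],
        "n_genes_A": sig_A.loc[common, "overlap"],
        "n_genes_B": sig_B.loc[common, "overlap"],
    }, index=common.rename("pathway"))
    out["rank_key"] = out[["p_adj_A", "p_adj_B"]].max(axis=1)
    out = out.sort_index().sort_values("rank_key", kind="stable")
    return out.head(top_n)
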