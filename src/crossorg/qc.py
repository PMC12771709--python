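"""Cell-level quality control, normalization, and cluster-composition statistics."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import chi2_contingency

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCThresholds:
    """Cell retention bounds: detected-gene range and mitochondrial percentage cap.

    A cell is kept iff min_genes <= detected genes <= max_genes and its
    mitochondrial percentage is strictly below max_mito_pct.
    """

    min_genes: int = 200
    max_genes: int = 8000
    max_mito_pct: float = 5.0

    def __post_init__(self):
        if not self.min_genes < self.max_genes:
            raise ValueError("min_genes must be < max_genes")
        if not 0.0 <= self.max_mito_pct <= 100.0:
            raise ValueError("max_mito_pct must be in [0, 100]")


@dataclass
class CompositionReport:
    """Condition x cluster contingency table with Pearson chi-squared statistics."""

    table: pd.DataFrame  # rows: conditions; columns: clusters; integer counts
    ratios: pd.Series    # per-cluster disease/control count ratio
    proportions: pd.DataFrame  # per-condition % of total cells
    chi2: float
    df: int
    p: float


def detected_genes(data: ad.AnnData) -> np.ndarray:
    X = data.X
    if sparse.issparse(X):
        return np.asarray((X > 0).sum(axis=1)).ravel()
    return (np.asarray(X) > 0).sum(axis=1)


def mito_percent(data: ad.AnnData) -> np.ndarray:
    """Percent of each cell's raw counts coming from MT- flagged genes."""
    if "mito" in data.var:
        mask = data.var["mito"].to_numpy(dtype=bool)
    else:
        mask = data.var_names.str.upper().str.startswith("MT-").to_numpy()
    X = data.X
    total = np.asarray(X.sum(axis=1)).ravel().astype(float)
    mito = np.asarray(X[:, mask].sum(axis=1)).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * mito / total, 0.0)
    return pct


def filter_cells(data: ad.AnnData, thresholds: QCThresholds = QCThresholds()) -> ad.AnnData:
    """Apply detected-gene and mitochondrial-percentage filters (gene set unchanged)."""
    det = detected_genes(data)
    pct = mito_percent(data)
    in_range = (det >= thresholds.min_genes) & (det <= thresholds.max_genes)
    mito_ok = pct < thresholds.max_mito_pct  # strictly below the cap
    keep = in_range & mito_ok
    if not keep.any():
        binding = ("mito percentage cap max_mito_pct" if in_range.any()
                   else "detected-gene range [min_genes, max_genes]")
        raise ValueError(f"no cells survive filtering; binding threshold: {binding}")
    log.info("filter_cells: %d -> %d cells (removed %d by gene range, %d by mito%%)",
             data.n_obs, int(keep.sum()), int((~in_range).sum()),
             int((in_range & ~mito_ok).sum()))
    return data[keep].copy()


def normalize(data: ad.AnnData, target_sum: int = 10_000) -> ad.AnnData:
    """Total-count scale each cell to ``target_sum`` and log1p into layer ``lognorm``.

    Raw counts in ``.X`` are preserved; the scaled pre-log values sum to
    ``target_sum`` per cell.
    """
    if target_sum <= 0:
        raise ValueError("target_sum must be positive")
    totals = np.asarray(data.X.sum(axis=1)).ravel().astype(float)
    if (totals == 0).any():
        n = int((totals == 0).sum())
        raise ValueError(f"{n} cell(s) have zero total counts; filter before normalizing")
    out = data.copy()
    X = out.X.astype(float)
    if sparse.issparse(X):
        scaled = sparse.diags(target_sum / totals) @ X.tocsr()
        out.layers["lognorm"] = scaled.log1p()
    else:
        scaled = X * (target_sum / totals)[:, None]
        out.layers["lognorm"] = np.log1p(scaled)
    out.uns["target_sum"] = int(target_sum)
    return out


def chi_squared_composition(
    table: pd.DataFrame,
    control_label: str = "control",
    disease_label: str = "disease",
) -> CompositionReport:
    """Pearson chi-squared (no continuity correction) on a condition x cluster table."""
    tab = table.astype(int)
    if (tab < 0).to_numpy().any():
        raise ValueError("contingency table entries must be non-negative")
    res = chi2_contingency(tab.to_numpy(), correction=False)
    with np.errstate(divide="ignore"):
        ratios = tab.loc[disease_label] / tab.loc[control_label]
    proportions = 100.0 * tab.sum(axis=1) / tab.to_numpy().sum()
    return CompositionReport(
        table=tab, ratios=ratios.astype(float),
        proportions=proportions.to_frame("pct_of_cells"),
        chi2=float(res.statistic), df=int(res.dof), p=float(res.pvalue),
    )


def composition_test(
    data: ad.AnnData,
    condition_field: str = "condition",
    cluster_field: str = "cell_type",
    control_label: str = "control",
    disease_label: str = "disease",
) -> CompositionReport:
    """Condition-by-cluster composition test on a labelled dataset."""
    for f in (condition_field, cluster_field):
        if f not in data.obs:
            raise ValueError(f"missing obs field {f!r}")
        if data.obs[f].isna().any():
            raise ValueError(f"obs field {f!r} has unlabelled cells")
    table = pd.crosstab(data.obs[condition_field], data.obs[cluster_field])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need >= 2 conditions and >= 2 clusters")
    return chi_squared_composition(table, control_label, disease_label)
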