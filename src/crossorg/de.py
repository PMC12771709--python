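"""Per-gene Poisson likelihood-ratio differential expression with library-size offset.

For each gene the Poisson log-linear model with a condition term and a
log(total-counts) offset is compared against the intercept-plus-offset null by
a likelihood-ratio test.  Both models have closed-form maximum-likelihood
solutions: the fitted rate per library-size unit is the group (respectively
grand) count sum divided by the group (grand) exposure, so the deviance
difference is

    LR = 2 * [ S_d * log(r_d / r) + S_c * log(r_c / r) ],

with S_g the per-group count sum, r_g = S_g / T_g the group rate, T_g the
group exposure (sum of per-cell total counts) and r the pooled rate.  P-values
come from the chi-squared distribution with 1 df.  This is exact, vectorizes
over genes, and is invariant to rescaling library sizes within a group.
"""

from __future__ import annotations

import logging

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

DE_COLUMNS = ["log2FC", "p_nominal", "p_adj", "pct_disease", "pct_control", "significant"]


def _xlogy(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """x * log(y) with the 0 * log(0) = 0 convention."""
    out = np.zeros_like(x, dtype=float)
    nz = x > 0
    out[nz] = x[nz] * np.log(y[nz])
    return out


def poisson_lrt(counts_a: np.ndarray, counts_b: np.ndarray,
                exposure_a: np.ndarray, exposure_b: np.ndarray):
    """Vectorized LR statistic and p-value for genes (columns) across two groups.

    ``counts_*`` are cells x genes arrays, ``exposure_*`` per-cell exposures
    (total raw counts).  Returns (lr, p) arrays over genes.
    """
    S_a = np.asarray(counts_a.sum(axis=0)).ravel().astype(float)
    S_b = np.asarray(counts_b.sum(axis=0)).ravel().astype(float)
    T_a = float(np.sum(exposure_a))
    T_b = float(np.sum(exposure_b))
    r_a = S_a / T_a
    r_b = S_b / T_b
    r = (S_a + S_b) / (T_a + T_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        lr = 2.0 * (_xlogy(S_a, np.where(r > 0, r_a / np.where(r > 0, r, 1.0), 1.0))
                    + _xlogy(S_b, np.where(r > 0, r_b / np.where(r > 0, r, 1.0), 1.0)))
    lr = np.maximum(lr, 0.0)
    return lr, chi2.sf(lr, df=1)


def poisson_de(
    data: ad.AnnData,
    condition_field: str = "condition",
    cell_type: str | None = None,
    cell_type_field: str = "cell_type",
    control_label: str = "control",
    disease_label: str = "disease",
    min_pct: float = 0.1,
    target_sum: int | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Poisson LRT per gene (disease vs control) within one cell type.

    Genes are tested if expressed in more than ``min_pct`` of cells in at least
    one group; all-zero genes are excluded and logged.  log2FC is computed on
    group means of total-count-normalized expression with pseudocount
    ``pseudocount``.  Returns a DETable-shaped frame indexed by gene with
    ``p_adj``/``significant`` left for :func:`adjust_and_flag`.
    """
    if condition_field not in data.obs:
        raise ValueError(f"missing obs field {condition_field!r}")
    sub = data
    if cell_type is not None:
        if cell_type_field not in data.obs:
            raise ValueError(f"missing obs field {cell_type_field!r}")
        sub = data[data.obs[cell_type_field] == cell_type]
    cond = sub.obs[condition_field]
    for lab in (control_label, disease_label):
        if (cond == lab).sum() < 2:
            raise ValueError(f"condition {lab!r} has fewer than 2 cells"
                             + (f" of type {cell_type!r}" if cell_type else ""))
    if target_sum is None:
        target_sum = int(sub.uns.get("target_sum", 10_000))

    X = sub.X
    Xd = (X.toarray() if sparse.issparse(X) else np.asarray(X)).astype(float)
    mask_d = (cond == disease_label).to_numpy()
    mask_c = (cond == control_label).to_numpy()
    totals = Xd.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("cells with zero total counts present; run QC first")

    pct_d = (Xd[mask_d] > 0).mean(axis=0)
    pct_c = (Xd[mask_c] > 0).mean(axis=0)
    nonzero = (Xd.sum(axis=0) > 0)
    testable = nonzero & ((pct_d > min_pct) | (pct_c > min_pct))
    n_allzero = int((~nonzero).sum())
    if n_allzero:
        log.info("poisson_de: excluded %d all-zero genes", n_allzero)
    if not testable.any():
        raise ValueError("no gene passes the expression filter")

    lr, p = poisson_lrt(Xd[mask_d][:, testable], Xd[mask_c][:, testable],
                        totals[mask_d], totals[mask_c])

    norm = Xd / totals[:, None] * target_sum
    m_d = norm[mask_d][:, testable].mean(axis=0)
    m_c = norm[mask_c][:, testable].mean(axis=0)
    log2fc = np.log2((m_d + pseudocount) / (m_c + pseudocount))

    out = pd.DataFrame(
        {"log2FC": log2fc, "p_nominal": p, "p_adj": np.nan,
         "pct_disease": pct_d[testable], "pct_control": pct_c[testable],
         "significant": False},
        index=pd.Index(np.asarray(sub.var_names)[testable], name="gene"),
    )
    return out


def adjust_and_flag(
    table: pd.DataFrame,
    alpha: float = 0.05,
    lfc_min: float = 0.1,
    method: str = "bonferroni",
) -> pd.DataFrame:
    """Multiple-testing adjustment plus the significance flag.

    ``method`` is "bonferroni" (p_adj = min(1, p*m), the paper-reported
    procedure) or "bh" (Benjamini-Hochberg step-up).  significant iff
    p_adj < alpha and |log2FC| > lfc_min.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if method not in ("bonferroni", "bh"):
        raise ValueError("method must be 'bonferroni' or 'bh'")
    out = table.copy()
    p = out["p_nominal"].to_numpy(dtype=float)
    sm_method = "bonferroni" if method == "bonferroni" else "fdr_bh"
    out["p_adj"] = multipletests(p, method=sm_method)[1]
    out["significant"] = (out["p_adj"] < alpha) & (out["log2FC"].abs() > lfc_min)
    return out
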