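"""Overlap statistics against external gene lists: coverage, directional
concordance, and one-sided Fisher enrichment.

Coverage is the percentage of query (organoid) DEGs also present in the
reference list: 100 * |intersection| / |query|.  Directional concordance
splits the intersection by fold-change sign agreement.  Overlap significance
is the one-sided (enrichment) Fisher exact test, i.e. the hypergeometric upper
tail of the 2x2 table implied by the universe, query and reference sets.
"""

from __future__ import annotations

import decimal
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

log = logging.getLogger(__name__)


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal round-half-up, the printing convention for percentages."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(value)).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass
class OverlapReport:
    n_query: int
    n_reference: int
    n_intersect: int
    coverage_pct: float           # full precision; render with round_half_up
    intersect_genes: list = field(default_factory=list)
    concordant: list = field(default_factory=list)
    discordant: list = field(default_factory=list)
    fisher_p: float = float("nan")
    universe_size: int = 0

    def as_dict(self) -> dict:
        return {"n_query": self.n_query, "n_reference": self.n_reference,
                "n_intersect": self.n_intersect,
                "coverage_pct": self.coverage_pct,
                "coverage_pct_1dp": round_half_up(self.coverage_pct, 1),
                "n_concordant": len(self.concordant),
                "n_discordant": len(self.discordant),
                "fisher_p": self.fisher_p, "universe_size": self.universe_size}


def coverage(query, reference) -> OverlapReport:
    """Coverage (%) = 100 * |query ∩ reference| / |query|."""
    query, reference = set(query), set(reference)
    if not query:
        raise ValueError("query gene set is empty")
    inter = sorted(query & reference)
    return OverlapReport(
        n_query=len(query), n_reference=len(reference), n_intersect=len(inter),
        coverage_pct=100.0 * len(inter) / len(query), intersect_genes=inter)


def directional_concordance(query_table: pd.DataFrame,
                            reference_table: pd.DataFrame) -> OverlapReport:
    """Split intersecting genes by log2FC sign agreement; zero signs excluded."""
    for tab, name in ((query_table, "query"), (reference_table, "reference")):
        if "log2FC" not in tab.columns:
            raise ValueError(f"{name} table lacks a log2FC column")
    report = coverage(query_table.index, reference_table.index)
    qs = np.sign(query_table.loc[report.intersect_genes, "log2FC"])
    rs = np.sign(reference_table.loc[report.intersect_genes, "log2FC"])
    defined = (qs != 0) & (rs != 0)
    dropped = [g for g, ok in defined.items() if not ok]
    if dropped:
        log.info("directional_concordance: %d genes with zero log2FC excluded",
                 len(dropped))
    report.concordant = sorted(g for g in report.intersect_genes
                               if defined[g] and qs[g] == rs[g])
    report.discordant = sorted(g for g in report.intersect_genes
                               if defined[g] and qs[g] != rs[g])
    return report


def overlap_fisher(query, reference, universe) -> float:
    """One-sided (enrichment) Fisher exact p for the query/reference overlap.

    Equals the hypergeometric upper tail P(X >= x) with N = |universe|,
    K = |reference|, n = |query| — symmetric in query and reference.
    """
    query, reference, universe = set(query), set(reference), set(universe)
    for name, s in (("query", query), ("reference", reference)):
        stray = sorted(s - universe)
        if stray:
            raise ValueError(f"{name} genes outside the universe: {stray[:10]}"
                             + (" ..." if len(stray) > 10 else ""))
    x = len(query & reference)
    return float(hypergeom.sf(x - 1, len(universe), len(reference), len(query)))


def gwas_overlap(de_table: pd.DataFrame, gwas_genes, universe) -> OverlapReport:
    """Overlap of significant DEGs with GWAS genes on the intersection background.

    ``universe`` is the stated background: genes tested for differential
    expression intersected with the GWAS study's gene universe.  Query =
    significant DEGs within it, reference = GWAS genes within it.
    """
    universe = {str(g).upper() for g in universe}
    if not universe:
        raise ValueError("empty background universe")
    if "significant" not in de_table.columns:
        raise ValueError("DE table lacks a 'significant' column; run adjust_and_flag")
    degs = {str(g).upper() for g in de_table.index[de_table["significant"]]} & universe
    gwas = {str(g).upper() for g in gwas_genes} & universe
    if not gwas:
        warnings.warn("no GWAS gene inside the background universe", stacklevel=2)
        return OverlapReport(n_query=len(degs), n_reference=0, n_intersect=0,
                             coverage_pct=0.0, universe_size=len(universe))
    if not degs:
        warnings.warn("no significant DEG inside the background universe", stacklevel=2)
        return OverlapReport(n_query=0, n_reference=len(gwas), n_intersect=0,
                             coverage_pct=0.0, universe_size=len(universe))
    report = coverage(degs, gwas)
    report.fisher_p = overlap_fisher(degs, gwas, universe)
    report.universe_size = len(universe)
    return report
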