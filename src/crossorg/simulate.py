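"""Synthetic single-cell, network and reference-list generators with known ground truth.

Two paired two-condition studies (arms ``"A"`` and ``"B"``) are simulated with
negative-binomial counts, planted differential-expression effects (shared /
contrasting / arm-specific), mitochondrial genes, cell-type identity programs
and log-normal library-size variation.  A signed regulatory network with known
perturbagens and post-mortem / GWAS / gene-set reference inputs with planted
overlap complete the pipeline inputs.  Every generator is deterministic under a
fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import NamedTuple

import anndata as ad
import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

CATEGORIES = ("shared", "contrasting", "specific_A", "specific_B")
ARMS = ("A", "B")


def _rng(seed: int, *key: str) -> np.random.Generator:
    """Independent stream derived from the master seed and a string key."""
    spawn = [int.from_bytes(k.encode(), "little") % (2**31) for k in key]
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one paired two-condition study simulation.

    ``baseline_mean`` is the mean of the log-normal distribution of per-gene
    negative-binomial means (counts per cell); ``dispersion`` is the NB size
    parameter (variance = mu + mu^2/dispersion).  Planted genes have their
    disease-condition mean multiplied by ``2**(+-planted_lfc)``.
    """

    n_genes: int = 2000
    cell_types: tuple = (("Neurons", 300), ("Astrocytes", 200), ("Other", 100))
    baseline_mean: float = 1.0
    baseline_sigma: float = 1.0
    dispersion: float = 2.0
    n_shared: int = 40
    n_contrasting: int = 40
    n_specific_A: int = 20
    n_specific_B: int = 20
    planted_lfc: float = 1.0
    mito_gene_fraction: float = 0.008
    mito_expr_mean_frac: float = 0.03
    libsize_cv: float = 0.3
    n_marker_genes: int = 30
    marker_fold: float = 8.0
    n_developmental: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not self.cell_types:
            raise ValueError("cell_types must be non-empty")
        for name, n in self.cell_types:
            if n < 1:
                raise ValueError(f"cell_types: n_cells for {name!r} must be >= 1")
        for f in ("baseline_mean", "baseline_sigma", "dispersion", "marker_fold"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        for f in ("mito_gene_fraction", "mito_expr_mean_frac", "libsize_cv"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f} must be in [0, 1]")
        planted = self.n_shared + self.n_contrasting + self.n_specific_A + self.n_specific_B
        if min(self.n_shared, self.n_contrasting, self.n_specific_A, self.n_specific_B) < 0:
            raise ValueError("planted DEG counts must be non-negative")
        if planted > self.n_genes:
            raise ValueError("planted DEG counts: n_shared + n_contrasting + "
                             "n_specific_A + n_specific_B exceeds n_genes")
        if self.n_developmental < 0:
            raise ValueError("n_developmental must be >= 0")

    @property
    def n_planted(self) -> int:
        return self.n_shared + self.n_contrasting + self.n_specific_A + self.n_specific_B


@dataclass
class GroundTruth:
    """Planted truth of a simulation: category partition, markers, networks, references."""

    categories: pd.DataFrame = None  # index gene; columns category, sign_A, sign_B, lfc
    markers: dict = field(default_factory=dict)  # cell type -> marker gene list
    developmental: list = field(default_factory=list)
    genes: list = field(default_factory=list)
    perturbagens: list = field(default_factory=list)  # dicts: node, direction, score
    references: dict = field(default_factory=dict)

    def planted_genes(self, *categories: str) -> set:
        if self.categories is None:
            return set()
        cats = categories or CATEGORIES
        return set(self.categories.index[self.categories["category"].isin(cats)])

    def to_dict(self) -> dict:
        return {
            "categories": (self.categories.reset_index().to_dict(orient="list")
                           if self.categories is not None else None),
            "markers": self.markers,
            "developmental": list(self.developmental),
            "genes": list(self.genes),
            "perturbagens": self.perturbagens,
            "references": self.references,
        }


def _plan(config: SimConfig) -> dict:
    """Seed-derived planted-effect plan shared by both study arms."""
    rng = _rng(config.seed, "plan")
    n_mito = int(round(config.n_genes * config.mito_gene_fraction))
    n_reg = config.n_genes - n_mito
    genes = [f"G{i:04d}" for i in range(n_reg)] + [f"MT-G{i:02d}" for i in range(n_mito)]
    mito = np.zeros(config.n_genes, dtype=bool)
    mito[n_reg:] = True

    # per-gene baseline means, log-normal with mean baseline_mean
    sig = config.baseline_sigma
    base = rng.lognormal(np.log(config.baseline_mean) - sig**2 / 2, sig, config.n_genes)

    # cell-type identity programs: disjoint marker blocks among regular genes
    order = rng.permutation(n_reg)
    pos = 0
    markers = {}
    for name, _ in config.cell_types:
        markers[name] = sorted(genes[i] for i in order[pos:pos + config.n_marker_genes])
        pos += config.n_marker_genes
    # planted DEGs drawn from the remaining regular genes, restricted to those
    # expressed at or above the median baseline so the planted categories are
    # in-principle recoverable (an effect on a never-detected gene is not a DEG)
    pool = order[pos:]
    expressed = pool[base[pool] >= np.median(base)]
    if config.n_planted > len(expressed):
        raise ValueError("n_genes too small for requested markers plus planted DEGs")
    chosen = expressed[:config.n_planted]
    cats = np.repeat(
        list(CATEGORIES),
        [config.n_shared, config.n_contrasting, config.n_specific_A, config.n_specific_B],
    )
    signs = rng.choice([-1, 1], size=config.n_planted)
    sign_A = np.where(cats == "specific_B", 0, signs)
    sign_B = np.select(
        [cats == "shared", cats == "contrasting", cats == "specific_B"],
        [signs, -signs, signs],
        default=0,
    )
    categories = pd.DataFrame(
        {"category": cats, "sign_A": sign_A, "sign_B": sign_B,
         "lfc": config.planted_lfc},
        index=pd.Index([genes[i] for i in chosen], name="gene"),
    ).sort_index()

    dev = sorted(rng.choice(genes, size=min(config.n_developmental, config.n_genes),
                            replace=False).tolist())
    return {"genes": genes, "mito": mito, "base": base, "markers": markers,
            "categories": categories, "developmental": dev,
            "gene_index": {g: i for i, g in enumerate(genes)}}


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion > 1e6:  # effectively Poisson
        return rng.poisson(mean)
    lam = rng.gamma(dispersion, mean / dispersion)
    return rng.poisson(lam)


def generate_study(config: SimConfig, study_label: str) -> tuple[ad.AnnData, GroundTruth]:
    """Simulate one arm ("A" or "B") of the paired two-study design.

    Returns raw NB counts (cells x genes, sparse) with per-cell condition,
    sample and true cell-type labels, per-gene mitochondrial / developmental /
    planted-category annotations, and the shared ground truth.  Calling with
    the same config and both labels yields paired studies in which shared genes
    move with the same sign and contrasting genes with opposite signs.
    """
    if study_label not in ARMS:
        raise ValueError(f"study_label must be one of {ARMS}, got {study_label!r}")
    plan = _plan(config)
    genes, mito, base = plan["genes"], plan["mito"], plan["base"]
    cats = plan["categories"]
    rng = _rng(config.seed, "counts", study_label)

    # disease-condition fold change per gene for this arm
    sign_col = cats[f"sign_{study_label}"]
    fold = np.ones(config.n_genes)
    for g, s in sign_col.items():
        if s != 0:
            fold[plan["gene_index"][g]] = 2.0 ** (s * cats.at[g, "lfc"])

    cv = config.libsize_cv
    lib_sigma = np.sqrt(np.log1p(cv**2)) if cv > 0 else 0.0

    blocks, obs_rows = [], []
    for cond in ("control", "disease"):
        for ct_name, n_cells in config.cell_types:
            means = base.copy()
            midx = [plan["gene_index"][g] for g in plan["markers"][ct_name]]
            means[midx] *= config.marker_fold
            if cond == "disease":
                means *= fold
            # rescale mito means so the expected mito library share is exact
            if mito.any() and config.mito_expr_mean_frac > 0:
                f = config.mito_expr_mean_frac
                means[mito] = (f / (1 - f)) * means[~mito].sum() / mito.sum()
            lib = (rng.lognormal(-lib_sigma**2 / 2, lib_sigma, n_cells)
                   if lib_sigma > 0 else np.ones(n_cells))
            mean_mat = lib[:, None] * means[None, :]
            blocks.append(_nb_sample(rng, mean_mat, config.dispersion))
            half = n_cells // 2
            for i in range(n_cells):
                obs_rows.append((cond, f"{cond}_s{1 if i < half else 2}", ct_name))

    X = sparse.csr_matrix(np.vstack(blocks).astype(np.int32))
    obs = pd.DataFrame(obs_rows, columns=["condition", "sample", "cell_type"])
    obs.index = [f"{study_label}_cell{i:05d}" for i in range(obs.shape[0])]
    var = pd.DataFrame(index=pd.Index(genes, name="gene"))
    var["mito"] = mito
    var["developmental"] = var.index.isin(plan["developmental"])
    var["planted_category"] = cats["category"].reindex(var.index).fillna("none")
    adata = ad.AnnData(X=X, obs=obs, var=var)
    adata.uns["study_label"] = study_label
    adata.uns["sim_config"] = {k: (list(map(list, v)) if k == "cell_types" else v)
                               for k, v in asdict(config).items()}

    truth = GroundTruth(categories=cats, markers=plan["markers"],
                        developmental=plan["developmental"], genes=list(genes))
    return adata, truth


def generate_signed_network(
    n_nodes: int,
    edge_density: float,
    n_true_regulators: int = 1,
    seed: int = 0,
) -> tuple[nx.DiGraph, GroundTruth]:
    """Acyclic signed digraph with planted top regulators.

    Node 0 (name ``N00``) is the primary regulator: every node is reachable
    from it, and observed change signs are assigned so that down-modulating it
    reverts the maximum number of nodes.  The recorded ground-truth score of
    each regulator is its exhaustively computed reversion score, and for a
    single planted regulator the construction retries until it is the strict
    top scorer.
    """
    from . import network as net

    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    if not 0.0 <= edge_density <= 1.0:
        raise ValueError("edge_density must be in [0, 1]")
    if not 1 <= n_true_regulators < n_nodes:
        raise ValueError("n_true_regulators must be in [1, n_nodes)")
    n_pairs = n_nodes * (n_nodes - 1) // 2
    m_target = int(round(edge_density * n_pairs))
    if m_target == 0:
        raise ValueError("edge_density too low: produces zero edges")

    names = [f"N{i:02d}" for i in range(n_nodes)]
    rng = _rng(seed, "network")
    last = None
    for _attempt in range(80):
        g = nx.DiGraph()
        g.add_nodes_from(names)
        # spanning backbone rooted at node 0 keeps every node reachable
        for j in range(1, n_nodes):
            i = int(rng.integers(0, j))
            g.add_edge(names[i], names[j], sign=int(rng.choice([-1, 1])))
        pairs = [(i, j) for i in range(n_nodes) for j in range(i + 1, n_nodes)
                 if not g.has_edge(names[i], names[j])]
        extra = max(0, m_target - (n_nodes - 1))
        if extra and pairs:
            for k in rng.choice(len(pairs), size=min(extra, len(pairs)), replace=False):
                i, j = pairs[k]
                g.add_edge(names[i], names[j], sign=int(rng.choice([-1, 1])))

        predicted = net.propagate_sign(g, names[0], "down")
        observed = {}
        for node in names[1:]:
            p = predicted.get(node)
            if p in (-1, 1):
                observed[node] = -p  # down-modulating node 0 reverts it
            else:
                observed[node] = int(rng.choice([-1, 1]))
        results = net.perturbagen_score(g, observed)
        scores = {r.node: r.score for r in results}
        regs = names[:n_true_regulators]
        truth = GroundTruth(perturbagens=[
            {"node": r, "direction": next(x.direction for x in results if x.node == r),
             "score": scores[r]} for r in regs])
        last = (g, observed, truth)
        if n_true_regulators > 1:
            break
        others = [s for n, s in scores.items() if n != names[0]]
        if not others or scores[names[0]] > max(others):
            break
    g, observed, truth = last
    nx.set_node_attributes(g, observed, "observed_sign")
    return g, truth


class ReferenceBundle(NamedTuple):
    post_mortem: pd.DataFrame  # index gene; columns log2FC, p_adj
    gwas_genes: list
    gene_sets: "object"  # enrichment.GeneSetCollection
    truth: dict


def generate_reference_lists(
    de_truth: GroundTruth,
    overlap_fraction: float = 0.5,
    universe_size: int | None = None,
    seed: int = 0,
    sign_agreement: float = 1.0,
) -> ReferenceBundle:
    """Post-mortem DE table, GWAS gene list and GMT collection with planted overlap.

    ``overlap_fraction`` of the planted organoid DEGs appear in the post-mortem
    table (with ``sign_agreement`` of them keeping the planted arm-A sign) and,
    independently drawn, in the GWAS list; decoy genes are drawn from the
    non-planted universe.  The GMT collection contains one set enriched for
    planted DEGs and null sets of random genes.
    """
    from .enrichment import GeneSetCollection

    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0, 1]")
    if not 0.0 <= sign_agreement <= 1.0:
        raise ValueError("sign_agreement must be in [0, 1]")
    universe = list(de_truth.genes)
    if universe_size is not None:
        if universe_size < 1:
            raise ValueError("universe_size must be >= 1")
        universe = universe[:universe_size]
    planted = sorted(de_truth.planted_genes() & set(universe))
    rng = _rng(seed, "references")
    n_overlap = int(round(overlap_fraction * len(planted)))
    if planted and 0 < overlap_fraction * len(planted) < 1:
        warnings.warn("overlap_fraction selects fewer than one planted gene; "
                      "reference overlap will be empty", stacklevel=2)
    nonplanted = sorted(set(universe) - set(planted))

    def pick(seq, k):
        k = min(k, len(seq))
        return sorted(rng.choice(seq, size=k, replace=False).tolist()) if k else []

    pm_overlap = pick(planted, n_overlap)
    pm_decoys = pick(nonplanted, max(20, n_overlap))
    sign_a = de_truth.categories["sign_A"] if de_truth.categories is not None else pd.Series(dtype=int)
    rows = []
    for g in pm_overlap:
        s = int(sign_a.get(g, 0)) or int(rng.choice([-1, 1]))
        if rng.random() >= sign_agreement:
            s = -s
        rows.append((g, s * float(rng.lognormal(np.log(0.5), 0.3)), 1e-4))
    for g in pm_decoys:
        rows.append((g, float(rng.choice([-1, 1])) * float(rng.lognormal(np.log(0.4), 0.3)), 1e-3))
    post_mortem = (pd.DataFrame(rows, columns=["gene", "log2FC", "p_adj"])
                   .set_index("gene").sort_index())

    gwas_overlap = pick(planted, n_overlap)
    gwas = sorted(set(gwas_overlap) | set(pick(nonplanted, max(30, n_overlap))))

    enriched = pick(planted, min(50, len(planted)))
    sets, descs = {}, {}
    if enriched:
        sets["PLANTED_DEG_SET"] = enriched
        descs["PLANTED_DEG_SET"] = "synthetic set enriched for planted DEGs"
    for i in range(3):
        sets[f"NULL_SET_{i + 1}"] = pick(universe, 40)
        descs[f"NULL_SET_{i + 1}"] = "synthetic null set"
    collection = GeneSetCollection(name="synthetic_sets", sets=sets, descriptions=descs)

    truth = {"post_mortem_overlap": pm_overlap, "gwas_overlap": gwas_overlap,
             "enriched_set": "PLANTED_DEG_SET" if enriched else None,
             "universe_size": len(universe)}
    return ReferenceBundle(post_mortem, gwas, collection, truth)


def generate_ccc_tables(
    genes: list,
    planted_targets: list,
    n_ligands: int = 15,
    n_targets: int = 25,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic ligand-activity and ligand-receptor tables (stand-ins for the
    output schema of upstream cell-cell-communication tools).

    The top-activity ligand targets ``planted_targets`` and appears in a
    significant ligand-receptor pair, so the planted target program survives
    the intersection step downstream.
    """
    rng = _rng(seed, "ccc")
    ligands = [f"LIG{i:02d}" for i in range(n_ligands)]
    acts = np.sort(rng.uniform(0.1, 0.6, n_ligands))[::-1]
    acts[0] = 0.95  # planted ligand dominates
    target_lists = [sorted(planted_targets)]
    pool = sorted(set(genes) - set(planted_targets))
    for _ in range(n_ligands - 1):
        k = min(n_targets, len(pool))
        target_lists.append(sorted(rng.choice(pool, size=k, replace=False).tolist()))
    ligand_table = pd.DataFrame({
        "ligand": ligands, "activity": acts,
        "targets": [",".join(t) for t in target_lists],
    })
    rows = []
    for i, lig in enumerate(ligands):
        rows.append((lig, f"RCP{i:02d}", f"{lig}_PATHWAY", int(i < max(3, n_ligands // 3))))
    # planted targets are carried by the top ligand's significant pair; augment
    # the pair-gene universe with the targets themselves so the strict
    # gene-level intersection is non-trivial
    for g in sorted(planted_targets)[: len(planted_targets) // 2]:
        rows.append((ligands[0], g, f"{ligands[0]}_PATHWAY", 1))
    pair_table = pd.DataFrame(rows, columns=["ligand", "receptor", "pathway", "significant"])
    return ligand_table, pair_table
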