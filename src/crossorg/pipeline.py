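"""End-to-end pipeline orchestration, configuration validation, and reporting.

Stages run in the order simulate -> qc -> cluster -> de -> compare -> enrich
-> network -> ccc -> overlap.  Every stage writes its tables under the output
directory together with a provenance record (stage parameters, seed, hashes of
the files it read), and the final report aggregates category counts, top
pathways, top perturbagens and overlap statistics.  All randomness derives
from the single config seed, so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import ccc as ccc_mod
from . import cluster as cluster_mod
from . import compare as compare_mod
from . import de as de_mod
from . import enrichment as enrich_mod
from . import io as io_mod
from . import network as net_mod
from . import overlap as overlap_mod
from . import qc as qc_mod
from . import simulate as sim_mod

log = logging.getLogger(__name__)

STAGES = ["simulate", "qc", "cluster", "de", "compare", "enrich", "network",
          "ccc", "overlap"]

DEFAULTS = {
    "seed": 0,
    "outdir": "results/pipeline",
    "inputs": {"study_A": None, "study_B": None},  # optional MTX triplet dirs
    "simulate": {
        "n_genes": 2000, "n_neurons": 300, "n_astrocytes": 200, "n_other": 100,
        "baseline_mean": 1.0, "dispersion": 2.0,
        "n_shared": 40, "n_contrasting": 40, "n_specific_A": 20, "n_specific_B": 20,
        "planted_lfc": 1.0, "mito_expr_mean_frac": 0.03, "libsize_cv": 0.3,
    },
    "qc": {"min_genes": 200, "max_genes": 8000, "max_mito_pct": 5.0,
           "target_sum": 10000},
    "cluster": {"n_pcs": 20, "k_candidates": [2, 3, 4]},
    "de": {"alpha": 0.05, "lfc_min": 0.1, "adjust": "bonferroni", "min_pct": 0.1},
    "compare": {"ns_threshold": 0.5},
    "enrich": {"min_mapped": 3, "alpha": 0.05, "top_n": 100},
    "network": {"n_nodes": 30, "edge_density": 0.12, "n_true_regulators": 1,
                "hub_quantile": 0.9},
    "ccc": {"min_fraction": 0.10, "top_n_ligands": 20, "alpha": 0.05,
            "top_n": 5, "mode": "strict"},
    "overlap": {"overlap_fraction": 0.5, "sign_agreement": 1.0},
}

_PROBABILITIES = {("de", "alpha"), ("enrich", "alpha"), ("ccc", "alpha")}
_PROPORTIONS = {("simulate", "mito_expr_mean_frac"), ("simulate", "libsize_cv"),
                ("network", "edge_density"), ("network", "hub_quantile"),
                ("ccc", "min_fraction"), ("compare", "ns_threshold"),
                ("overlap", "overlap_fraction"), ("overlap", "sign_agreement")}


def validate_config(config: dict | None) -> tuple[dict, list]:
    """Merge with defaults and collect every validation error.

    Unknown keys are rejected; probabilities must lie in (0, 1), proportions
    in [0, 1]; referenced input paths must exist.  Returns (merged, errors).
    """
    errors: list[str] = []
    merged = copy.deepcopy(DEFAULTS)
    config = config or {}
    if not isinstance(config, dict):
        return merged, ["config must be a mapping"]
    for key, val in config.items():
        if key not in DEFAULTS:
            errors.append(f"unknown config key: {key!r}")
            continue
        if isinstance(DEFAULTS[key], dict):
            if not isinstance(val, dict):
                errors.append(f"{key}: expected a mapping of parameters")
                continue
            for sub, subval in val.items():
                if sub not in DEFAULTS[key]:
                    errors.append(f"unknown config key: {key}.{sub}")
                else:
                    merged[key][sub] = subval
        else:
            merged[key] = val

    for block, field in _PROBABILITIES:
        v = merged[block][field]
        if not (isinstance(v, (int, float)) and 0.0 < v < 1.0):
            errors.append(f"{block}.{field} = {v!r}: must be in (0, 1)")
    for block, field in _PROPORTIONS:
        v = merged[block][field]
        if not (isinstance(v, (int, float)) and 0.0 <= v <= 1.0):
            errors.append(f"{block}.{field} = {v!r}: must be in [0, 1]")
    if not isinstance(merged["seed"], int):
        errors.append("seed must be an integer")
    if not merged["qc"]["min_genes"] < merged["qc"]["max_genes"]:
        errors.append("qc.min_genes must be < qc.max_genes")
    if merged["de"]["adjust"] not in ("bonferroni", "bh"):
        errors.append("de.adjust must be 'bonferroni' or 'bh'")
    if merged["ccc"]["mode"] not in ("strict", "augmented"):
        errors.append("ccc.mode must be 'strict' or 'augmented'")
    for arm in ("study_A", "study_B"):
        p = merged["inputs"][arm]
        if p is not None and not Path(p).exists():
            errors.append(f"inputs.{arm}: path does not exist: {p}")
    return merged, errors


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh) or {}


class Pipeline:
    """Stateful runner holding the artifacts of completed stages."""

    def __init__(self, config: dict | None = None, outdir=None):
        self.config, errors = validate_config(config)
        if errors:
            raise ValueError("invalid config:\n  " + "\n  ".join(errors))
        if outdir is not None:
            self.config["outdir"] = str(outdir)
        self.outdir = Path(self.config["outdir"])
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.artifacts: dict = {}
        self.report: dict = {"stages": []}

    # -- provenance -------------------------------------------------------
    def _provenance(self, stage: str, params: dict, inputs: list) -> None:
        rec = {"stage": stage, "seed": self.config["seed"], "params": params,
               "input_hashes": {str(p): io_mod.file_sha256(p) for p in inputs}}
        path = self.outdir / f"provenance_{stage}.json"
        with open(path, "w") as fh:
            json.dump(rec, fh, indent=1, sort_keys=True)
        self.report["stages"].append(stage)

    def _sim_config(self) -> sim_mod.SimConfig:
        s = self.config["simulate"]
        return sim_mod.SimConfig(
            n_genes=s["n_genes"],
            cell_types=(("Neurons", s["n_neurons"]), ("Astrocytes", s["n_astrocytes"]),
                        ("Other", s["n_other"])),
            baseline_mean=s["baseline_mean"], dispersion=s["dispersion"],
            n_shared=s["n_shared"], n_contrasting=s["n_contrasting"],
            n_specific_A=s["n_specific_A"], n_specific_B=s["n_specific_B"],
            planted_lfc=s["planted_lfc"],
            mito_expr_mean_frac=s["mito_expr_mean_frac"],
            libsize_cv=s["libsize_cv"], seed=self.config["seed"],
        )

    # -- stages -----------------------------------------------------------
    def stage_simulate(self):
        cfg = self._sim_config()
        if self.config["inputs"]["study_A"]:
            studies = {arm: io_mod.read_study(self.config["inputs"][f"study_{arm}"])
                       for arm in sim_mod.ARMS}
            truth = None
        else:
            studies = {}
            for arm in sim_mod.ARMS:
                studies[arm], truth = sim_mod.generate_study(cfg, arm)
                io_mod.write_study(studies[arm], self.outdir / f"study_{arm}")
        self.artifacts["studies"] = studies
        self.artifacts["truth"] = truth
        self._provenance("simulate", self.config["simulate"], [])
        return studies

    def stage_qc(self):
        q = self.config["qc"]
        thresholds = qc_mod.QCThresholds(q["min_genes"], q["max_genes"], q["max_mito_pct"])
        out = {}
        summary = []
        for arm, data in self.artifacts["studies"].items():
            filtered = qc_mod.filter_cells(data, thresholds)
            out[arm] = qc_mod.normalize(filtered, q["target_sum"])
            summary.append((arm, data.n_obs, filtered.n_obs))
        self.artifacts["qc"] = out
        io_mod.write_table(pd.DataFrame(summary, columns=["study", "cells_in",
                                                          "cells_kept"]),
                           self.outdir / "qc_summary.tsv", index=False)
        self._provenance("qc", q, [])
        return out

    def stage_cluster(self):
        c = self.config["cluster"]
        truth = self.artifacts["truth"]
        results, compositions = {}, {}
        for arm, data in self.artifacts["qc"].items():
            res = cluster_mod.reduce_and_cluster(
                data, n_pcs=c["n_pcs"], k_candidates=c["k_candidates"],
                seed=self.config["seed"])
            markers = cluster_mod.MarkerSet(positive=truth.markers)
            mapping = cluster_mod.annotate_clusters(data, res.labels, markers)
            data.obs["cluster"] = res.labels
            fine = res.labels.map(mapping)
            data.obs["annotated_type"] = cluster_mod.merge_celltypes(
                fine, {v: v for v in mapping.values()})
            comp = qc_mod.composition_test(data, "condition", "annotated_type")
            results[arm] = res
            compositions[arm] = comp
            io_mod.write_table(comp.table, self.outdir / f"composition_{arm}.tsv")
        self.artifacts["cluster"] = results
        self.artifacts["composition"] = compositions
        self.report["composition"] = {
            arm: {"chi2": comp.chi2, "df": comp.df, "p": comp.p}
            for arm, comp in compositions.items()}
        self._provenance("cluster", c, [])
        return results

    def stage_de(self):
        d = self.config["de"]
        tables: dict = {}
        for arm, data in self.artifacts["qc"].items():
            for ct in ("Neurons", "Astrocytes"):
                if (data.obs["annotated_type"] == ct).sum() < 4:
                    log.warning("stage_de: too few %s cells in study %s", ct, arm)
                    continue
                tab = de_mod.poisson_de(data, cell_type=ct,
                                        cell_type_field="annotated_type",
                                        min_pct=d["min_pct"])
                tab = de_mod.adjust_and_flag(tab, alpha=d["alpha"],
                                             lfc_min=d["lfc_min"], method=d["adjust"])
                tables[(arm, ct)] = tab
                io_mod.write_table(tab, self.outdir / f"de_{arm}_{ct}.tsv")
        self.artifacts["de"] = tables
        self._provenance("de", d, [])
        return tables

    def stage_compare(self):
        d, c = self.config["de"], self.config["compare"]
        truth = self.artifacts["truth"]
        cats = {}
        counts = {}
        for ct in ("Neurons", "Astrocytes"):
            if ("A", ct) not in self.artifacts["de"] or ("B", ct) not in self.artifacts["de"]:
                continue
            table = compare_mod.categorize_degs(
                self.artifacts["de"][("A", ct)], self.artifacts["de"][("B", ct)],
                alpha=d["alpha"], lfc_min=d["lfc_min"],
                ns_threshold=c["ns_threshold"])
            if truth is not None and truth.developmental:
                table = compare_mod.flag_developmental(table, truth.developmental)
            cats[ct] = table
            counts[ct] = table["category"].value_counts().to_dict()
            io_mod.write_table(compare_mod.render_with_asterisks(table),
                               self.outdir / f"categories_{ct}.tsv")
        self.artifacts["categories"] = cats
        self.report["category_counts"] = counts
        self._provenance("compare", {**d, **c}, [])
        return cats

    def stage_enrich(self):
        e = self.config["enrich"]
        o = self.config["overlap"]
        truth = self.artifacts["truth"]
        refs = sim_mod.generate_reference_lists(
            truth, overlap_fraction=o["overlap_fraction"],
            seed=self.config["seed"], sign_agreement=o["sign_agreement"])
        self.artifacts["references"] = refs
        enrich_mod.write_gmt(refs.gene_sets, self.outdir / "gene_sets.gmt")
        tables = {}
        for ct, cat_table in self.artifacts["categories"].items():
            de_A = self.artifacts["de"][("A", ct)]
            universe = set(de_A.index) & set(self.artifacts["de"][("B", ct)].index)
            query = set(cat_table.index[cat_table["category"].isin(
                ["shared", "contrasting"])]) & universe
            if not query:
                log.warning("stage_enrich: empty shared+contrasting query for %s", ct)
                continue
            tab = enrich_mod.ora(query, universe, refs.gene_sets,
                                 min_mapped=e["min_mapped"], alpha=e["alpha"],
                                 log2fc=de_A["log2FC"])
            tables[ct] = enrich_mod.top_pathways(tab, e["top_n"])
            io_mod.write_table(tables[ct].drop(columns="genes"),
                               self.outdir / f"enrichment_{ct}.tsv")
        self.artifacts["enrichment"] = tables
        self.report["top_pathways"] = {
            ct: tab.index[:5].tolist() for ct, tab in tables.items()}
        self._provenance("enrich", e, [])
        return tables

    def stage_network(self):
        n = self.config["network"]
        graph, net_truth = sim_mod.generate_signed_network(
            n_nodes=n["n_nodes"], edge_density=n["edge_density"],
            n_true_regulators=n["n_true_regulators"], seed=self.config["seed"])
        observed = {node: s for node, s in
                    graph.nodes(data="observed_sign") if s in (-1, 1)}
        ranking = net_mod.perturbagen_score(graph, observed)
        roles = net_mod.topology_roles(graph, hub_quantile=n["hub_quantile"])
        net_mod.write_edge_list(graph, self.outdir / "network_edges.tsv")
        io_mod.write_table(pd.DataFrame(
            [(r.node, r.direction, r.score, ",".join(r.reverted)) for r in ranking],
            columns=["node", "direction", "score", "reverted"]),
            self.outdir / "perturbagens.tsv", index=False)
        io_mod.write_table(roles, self.outdir / "network_roles.tsv")
        self.artifacts["network"] = (graph, ranking, roles, net_truth)
        self.report["top_perturbagens"] = [
            {"node": r.node, "direction": r.direction, "score": r.score}
            for r in ranking[:3]]
        self._provenance("network", n, [])
        return ranking

    def stage_ccc(self):
        cc = self.config["ccc"]
        refs = self.artifacts["references"]
        expressed = {arm: ccc_mod.expression_filter(self.artifacts["qc"][arm],
                                                    cc["min_fraction"])
                     for arm in sim_mod.ARMS}
        both = expressed["A"] & expressed["B"]
        planted = sorted(set(refs.gene_sets.sets.get("PLANTED_DEG_SET", [])) & both)
        if len(planted) < 5:
            planted = sorted(both)[:20]
        enrich_tabs = {}
        for i, arm in enumerate(sim_mod.ARMS):
            lig, pairs = sim_mod.generate_ccc_tables(
                sorted(both), planted, seed=self.config["seed"] + i)
            io_mod.write_table(lig, self.outdir / f"ccc_ligands_{arm}.tsv", index=False)
            io_mod.write_table(pairs, self.outdir / f"ccc_pairs_{arm}.tsv", index=False)
            query = ccc_mod.intersect_targets(lig, pairs, cc["top_n_ligands"],
                                              mode=cc["mode"]) & both
            if not query:
                log.warning("stage_ccc: empty intersection for study %s", arm)
                continue
            enrich_tabs[arm] = enrich_mod.ora(
                query, both, refs.gene_sets,
                min_mapped=self.config["enrich"]["min_mapped"], alpha=cc["alpha"])
        shared = (ccc_mod.shared_significant_pathways(
            enrich_tabs["A"], enrich_tabs["B"], alpha=cc["alpha"], top_n=cc["top_n"])
            if len(enrich_tabs) == 2 else pd.DataFrame())
        io_mod.write_table(shared, self.outdir / "ccc_shared_pathways.tsv")
        self.artifacts["ccc"] = shared
        self.report["ccc_shared_pathways"] = shared.index.tolist()
        self._provenance("ccc", cc, [])
        return shared

    def stage_overlap(self):
        refs = self.artifacts["references"]
        out = {}
        for (arm, ct), de_table in self.artifacts["de"].items():
            if arm != "A":
                continue
            sig = set(de_table.index[de_table["significant"]])
            if not sig:
                continue
            rep = overlap_mod.coverage(sig, set(refs.post_mortem.index))
            conc = overlap_mod.directional_concordance(
                de_table[de_table["significant"]], refs.post_mortem)
            rep.concordant, rep.discordant = conc.concordant, conc.discordant
            universe = set(de_table.index) | set(refs.post_mortem.index)
            rep.fisher_p = overlap_mod.overlap_fisher(
                sig, set(refs.post_mortem.index) & universe, universe)
            rep.universe_size = len(universe)
            out[f"post_mortem_{ct}"] = rep
            gwas_universe = set(de_table.index)
            out[f"gwas_{ct}"] = overlap_mod.gwas_overlap(
                de_table, refs.gwas_genes, gwas_universe)
        rows = [{"comparison": k, **r.as_dict()} for k, r in out.items()]
        io_mod.write_table(pd.DataFrame(rows), self.outdir / "overlap_reports.tsv",
                           index=False)
        self.artifacts["overlap"] = out
        self.report["overlap"] = {k: r.as_dict() for k, r in out.items()}
        self._provenance("overlap", self.config["overlap"], [])
        return out

    # -- driver -----------------------------------------------------------
    def run_all(self) -> dict:
        for stage in STAGES:
            try:
                getattr(self, f"stage_{stage}")()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        self.report["n_stages"] = len(self.report["stages"])
        with open(self.outdir / "report.json", "w") as fh:
            json.dump(_jsonable(self.report), fh, indent=1, sort_keys=True)
        return self.report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def run_pipeline(config: dict | None = None, outdir=None) -> dict:
    """Validate the config, run every stage in order, and return the report."""
    return Pipeline(config, outdir=outdir).run_all()
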