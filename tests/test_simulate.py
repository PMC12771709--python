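"""Generator contracts: config echo, determinism, planted effects, ground truth."""

import json

import numpy as np
import pandas as pd
import pytest

from crossorg import (SimConfig, generate_ccc_tables, generate_reference_lists,
                      generate_signed_network, generate_study, perturbagen_score)
from crossorg.simulate import CATEGORIES


class TestSimConfig:
    @pytest.mark.parametrize("kwargs,msg", [
        (dict(n_shared=500, n_contrasting=200), "planted DEG"),
        (dict(mito_expr_mean_frac=1.5), "mito_expr_mean_frac"),
        (dict(libsize_cv=-0.1), "libsize_cv"),
        (dict(dispersion=0.0), "dispersion"),
        (dict(cell_types=(("Neurons", 0),)), "Neurons"),
    ])
    def test_invalid_config_names_offending_field(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            SimConfig(n_genes=600, **kwargs)


class TestGenerateStudy:
    def test_ground_truth_echoes_planted_counts(self, study_pair, small_config):
        _, _, truth = study_pair
        counts = truth.categories["category"].value_counts()
        assert counts["shared"] == small_config.n_shared
        assert counts["contrasting"] == small_config.n_contrasting
        assert counts["specific_A"] == small_config.n_specific_A
        assert counts["specific_B"] == small_config.n_specific_B

    def test_category_partition(self, study_pair):
        _, _, truth = study_pair
        assert not truth.categories.index.duplicated().any()
        assert set(truth.categories["category"]) <= set(CATEGORIES)

    def test_fixed_seed_is_byte_identical(self, small_config):
        a1, t1 = generate_study(small_config, "A")
        a2, t2 = generate_study(small_config, "A")
        assert (a1.X != a2.X).nnz == 0
        assert a1.obs.equals(a2.obs) and a1.var.equals(a2.var)
        assert t1.categories.equals(t2.categories)

    def test_counts_nonnegative_integer_and_labels_populated(self, study_pair):
        A, _, _ = study_pair
        assert A.X.min() >= 0
        assert np.allclose(A.X.data, np.round(A.X.data))
        assert set(A.obs["condition"]) == {"control", "disease"}
        assert A.obs["sample"].nunique() == 4
        assert A.obs["cell_type"].notna().all()

    def test_mito_genes_prefixed_and_fraction_matches(self, study_pair, small_config):
        A, _, _ = study_pair
        mito = A.var["mito"]
        assert all(g.startswith("MT-") for g in A.var_names[mito])
        totals = np.asarray(A.X.sum(axis=1)).ravel()
        mt = np.asarray(A.X[:, mito.to_numpy()].sum(axis=1)).ravel()
        assert A.n_obs >= 500
        frac = (mt / totals).mean()
        assert frac == pytest.approx(small_config.mito_expr_mean_frac, rel=0.25)

    def test_paired_arms_share_and_oppose_planted_signs(self, study_pair):
        _, _, truth = study_pair
        cats = truth.categories
        shared = cats[cats["category"] == "shared"]
        contr = cats[cats["category"] == "contrasting"]
        assert (shared["sign_A"] == shared["sign_B"]).all()
        assert (contr["sign_A"] == -contr["sign_B"]).all()
        spec_a = cats[cats["category"] == "specific_A"]
        assert (spec_a["sign_B"] == 0).all() and (spec_a["sign_A"] != 0).all()

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_planted_fold_change_recovered_empirically(self, seed):
        """A planted up-gene at lfc=1 shows a disease/control mean ratio near 2."""
        cfg = SimConfig(n_genes=400, cell_types=(("Neurons", 500),),
                        n_shared=10, n_contrasting=0, n_specific_A=0,
                        n_specific_B=0, libsize_cv=0.0, seed=seed)
        A, truth = generate_study(cfg, "A")
        up = truth.categories.index[(truth.categories["category"] == "shared")
                                    & (truth.categories["sign_A"] == 1)]
        X = A.X.toarray()
        dis = A.obs["condition"].to_numpy() == "disease"
        idx = [A.var_names.get_loc(g) for g in up]
        ratios = X[dis][:, idx].mean(axis=0) / X[~dis][:, idx].mean(axis=0)
        assert np.all((ratios > 1.7) & (ratios < 2.3))

    def test_invalid_study_label_rejected(self, small_config):
        with pytest.raises(ValueError, match="study_label"):
            generate_study(small_config, "AD-like")


class TestGenerateSignedNetwork:
    def test_zero_density_is_error(self):
        with pytest.raises(ValueError, match="zero edges"):
            generate_signed_network(2, 0.0, seed=0)

    def test_fixed_seed_gives_identical_edge_list(self):
        g1, _ = generate_signed_network(10, 0.25, seed=5)
        g2, _ = generate_signed_network(10, 0.25, seed=5)
        assert sorted(g1.edges(data="sign")) == sorted(g2.edges(data="sign"))

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_regulator_is_unique_top_scorer(self, seed):
        g, truth = generate_signed_network(6, 0.4, n_true_regulators=1, seed=seed)
        observed = {n: s for n, s in g.nodes(data="observed_sign") if s in (-1, 1)}
        ranking = perturbagen_score(g, observed)
        planted = truth.perturbagens[0]
        assert ranking[0].node == planted["node"]
        assert ranking[0].score == planted["score"]
        others = [r.score for r in ranking if r.node != planted["node"]]
        assert planted["score"] > max(others)

    def test_acyclic_and_signed(self):
        import networkx as nx
        g, _ = generate_signed_network(15, 0.2, seed=9)
        assert nx.is_directed_acyclic_graph(g)
        assert set(nx.get_edge_attributes(g, "sign").values()) <= {-1, 1}


class TestGenerateReferenceLists:
    def test_zero_overlap_fraction_gives_empty_intersection(self, study_pair):
        _, _, truth = study_pair
        refs = generate_reference_lists(truth, overlap_fraction=0.0, seed=0)
        assert set(refs.post_mortem.index) & truth.planted_genes() == set()

    def test_full_overlap_full_agreement_is_fully_concordant(self, study_pair):
        _, _, truth = study_pair
        refs = generate_reference_lists(truth, overlap_fraction=1.0,
                                        sign_agreement=1.0, seed=0)
        planted = truth.planted_genes()
        assert planted <= set(refs.post_mortem.index)
        active = truth.categories[truth.categories["sign_A"] != 0]
        signs = np.sign(refs.post_mortem.loc[active.index, "log2FC"])
        assert (signs == active["sign_A"]).all()

    def test_half_overlap_counts_exactly(self, study_pair):
        _, _, truth = study_pair
        n_planted = len(truth.planted_genes())
        refs = generate_reference_lists(truth, overlap_fraction=0.5, seed=0)
        assert len(set(refs.post_mortem.index) & truth.planted_genes()) \
            == round(0.5 * n_planted)

    def test_collection_has_enriched_and_null_sets(self, study_pair):
        _, _, truth = study_pair
        refs = generate_reference_lists(truth, seed=0)
        assert "PLANTED_DEG_SET" in refs.gene_sets.sets
        assert any(s.startswith("NULL_SET") for s in refs.gene_sets.sets)
        planted = truth.planted_genes()
        assert set(refs.gene_sets.sets["PLANTED_DEG_SET"]) <= planted

    def test_determinism(self, study_pair):
        _, _, truth = study_pair
        r1 = generate_reference_lists(truth, seed=7)
        r2 = generate_reference_lists(truth, seed=7)
        assert r1.post_mortem.equals(r2.post_mortem)
        assert r1.gwas_genes == r2.gwas_genes
        assert json.dumps(r1.gene_sets.sets) == json.dumps(r2.gene_sets.sets)


class TestGenerateCCCTables:
    def test_planted_ligand_tops_activity_and_is_significant(self):
        genes = [f"G{i:03d}" for i in range(100)]
        lig, pairs = generate_ccc_tables(genes, planted_targets=genes[:10], seed=1)
        top = lig.sort_values("activity", ascending=False).iloc[0]
        assert set(str(top.targets).split(",")) == set(genes[:10])
        sig = pairs[pairs.significant == 1]
        assert top.ligand in set(sig.ligand)
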