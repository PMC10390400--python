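"""Pseudobulk, cross-species DE, enrichment, family scores, bulk DE, LR scores."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from orthoweave.compare import (
    bulk_de,
    cross_species_de,
    enrichment_test,
    family_score,
    lr_pathway_strength,
    pseudobulk_pca,
    pseudobulk_profiles,
)
from orthoweave.expression import log_normalize

from conftest import make_counts


def annotated(norm, types, species=None):
    return pd.DataFrame(
        {
            "barcode": norm.obs["barcode"],
            "species": species if species is not None else norm.obs["species"],
            "cluster": 0,
            "cell_type": types,
        },
        index=norm.obs_names,
    )


class TestPseudobulk:
    def test_group_mean_arithmetic(self):
        m = np.array([[1.0, 5], [3, 5]])
        norm = make_counts(m)  # use values directly as "normalized"
        cells = annotated(norm, ["t"] * 2)
        prof = pseudobulk_profiles(norm, cells, min_cells=2)
        assert prof.loc[("test", "t"), "g0"] == pytest.approx(
            np.mean(np.asarray(norm.X.todense())[:, 0])
        )

    def test_row_count_equals_retained_groups(self):
        rng = np.random.default_rng(0)
        norm = make_counts(rng.poisson(2, size=(40, 5)))
        types = ["a"] * 15 + ["b"] * 20 + ["c"] * 5
        cells = annotated(norm, types)
        with pytest.warns(UserWarning, match="dropped"):
            prof = pseudobulk_profiles(norm, cells, min_cells=10)
        assert len(prof) == 2

    def test_empty_annotation_errors(self):
        norm = make_counts(np.ones((2, 2)))
        with pytest.raises(ValueError):
            pseudobulk_profiles(norm, pd.DataFrame())

    def test_same_type_profiles_closer_than_different_types(self, default_run):
        prof = pseudobulk_profiles(default_run.norm, default_run.cells)
        pcs = pseudobulk_pca(prof, n_components=2)
        # human and mouse carry identical planted programs (no immune boost),
        # so same-type profiles across those species should be nearer than
        # different types within a species
        d = lambda a, b: np.linalg.norm(pcs.loc[a] - pcs.loc[b])
        same = d(("human", "pit mucous cell"), ("mouse", "pit mucous cell"))
        diff = d(("human", "pit mucous cell"), ("human", "chief cell"))
        assert same < diff


class TestCrossSpeciesDE:
    def test_antisymmetry_of_fold_changes(self, default_run):
        r_ab = cross_species_de(
            default_run.norm, default_run.cells, "pit mucous cell", "pig", "human"
        )
        r_ba = cross_species_de(
            default_run.norm, default_run.cells, "pit mucous cell", "human", "pig"
        )
        a = r_ab.set_index("gene")["log2fc"]
        b = r_ba.set_index("gene")["log2fc"]
        common = a.index.intersection(b.index)
        assert len(common) > 0
        assert np.allclose(a[common], -b[common], atol=1e-12)

    def test_planted_immune_program_recovered(self, default_run):
        truth = default_run.truth
        res = cross_species_de(
            default_run.norm, default_run.cells, "pit mucous cell",
            truth.immune["species"], "human",
        )
        hits = set(res.loc[(res["p_adj"] < 0.05) & (res["log2fc"] > 0), "gene"])
        planted = [g for g in truth.immune["genes"] if g in default_run.norm.var_names]
        sensitivity = len(hits & set(planted)) / len(planted)
        assert sensitivity >= 0.9

    def test_insufficient_cells_errors(self):
        norm = log_normalize(make_counts(np.ones((6, 4))))
        cells = annotated(norm, ["t"] * 6, species=["a"] * 2 + ["b"] * 4)
        with pytest.raises(ValueError, match="'a'"):
            cross_species_de(norm, cells, "t", "a", "b")

    def test_null_runs_rarely_discover(self):
        rng = np.random.default_rng(1)
        n_runs, false_runs = 40, 0
        for _ in range(n_runs):
            m = rng.poisson(3, size=(80, 150))
            norm = log_normalize(make_counts(m))
            species = np.array(["a"] * 40 + ["b"] * 40)
            cells = annotated(norm, ["t"] * 80, species=species)
            res = cross_species_de(norm, cells, "t", "a", "b")
            if (res["p_adj"] < 0.05).any():
                false_runs += 1
        assert false_runs <= 0.1 * n_runs

    def test_permuted_labels_give_uniform_pvalues(self):
        from orthoweave.cluster import rank_sum_de

        rng = np.random.default_rng(2)
        m = rng.poisson(4, size=(200, 1000)) * rng.integers(1, 4, size=(200, 1))
        norm = log_normalize(make_counts(m))
        mask = np.zeros(200, dtype=bool)
        mask[rng.permutation(200)[:100]] = True
        _, full = rank_sum_de(norm, mask, ~mask, min_pct=0, min_log2fc=0)
        p = full["p"].dropna().to_numpy()
        assert len(p) >= 1000
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.01


class TestEnrichment:
    def test_worked_hypergeometric_value(self):
        universe = [f"g{i}" for i in range(10)]
        sets = {"s": universe[:5]}
        res = enrichment_test(universe[:3], sets, universe)
        # all 3 hits inside the 5-gene set: C(5,3)/C(10,3) = 10/120
        assert res["p"].iloc[0] == pytest.approx(10 / 120)

    def test_empty_hit_list_all_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        res = enrichment_test([], {"s": universe[:4]}, universe)
        assert (res["p"] == 1.0).all()

    def test_hit_outside_universe_errors(self):
        with pytest.raises(ValueError):
            enrichment_test(["x"], {"s": ["a"]}, ["a", "b"])

    def test_matches_fisher_exact(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n_univ = int(rng.integers(10, 60))
            universe = [f"g{i}" for i in range(n_univ)]
            set_genes = list(rng.choice(universe, size=rng.integers(1, n_univ), replace=False))
            hits = list(rng.choice(universe, size=rng.integers(0, n_univ // 2 + 1), replace=False))
            res = enrichment_test(hits, {"s": set_genes}, universe)
            k = len(set(hits) & set(set_genes))
            table = [
                [k, len(set_genes) - k],
                [len(hits) - k, n_univ - len(set_genes) - len(hits) + k],
            ]
            _, p_fisher = stats.fisher_exact(table, alternative="greater")
            assert res["p"].iloc[0] == pytest.approx(p_fisher, rel=1e-9)

    def test_invariant_under_symbol_relabeling(self):
        universe = [f"g{i}" for i in range(30)]
        hits, set_genes = universe[:8], universe[4:16]
        p0 = enrichment_test(hits, {"s": set_genes}, universe)["p"][0]
        relabel = {g: f"x{i}" for i, g in enumerate(universe)}
        p1 = enrichment_test(
            [relabel[g] for g in hits],
            {"s": [relabel[g] for g in set_genes]},
            [relabel[g] for g in universe],
        )["p"][0]
        assert p0 == pytest.approx(p1)


class TestFamilyScore:
    def test_single_gene_family_equals_gene_value(self):
        m = np.array([[2.0, 7], [4, 1]])
        norm = make_counts(m)
        scores, _ = family_score(norm, None, ["g0"])
        assert np.allclose(scores, np.asarray(norm.X.todense())[:, 0])

    def test_two_gene_mean(self):
        norm = make_counts(np.array([[2.0, 4.0]]))
        scores, _ = family_score(norm, None, ["g0", "g1"])
        assert scores.iloc[0] == pytest.approx(3.0)

    def test_missing_all_members_errors(self):
        norm = make_counts(np.ones((2, 2)))
        with pytest.raises(ValueError):
            family_score(norm, None, ["NOPE"])

    def test_planted_boost_detected_with_power(self, default_run):
        truth = default_run.truth
        cells = default_run.cells
        boosted = truth.immune["species"]
        ga = cells.index[cells["species"] == boosted]
        gb = cells.index[cells["species"] == "human"]
        scores, contrast = family_score(
            default_run.norm, cells, truth.immune["genes"], ga, gb
        )
        assert contrast["difference"] > 0
        assert contrast["p"] < 0.05


class TestBulkDE:
    def make_fpkm(self, values):
        return pd.DataFrame(
            values, columns=["a1", "a2", "b1", "b2"],
            index=[f"g{i}" for i in range(len(values))],
        )

    def test_low_fpkm_is_unexpressed_without_p(self):
        res = bulk_de(self.make_fpkm([[0.8, 0.8, 0.8, 0.8]]), ["a1", "a2"], ["b1", "b2"])
        assert res["status"].iloc[0] == "unexpressed"
        assert np.isnan(res["p"].iloc[0])

    def test_small_fold_change_never_de(self):
        # log2FC = 0.9 with tiny p -> still ns
        a = 2 ** 0.9 * 10 - 1 + 1e-9
        res = bulk_de(self.make_fpkm([[a, a, 9.0, 9.0]]), ["a1", "a2"], ["b1", "b2"])
        assert abs(res["log2fc"].iloc[0]) <= 1.0
        assert res["status"].iloc[0] == "ns"

    def test_status_partition_exhaustive_exclusive(self):
        rng = np.random.default_rng(4)
        fpkm = self.make_fpkm(rng.lognormal(1, 2, size=(300, 4)))
        res = bulk_de(fpkm, ["a1", "a2"], ["b1", "b2"])
        assert set(res["status"]) <= {"up", "down", "ns", "unexpressed"}
        assert res["status"].notna().all()
        low = res.index[np.maximum(res["mean_a"], res["mean_b"]) < 1]
        assert (res.loc[low, "status"] == "unexpressed").all()
        small = res.index[(res["log2fc"].abs() <= 1.0)]
        assert not (res.loc[small, "status"].isin(["up", "down"])).any()

    def test_single_replicate_errors(self):
        with pytest.raises(ValueError):
            bulk_de(self.make_fpkm([[1, 1, 1, 1]]), ["a1"], ["b1", "b2"])

    def test_planted_fourfold_recovery(self):
        from orthoweave import SimulationConfig, generate_bulk

        cfg = SimulationConfig(seed=13)
        fpkm, truth = generate_bulk(cfg)
        res = bulk_de(fpkm, ["pig_tnfa_1", "pig_tnfa_2"], ["pig_control_1", "pig_control_2"])
        up = set(res.index[res["status"] == "up"])
        assert len(up & set(truth.bulk_de_genes)) >= 0.9 * len(truth.bulk_de_genes)


class TestLRStrength:
    def make_system(self):
        # two species, sender type S and receiver type R; ligand L boosted in pig
        genes = ["L1", "R1", "L2", "R2"]
        rows = []
        species, types = [], []
        vals = {
            ("human", "S"): [2.0, 0, 1.0, 0],
            ("human", "R"): [0, 3.0, 0, 1.0],
            ("pig", "S"): [8.0, 0, 1.0, 0],
            ("pig", "R"): [0, 12.0, 0, 1.0],
        }
        for (sp_id, t), v in vals.items():
            for _ in range(5):
                rows.append(v)
                species.append(sp_id)
                types.append(t)
        m = np.log1p(np.array(rows))  # "normalized" values; expm1 recovers vals
        norm = make_counts(m, genes=genes, barcodes=[f"c{i}" for i in range(len(rows))])
        norm.obs["species"] = species
        cells = pd.DataFrame(
            {"barcode": norm.obs["barcode"], "species": species,
             "cluster": 0, "cell_type": types},
            index=norm.obs_names,
        )
        pairs = pd.DataFrame(
            [("L1", "R1", "pw1"), ("L2", "R2", "pw2")],
            columns=["ligand", "receptor", "pathway"],
        )
        return norm, cells, pairs

    def test_pair_score_is_product_of_means(self):
        norm, cells, pairs = self.make_system()
        scores, _ = lr_pathway_strength(norm, cells, pairs, ["S"], ["R"])
        human_pw1 = scores.query("species=='human' and pathway=='pw1'")["score"].iloc[0]
        assert human_pw1 == pytest.approx(2.0 * 3.0)

    def test_bilinearity_doubling_ligand(self):
        norm, cells, pairs = self.make_system()
        scores, _ = lr_pathway_strength(norm, cells, pairs, ["S"], ["R"])
        s_h = scores.query("species=='human' and pathway=='pw1'")["score"].iloc[0]
        # double the ligand expression
        x = np.asarray(norm.X.todense())
        li = list(norm.var_names).index("L1")
        x[:, li] = np.log1p(2 * np.expm1(x[:, li]))
        norm2 = make_counts(x, genes=list(norm.var_names),
                            barcodes=list(norm.obs["barcode"]))
        norm2.obs["species"] = norm.obs["species"].to_numpy()
        s2, _ = lr_pathway_strength(norm2, cells, pairs, ["S"], ["R"])
        assert s2.query("species=='human' and pathway=='pw1'")["score"].iloc[0] == (
            pytest.approx(2 * s_h)
        )

    def test_relative_strengths_sum_to_one(self):
        norm, cells, pairs = self.make_system()
        _, strengths = lr_pathway_strength(norm, cells, pairs, ["S"], ["R"])
        sums = strengths.groupby("species")["relative_strength"].sum()
        assert np.allclose(sums, 1.0)

    def test_planted_pathway_stronger_in_active_species(self):
        norm, cells, pairs = self.make_system()
        _, strengths = lr_pathway_strength(norm, cells, pairs, ["S"], ["R"])
        rel = strengths.set_index(["species", "pathway"])["relative_strength"]
        assert rel[("pig", "pw1")] > rel[("human", "pw1")]

    def test_absent_ligand_scores_zero_both_absent_skipped(self):
        norm, cells, pairs = self.make_system()
        pairs2 = pd.concat(
            [pairs, pd.DataFrame([("NOPE", "R1", "pw3"), ("NO1", "NO2", "pw4")],
                                 columns=pairs.columns)],
            ignore_index=True,
        )
        with pytest.warns(UserWarning, match="absent"):
            scores, strengths = lr_pathway_strength(norm, cells, pairs2, ["S"], ["R"])
        assert (scores.query("pathway=='pw3'")["score"] == 0).all()
        assert "pw4" not in set(strengths["pathway"])

    def test_ligand_equals_receptor_rejected(self):
        norm, cells, _ = self.make_system()
        bad = pd.DataFrame([("L1", "L1", "p")], columns=["ligand", "receptor", "pathway"])
        with pytest.raises(ValueError):
            lr_pathway_strength(norm, cells, bad, ["S"], ["R"])
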