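import numpy as np
import pandas as pd
import pytest

from dermeval.crosscompare import (disease_ranking, fc_correlation_matrix,
                                   match_score, match_score_table,
                                   overlap_counts, pc_response_vectors,
                                   pc_scores, psi_concordance,
                                   psoriasis_concordance, topn_concordance)
from dermeval.dataio import ExpressionSignature, GeneSet, HomologyMap
from dermeval.diffexpr import DEResult
from dermeval.synthdata import (SynthConfig, generate_counts,
                                generate_disease_signatures)


def _hmap(n=30):
    return HomologyMap(pd.DataFrame(
        [(f"HG{i}", f"Gene{i}", f"GENE{i}") for i in range(1, n + 1)],
        columns=["homologene_id", "mouse_symbol", "human_symbol"]))


def _signature(table: pd.DataFrame, disease="psoriasis"):
    return ExpressionSignature("s1", disease, table)


def _de(fc: pd.Series) -> DEResult:
    tab = pd.DataFrame({"log2fc": fc, "lrt": 1.0, "pvalue": 0.5,
                        "fdr": 0.5, "logcpm": 5.0, "detected": True})
    tab.index.name = "gene"
    return DEResult(table=tab)


class TestPCVectors:
    def _design(self, n_groups=2):
        rows = []
        for g in range(n_groups):
            for trt in ("CTL", "IMQ"):
                for r in (1, 2):
                    rows.append({"sample_id": f"g{g}_{trt}_{r}",
                                 "strain": f"S{g}", "sex": "M",
                                 "treatment": trt, "replicate": str(r)})
        return pd.DataFrame(rows).set_index("sample_id")

    def test_identical_treatments_zero_vectors(self):
        design = self._design()
        rng = np.random.default_rng(0)
        base = rng.normal(5, 1, (50, 1))
        expr = pd.DataFrame(np.tile(base, (1, len(design))),
                            index=[f"Gene{i}" for i in range(50)],
                            columns=design.index)
        vecs = pc_response_vectors(expr, design)
        assert all(v.length < 1e-9 for v in vecs)

    def test_mirrored_responses_antiparallel(self):
        design = self._design()
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(0, 0.01, (60, len(design))),
                            index=[f"Gene{i}" for i in range(60)],
                            columns=design.index)
        effect = np.zeros(60)
        effect[:30] = 3.0
        for s in design.index:
            if design.loc[s, "treatment"] == "IMQ":
                sign = 1.0 if design.loc[s, "strain"] == "S0" else -1.0
                expr[s] += sign * effect
        vecs = pc_response_vectors(expr, design)
        d0, d1 = vecs[0].direction, vecs[1].direction
        assert float(d0 @ d1) < -0.99

    def test_scores_match_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.normal(0, 1, (80, 10)),
                            index=[f"Gene{i}" for i in range(80)],
                            columns=[f"s{j}" for j in range(10)])
        scores = pc_scores(expr, 2)
        x = expr.to_numpy() - expr.to_numpy().mean(axis=1, keepdims=True)
        evals, evecs = np.linalg.eigh(x.T @ x)
        for j in range(2):
            expected = x.T @ x @ evecs[:, -1 - j]
            got = scores.iloc[:, j].to_numpy()
            oracle = evecs[:, -1 - j] * np.sqrt(evals[-1 - j])
            align = np.sign(oracle @ got)
            assert np.allclose(got, align * oracle, atol=1e-8)

    def test_group_missing_treatment_skipped(self):
        design = self._design()
        design = design[~((design["strain"] == "S1")
                          & (design["treatment"] == "IMQ"))]
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.normal(0, 1, (20, len(design))),
                            index=[f"Gene{i}" for i in range(20)],
                            columns=design.index)
        vecs = pc_response_vectors(expr, design)
        assert [v.strain for v in vecs] == ["S0"]


class TestFcCorrelation:
    def test_self_and_negation(self):
        rng = np.random.default_rng(4)
        fc = pd.Series(rng.normal(0, 1, 100),
                       index=[f"Gene{i}" for i in range(100)])
        mat = fc_correlation_matrix({"a": fc, "b": fc, "c": -fc})
        assert mat.loc["a", "b"] == pytest.approx(1.0)
        assert mat.loc["a", "c"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(mat), 1.0)
        assert mat.equals(mat.T)

    def test_too_few_shared_genes_undefined(self):
        a = pd.Series([1.0] * 5, index=[f"G{i}" for i in range(5)])
        b = pd.Series([1.0] * 5, index=[f"H{i}" for i in range(5)])
        mat = fc_correlation_matrix({"a": a, "b": b})
        assert np.isnan(mat.loc["a", "b"])

    def test_aberrant_strain_anticorrelated(self):
        """The strain with inverted shared-module response must show a
        negative mean fold-change correlation with the other strains."""
        cfg = SynthConfig(n_genes=600, strains=("B6", "CD1", "MOLF"),
                          shared_module_size=150, strain_module_size=0,
                          interaction_module_size=0,
                          strain_response_scale=(1.0, 1.0, 1.0), seed=21)
        _, truth = generate_counts(cfg)
        tables = {f"{s}_M": truth.planted_lfc[(s, "M")]
                  for s in cfg.strains}
        mat = fc_correlation_matrix(tables)
        assert mat.loc["MOLF_M", ["B6_M", "CD1_M"]].mean() < 0


class TestPsoriasisConcordance:
    def test_identical_vectors_perfect_correlation(self):
        n = 30
        vals = np.linspace(-2, 2, n)
        mouse = pd.Series(vals, index=[f"Gene{i}" for i in range(1, n + 1)])
        tab = pd.DataFrame({"log2fc": vals, "pvalue": 0.01, "fdr": 0.01},
                           index=[f"GENE{i}" for i in range(1, n + 1)])
        out = psoriasis_concordance(_de(mouse), _signature(tab), _hmap(n))
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["spearman_r"] == pytest.approx(1.0)

    def test_permuted_fc_within_null_band(self):
        n = 500
        rng = np.random.default_rng(5)
        hmap = HomologyMap(pd.DataFrame(
            [(f"HG{i}", f"Gene{i}", f"GENE{i}") for i in range(1, n + 1)],
            columns=["homologene_id", "mouse_symbol", "human_symbol"]))
        human = rng.normal(0, 1, n)
        tab = pd.DataFrame({"log2fc": human, "pvalue": 0.5, "fdr": 0.5},
                           index=[f"GENE{i}" for i in range(1, n + 1)])
        mouse = pd.Series(rng.permutation(human),
                          index=[f"Gene{i}" for i in range(1, n + 1)])
        out = psoriasis_concordance(_de(mouse), _signature(tab), hmap)
        assert abs(out["pearson_r"]) < 3 / np.sqrt(n)

    def test_empty_join_rejected(self):
        mouse = pd.Series([1.0], index=["Xenogene1"])
        tab = pd.DataFrame({"log2fc": [1.0], "pvalue": [0.5], "fdr": [0.5]},
                           index=["GENE1"])
        with pytest.raises(ValueError, match="joined"):
            psoriasis_concordance(_de(mouse), _signature(tab), _hmap())


class TestMatchScore:
    def test_null_response_scores_exactly_one(self):
        n = 20
        mouse = pd.Series(0.0, index=[f"Gene{i}" for i in range(1, n + 1)])
        rng = np.random.default_rng(6)
        tab = pd.DataFrame({"log2fc": rng.normal(0, 2, n),
                            "pvalue": 0.01, "fdr": 0.01},
                           index=[f"GENE{i}" for i in range(1, n + 1)])
        out = match_score(mouse, _signature(tab), _hmap(n), n=5,
                          scale="ratio")
        assert out["score"] == 1.0
        out_log = match_score(mouse, _signature(tab), _hmap(n), n=5,
                              scale="log2")
        assert out_log["score"] == 0.0

    def test_toy_fixture_matches_hand_computation(self):
        # 10-gene signature, n = 3; printed values
        human_fc = [3.0, 2.5, 2.0, 1.0, 0.5, -0.5, -1.0, -2.0, -2.5, -3.0]
        mouse_fc = [1.0, 2.0, 0.5, 0.0, 0.0, 0.0, 0.0, -1.0, -0.5, -2.0]
        idx_h = [f"GENE{i}" for i in range(1, 11)]
        idx_m = [f"Gene{i}" for i in range(1, 11)]
        tab = pd.DataFrame({"log2fc": human_fc, "pvalue": 0.001,
                            "fdr": 0.001}, index=idx_h)
        mouse = pd.Series(mouse_fc, index=idx_m)
        out = match_score(mouse, _signature(tab), _hmap(10), n=3,
                          scale="ratio")
        # top 3 disease-increased: GENE1..3 -> mouse ratios 2, 4, sqrt(2)/1
        up = (2**1.0 + 2**2.0 + 2**0.5) / 3
        # top 3 disease-decreased: GENE10, 9, 8 -> reciprocal ratios
        down = (2**2.0 + 2**0.5 + 2**1.0) / 3
        assert out["up_component"] == pytest.approx(up)
        assert out["down_component"] == pytest.approx(down)
        assert out["score"] == pytest.approx((up + down) / 2)

    def test_invariant_to_genes_outside_top_sets(self):
        rng = np.random.default_rng(7)
        n = 40
        tab = pd.DataFrame({"log2fc": np.linspace(3, -3, n),
                            "pvalue": 0.001, "fdr": 0.001},
                           index=[f"GENE{i}" for i in range(1, n + 1)])
        mouse = pd.Series(rng.normal(0, 1, n),
                          index=[f"Gene{i}" for i in range(1, n + 1)])
        base = match_score(mouse, _signature(tab), _hmap(n), n=5)
        mouse_mod = mouse.copy()
        mouse_mod.iloc[15:25] += 5.0  # middle-ranked genes only
        mod = match_score(mouse_mod, _signature(tab), _hmap(n), n=5)
        assert mod["score"] == pytest.approx(base["score"])

    def test_empty_join_rejected(self):
        mouse = pd.Series([1.0], index=["Gene1"])
        tab = pd.DataFrame({"log2fc": [1.0], "pvalue": [0.5], "fdr": [0.5]},
                           index=["XENOGENE1"])  # absent from the map
        with pytest.raises(ValueError, match="joined"):
            match_score(mouse, _signature(tab), _hmap(5))


class TestDiseaseRanking:
    def _table(self):
        return pd.DataFrame([
            {"signature_id": "s1", "disease": "a", "group": "g1",
             "score": 2.0},
            {"signature_id": "s1", "disease": "a", "group": "g2",
             "score": 1.0},
            {"signature_id": "s2", "disease": "b", "group": "g1",
             "score": 0.5},
            {"signature_id": "s2", "disease": "b", "group": "g2",
             "score": 3.0},
        ])

    def test_single_disease_rank_one(self):
        tab = self._table()[lambda d: d["disease"] == "a"]
        ranking, best = disease_ranking(tab)
        assert ranking.loc["a", "rank"] == 1
        assert (best["best_disease"] == "a").all()

    def test_best_match_per_group(self):
        ranking, best = disease_ranking(self._table())
        assert best.loc["g1", "best_disease"] == "a"
        assert best.loc["g2", "best_disease"] == "b"

    def test_row_order_invariance(self):
        tab = self._table()
        shuffled = tab.sample(frac=1.0, random_state=3)
        r1, b1 = disease_ranking(tab)
        r2, b2 = disease_ranking(shuffled)
        pd.testing.assert_frame_equal(r1, r2)
        pd.testing.assert_frame_equal(b1, b2)

    def test_planted_concordance_orders_scores(self):
        cfg = SynthConfig(n_genes=800, strains=("A",),
                          shared_module_size=100, strain_module_size=0,
                          interaction_module_size=0,
                          strain_response_scale=(1.0,),
                          flip_last_strain_males=False, seed=30)
        cm, truth = generate_counts(cfg)
        sigs = generate_disease_signatures(truth, [0.0, 0.5, 1.0], seed=2)
        hmap = HomologyMap(pd.DataFrame(
            [(f"HG{i}", f"Gene{i}", f"GENE{i}")
             for i in range(1, cfg.n_genes + 1)],
            columns=["homologene_id", "mouse_symbol", "human_symbol"]))
        fc = truth.planted_lfc[("A", "F")]
        scores = [match_score(fc, s, hmap, n=50, scale="log2")["score"]
                  for s in sigs]
        assert scores[0] < scores[1] < scores[2]


class TestTopNAndOverlaps:
    def test_all_null_de_no_flags(self):
        n = 20
        mouse = pd.Series(0.0, index=[f"Gene{i}" for i in range(1, n + 1)])
        tab = pd.DataFrame({"log2fc": np.linspace(3, 1, n), "pvalue": 0.001,
                            "fdr": 0.001},
                           index=[f"GENE{i}" for i in range(1, n + 1)])
        out = topn_concordance(_signature(tab), {"g": _de(mouse)}, _hmap(n),
                               n=5)
        assert out["n_groups"].sum() == 0

    def test_universal_responder_flagged_everywhere(self):
        n = 20
        fc = pd.Series(0.0, index=[f"Gene{i}" for i in range(1, n + 1)])
        fc["Gene1"] = 3.0
        de = _de(fc)
        de.table["fdr"] = 0.01
        tab = pd.DataFrame({"log2fc": np.linspace(3, 1, n), "pvalue": 0.001,
                            "fdr": 0.001},
                           index=[f"GENE{i}" for i in range(1, n + 1)])
        out = topn_concordance(_signature(tab), {"g1": de, "g2": de},
                               _hmap(n), n=5)
        assert out.loc["GENE1", "n_groups"] == 2

    def test_overlap_counts_match_brute_force(self):
        rng = np.random.default_rng(8)
        pool = [f"G{i}" for i in range(40)]
        sets = {k: set(rng.choice(pool, 15, replace=False))
                for k in ("A", "B", "C")}
        out = overlap_counts(sets)
        for g in pool:
            inside = frozenset(k for k in sets if g in sets[k])
            if inside:
                key = "&".join(sorted(inside))
                assert g in set.intersection(*(sets[k] for k in inside))
        total = sum(out.values())
        assert total == len(set.union(*sets.values()))

    def test_disjoint_and_identical_sets(self):
        a = {"x", "y"}
        b = {"z"}
        out = overlap_counts({"A": a, "B": b})
        assert out["A&B"] == 0 and out["A"] == 2 and out["B"] == 1
        out2 = overlap_counts({"A": a, "B": set(a), "C": set(a)})
        assert out2["A&B&C"] == 2
        assert out2["A"] == out2["A&B"] == 0


class TestPsiConcordance:
    def test_empty_lists_give_zero_counts(self):
        mouse = pd.Series([1.0], index=["Gene1"])
        psi_i = GeneSet("pi", "", (), namespace="human")
        psi_d = GeneSet("pd", "", (), namespace="human")
        out = psi_concordance(psi_i, psi_d, {"g": _de(mouse)}, _hmap())
        assert out.loc["g", "same_direction_total"] == 0

    def test_planted_direction_counts(self):
        n = 10
        fc = pd.Series([2.0] * 5 + [-2.0] * 5,
                       index=[f"Gene{i}" for i in range(1, n + 1)])
        de = _de(fc)
        de.table["fdr"] = 0.01
        psi_i = GeneSet("pi", "", tuple(f"GENE{i}" for i in range(1, 6)),
                        namespace="human")
        psi_d = GeneSet("pd", "", tuple(f"GENE{i}" for i in range(6, 11)),
                        namespace="human")
        out = psi_concordance(psi_i, psi_d, {"g": de}, _hmap(n))
        assert out.loc["g", "psi_increased_same"] == 5
        assert out.loc["g", "psi_decreased_same"] == 5
        assert out.loc["g", "opposite_direction_total"] == 0
        # flip the mouse response: everything lands opposite
        out2 = psi_concordance(psi_i, psi_d, {"g": _de_flip(fc)}, _hmap(n))
        assert out2.loc["g", "opposite_direction_total"] == 10


def _de_flip(fc):
    de = _de(-fc)
    de.table["fdr"] = 0.01
    return de
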