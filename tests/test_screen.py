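"""Association screens: binarization rules, planted-signal recovery,
probe bookkeeping, fold filtering, clustering and enrichment."""

import logging

import numpy as np
import pandas as pd
import pytest

from mdm2pgx import (
    AlterationData,
    ExpressionMatrix,
    SCORE_GENES,
    SimulationSpec,
    binarize_alterations,
    cluster_panel,
    dichotomize,
    enrich,
    expression_screen,
    filter_probes,
    fold_difference_filter,
    generate_panel,
    genomic_screen,
    moderated_t,
    read_gmt,
    select_gene_probes,
    spearman,
    two_sample_t,
)


# ---------------------------------------------------------------------------
# Binarization
# ---------------------------------------------------------------------------

class TestBinarize:
    @staticmethod
    def build(mut, scna):
        cl = [f"CL{i}" for i in range(len(mut))]
        return AlterationData(
            pd.DataFrame([mut], index=pd.Index(["G"], name="gene"), columns=cl),
            pd.DataFrame([scna], index=pd.Index(["G"], name="gene"), columns=cl),
        )

    def test_alteration_rules(self, config):
        # columns: amplified, diploid, deleted, mutated, moderate gain
        alt = self.build([0, 0, 0, 1, 0], [8, 2, 0, 3, 4])
        binary = binarize_alterations(alt, config)
        assert binary.loc["G"].tolist() == [1, 0, 1, 1, 0]

    def test_idempotent_and_order_independent(self, config):
        alt = self.build([0, 1, 0, 1], [8, 2, 0, 4])
        b1 = binarize_alterations(alt, config)
        shuffled = AlterationData(
            alt.mutation_matrix[["CL2", "CL0", "CL3", "CL1"]],
            alt.scna_matrix[["CL2", "CL0", "CL3", "CL1"]],
        )
        b2 = binarize_alterations(shuffled, config)
        pd.testing.assert_frame_equal(b1, b2[b1.columns])

    def test_gene_set_union_with_zero_fill(self, config):
        cl = ["CL0", "CL1"]
        alt = AlterationData(
            pd.DataFrame([[1, 0]], index=pd.Index(["A"], name="gene"), columns=cl),
            pd.DataFrame([[9, 2]], index=pd.Index(["B"], name="gene"), columns=cl),
        )
        binary = binarize_alterations(alt, config)
        assert binary.loc["A"].tolist() == [1, 0]  # mutation only
        assert binary.loc["B"].tolist() == [1, 0]  # amplification only


# ---------------------------------------------------------------------------
# Genomic screen
# ---------------------------------------------------------------------------

class TestGenomicScreen:
    def test_tp53_is_top_hit_on_default_panel(self, default_panel, default_dichotomy, config):
        _, bundle, _ = default_panel
        _, _, ic50 = default_dichotomy
        binary = binarize_alterations(bundle.alterations, config)
        table = genomic_screen(binary, ic50, config)
        assert table.iloc[0]["feature_id"] == "TP53"
        assert table.iloc[0]["adj_p"] < 1e-6
        assert table.iloc[0]["direction"] == "resistance_associated"
        # TP53 is the only BH-significant gene; the background is null
        assert (table["adj_p"] < config.adj_p_threshold).sum() == 1

    def test_singleton_alteration_excluded(self, config):
        cl = [f"CL{i}" for i in range(12)]
        binary = pd.DataFrame(
            [[1] + [0] * 11, [1, 1] + [0] * 10],
            index=pd.Index(["ONCE", "TWICE"], name="gene"), columns=cl,
        )
        ic50 = pd.Series(np.linspace(0.5, 20, 12), index=cl)
        table = genomic_screen(binary, ic50, config)
        assert set(table["feature_id"]) == {"TWICE"}


# ---------------------------------------------------------------------------
# Probe filtering and the triple test
# ---------------------------------------------------------------------------

class TestFilterProbes:
    @staticmethod
    def matrix(rows, n=4):
        return ExpressionMatrix(
            pd.DataFrame(
                rows, index=pd.Index([f"p{i}" for i in range(len(rows))], name="probe_id"),
                columns=[f"CL{i}" for i in range(n)],
            ),
            level="probe",
        )

    def test_probe_below_floor_everywhere_removed(self, config):
        m = self.matrix([[4.9, 4.9, 4.9, 4.9], [7, 8, 9, 6]])
        kept = filter_probes(m, config)
        assert kept.feature_ids == ["p1"]

    def test_single_value_at_floor_retained(self, config):
        m = self.matrix([[5.0, 3.0, 3.0, 3.0]])
        assert filter_probes(m, config).feature_ids == ["p0"]

    def test_empty_matrix_rejected(self, config):
        with pytest.raises(ValueError):
            filter_probes(
                ExpressionMatrix(pd.DataFrame(index=pd.Index([], name="probe_id")), "probe"),
                config,
            )


class TestExpressionScreen:
    @pytest.fixture(scope="class")
    def small_screen(self, config):
        rng = np.random.default_rng(17)
        n = 30
        cl = [f"CL{i}" for i in range(n)]
        ic50 = pd.Series(10.0 ** rng.uniform(-1, 1.4, n), index=cl)
        records = pd.DataFrame(
            {
                "cl_id": cl, "drug_id": "d", "abs_ic50_uM": ic50.values,
                "rel_ic50_uM": ic50.values, "censor": "none", "response_class": None,
            }
        )
        _, labels = dichotomize(records, config)
        X = rng.normal(7, 1, size=(20, n))
        X[0] -= 1.5 * np.log10(ic50.values)  # one informative feature
        X[1] = 6.0  # one constant feature
        matrix = ExpressionMatrix(
            pd.DataFrame(X, index=pd.Index([f"g{i}" for i in range(20)], name="probe_id"), columns=cl),
            level="probe",
        )
        table = expression_screen(matrix, ic50, labels, config)
        return matrix, ic50, labels, table

    def test_matches_kernels_per_feature(self, small_screen):
        matrix, ic50, labels, table = small_screen
        sens = (labels == "sensitive").to_numpy()
        X = matrix.values.to_numpy()
        mod, _, _ = moderated_t(X, sens.astype(int))
        for i, row in table.iterrows():
            x_s, x_r = X[i][sens], X[i][~sens]
            if np.ptp(X[i]) > 0:
                t_ref = two_sample_t(x_s, x_r)
                assert row["t_stat"] == pytest.approx(t_ref.statistic, rel=1e-10)
                assert row["t_p"] == pytest.approx(t_ref.p, rel=1e-10)
                sp_ref = spearman(X[i], ic50.to_numpy())
                assert row["spearman_rho"] == pytest.approx(sp_ref.statistic, rel=1e-10)
                assert row["spearman_p"] == pytest.approx(sp_ref.p, rel=1e-8)
            assert row["moderated_p"] == pytest.approx(mod[i].p, rel=1e-12)

    def test_constant_feature_never_significant(self, small_screen):
        _, _, _, table = small_screen
        row = table.set_index("feature_id").loc["g1"]
        assert row["t_p"] == 1.0 and row["spearman_p"] == 1.0
        assert not row["significant"]
        assert row["direction"] == "unset"

    def test_intersection_subset_of_each_arm(self, small_screen, config):
        _, _, _, table = small_screen
        sig = table["significant"]
        for arm in ("t_adj_p", "moderated_adj_p", "spearman_adj_p"):
            assert (table.loc[sig, arm] < config.adj_p_threshold).all()

    def test_tightening_threshold_never_adds_features(self, small_screen, config):
        _, _, _, table = small_screen
        loose = set(table.loc[table["significant"], "feature_id"])
        tight_cfg = 0.01
        tight = set(
            table.loc[
                (table["t_adj_p"] < tight_cfg)
                & (table["moderated_adj_p"] < tight_cfg)
                & (table["spearman_adj_p"] < tight_cfg),
                "feature_id",
            ]
        )
        assert tight <= loose

    def test_tiny_group_rejected(self, small_screen, config):
        matrix, ic50, labels, _ = small_screen
        bad = labels.copy()
        bad[:] = "resistant"
        bad.iloc[0] = "sensitive"
        with pytest.raises(ValueError):
            expression_screen(matrix, ic50, bad, config)


class TestPlantedRecovery:
    def test_signature_recovered_across_seeds(self, config):
        """All 11 signature genes pass the triple intersection and fold
        filter, and no background gene does, in >= 95% of seeds."""
        clean = 0
        n_seeds = 20
        for seed in range(n_seeds):
            spec = SimulationSpec(seed=seed)
            bundle, _ = generate_panel(spec, config)
            ic50 = bundle.sensitivity.set_index("cl_id")["abs_ic50_uM"]
            _, labels = dichotomize(bundle.sensitivity, config)
            filtered = filter_probes(bundle.expression, config)
            table = expression_screen(filtered, ic50, labels, config)
            gene_table = select_gene_probes(table, bundle.probe_annotation)
            hits = fold_difference_filter(
                gene_table[gene_table["significant"]], config
            )
            found = set(hits["feature_id"])
            if set(SCORE_GENES) <= found and not (found - set(SCORE_GENES)):
                clean += 1
        assert clean >= 0.95 * n_seeds


# ---------------------------------------------------------------------------
# Probe-to-gene selection and fold filter
# ---------------------------------------------------------------------------

def probe_table(feature_ids, folds=None):
    n = len(feature_ids)
    return pd.DataFrame(
        {
            "feature_id": feature_ids,
            "t_p": 0.01, "moderated_p": 0.01, "spearman_p": 0.01,
            "log2_fold_diff": folds if folds is not None else [0.0] * n,
            "significant": True,
        }
    )


class TestSelectGeneProbes:
    def test_keeps_highest_quality_probe(self):
        ann = pd.DataFrame(
            {
                "probe_id": ["pA1", "pA2"],
                "gene_symbol": ["A", "A"],
                "quality_score": [0.4, 0.9],
            }
        )
        out = select_gene_probes(probe_table(["pA1", "pA2"]), ann)
        assert out["probe_id"].tolist() == ["pA2"]
        assert out["feature_id"].tolist() == ["A"]

    def test_tie_broken_lexicographically(self):
        ann = pd.DataFrame(
            {
                "probe_id": ["pA2", "pA1"],
                "gene_symbol": ["A", "A"],
                "quality_score": [0.5, 0.5],
            }
        )
        out = select_gene_probes(probe_table(["pA2", "pA1"]), ann)
        assert out["probe_id"].tolist() == ["pA1"]

    def test_row_count_equals_distinct_mapped_genes(self):
        rng = np.random.default_rng(4)
        genes = [f"G{i}" for i in range(316)]
        probe_ids, gene_map = [], []
        for g in genes:
            for j in range(int(rng.integers(1, 4))):
                probe_ids.append(f"{g}_p{j}")
                gene_map.append(g)
        probe_ids.append("orphan_probe")  # no gene mapping
        gene_map.append(None)
        ann = pd.DataFrame(
            {
                "probe_id": probe_ids,
                "gene_symbol": gene_map,
                "quality_score": rng.random(len(probe_ids)),
            }
        )
        out = select_gene_probes(probe_table(probe_ids), ann)
        assert len(out) == 316
        assert set(out["feature_id"]) == set(genes)

    def test_missing_quality_scores_fall_back(self, caplog):
        ann = pd.DataFrame(
            {
                "probe_id": ["p1", "p2"],
                "gene_symbol": ["A", "A"],
                "quality_score": [np.nan, np.nan],
            }
        )
        with caplog.at_level(logging.WARNING, logger="mdm2pgx"):
            out = select_gene_probes(probe_table(["p1", "p2"]), ann)
        assert len(out) == 1
        assert any("quality scores" in m for m in caplog.messages)


class TestFoldFilter:
    def test_strict_threshold(self, config):
        table = probe_table(["a", "b", "c"], folds=[0.5, -0.51, 0.0])
        out = fold_difference_filter(table, config)
        assert out["feature_id"].tolist() == ["b"]


# ---------------------------------------------------------------------------
# Clustering and enrichment
# ---------------------------------------------------------------------------

class TestClusterPanel:
    def test_recovers_three_separated_blobs(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(6)
        n_per, n_genes = 20, 30
        # correlation distance separates profile *shapes*, so each blob
        # gets its own up/down pattern over the genes
        patterns = [
            np.repeat([3.0, -3.0, 0.0], 10),
            np.repeat([0.0, 3.0, -3.0], 10),
            np.repeat([-3.0, 0.0, 3.0], 10),
        ]
        blocks = [
            p[None, :] + 0.1 * rng.standard_normal((n_per, n_genes))
            for p in patterns
        ]
        X = np.vstack(blocks).T  # genes x lines
        cl = [f"CL{i}" for i in range(3 * n_per)]
        matrix = ExpressionMatrix(
            pd.DataFrame(X, index=pd.Index([f"g{i}" for i in range(n_genes)], name="gene_symbol"), columns=cl),
            level="gene",
        )
        labels = pd.Series(["sensitive"] * 30 + ["resistant"] * 30, index=pd.Index(cl, name="cl_id"))
        assignment, rates, test = cluster_panel(matrix, labels, k=3)
        true = np.repeat([0, 1, 2], n_per)
        assert adjusted_rand_score(true, assignment.to_numpy()) == 1.0
        assert test is not None and 0 < test.p <= 1
        assert rates["n"].sum() == 60

    def test_identical_profiles_rejected(self):
        cl = [f"CL{i}" for i in range(6)]
        matrix = ExpressionMatrix(
            pd.DataFrame(np.ones((4, 6)) * [[1], [2], [3], [4]],
                         index=pd.Index(list("abcd"), name="gene_symbol"), columns=cl),
            level="gene",
        )
        labels = pd.Series(["sensitive"] * 3 + ["resistant"] * 3, index=pd.Index(cl, name="cl_id"))
        with pytest.raises(ValueError):
            cluster_panel(matrix, labels, k=2)

    def test_k_one_skips_proportion_test(self, default_panel, default_dichotomy):
        _, bundle, _ = default_panel
        _, labels, _ = default_dichotomy
        sub = ExpressionMatrix(bundle.expression.values.iloc[:20], "probe")
        assignment, rates, test = cluster_panel(sub, labels, k=1)
        assert (assignment == 1).all() and test is None


class TestEnrich:
    def test_planted_pathway_set_ranks_first(self, default_panel, default_dichotomy, config):
        _, bundle, _ = default_panel
        _, labels, ic50 = default_dichotomy
        filtered = filter_probes(bundle.expression, config)
        table = expression_screen(filtered, ic50, labels, config)
        gene_table = select_gene_probes(table, bundle.probe_annotation)
        selected = fold_difference_filter(
            gene_table[gene_table["significant"]], config
        )["feature_id"].tolist()
        universe = gene_table["feature_id"].tolist()
        rng = np.random.default_rng(13)
        collection = {"p53_signalling": list(SCORE_GENES)}
        for i in range(10):
            collection[f"random_set_{i}"] = list(
                rng.choice(universe, size=25, replace=False)
            )
        out = enrich(selected, collection, universe)
        assert out.iloc[0]["set_name"] == "p53_signalling"
        assert out.iloc[0]["adj_p"] < 0.01

    def test_disjoint_set_skipped_with_warning(self, caplog):
        uni = [f"g{i}" for i in range(10)]
        with caplog.at_level(logging.WARNING, logger="mdm2pgx"):
            out = enrich(uni[:3], {"alien": ["zz1", "zz2"]}, uni)
        assert out.empty
        assert any("disjoint" in m for m in caplog.messages)

    def test_selection_equal_universe_gives_p_one(self):
        uni = [f"g{i}" for i in range(10)]
        out = enrich(uni, {"s1": uni[:4], "s2": uni[4:7]}, uni)
        assert (out["p"] == 1.0).all()

    def test_gmt_round_trip(self, tmp_path):
        gmt = tmp_path / "sets.gmt"
        gmt.write_text("setA\tdesc\tg1\tg2\tg3\nsetB\tdesc\tg4\n")
        sets = read_gmt(gmt)
        assert sets == {"setA": ["g1", "g2", "g3"], "setB": ["g4"]}
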