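import numpy as np
import pytest

from coastcore.maxent import (
    FeatureExpander,
    ModelConfig,
    aicc,
    default_penalties,
    fit_maxent,
    partial_response,
    predict_model,
    realized_ratio,
    sample_background,
    accessible_mask,
    select_model_grid,
    spearman_prune,
    vif_prune,
)


class TestFeatureExpansion:
    def test_linear_columns_scaled(self, rng):
        X = rng.normal(0, 3, (50, 2))
        exp = FeatureExpander(X, ["a", "b"], "l")
        F = exp.transform(X)
        assert F.shape == (50, 2)
        assert F.min() >= 0 and F.max() <= 1

    def test_lq_column_count(self, rng):
        X = rng.normal(size=(30, 3))
        exp = FeatureExpander(X, list("abc"), "lq")
        assert exp.n_features == 6
        F = exp.transform(X)
        np.testing.assert_allclose(F[:, 1], F[:, 0] ** 2)

    def test_hinge_formula(self):
        X = np.linspace(0, 1, 11)[:, None]
        exp = FeatureExpander(X, ["x"], "lh", hinge_knots=3)
        F = exp.transform(np.array([[0.0], [0.3], [0.5], [0.8], [1.0]]))
        knots = exp.knots
        for k, t in enumerate(knots):
            fwd = F[:, 1 + 2 * k]
            rev = F[:, 2 + 2 * k]
            x = np.array([0.0, 0.3, 0.5, 0.8, 1.0])
            np.testing.assert_allclose(fwd, np.maximum(0, (x - t) / (1 - t)))
            np.testing.assert_allclose(rev, np.maximum(0, (t - x) / t))

    def test_zero_variance_excluded(self, rng):
        X = np.column_stack([rng.normal(size=20), np.full(20, 3.0)])
        with pytest.warns(UserWarning):
            exp = FeatureExpander(X, ["a", "const"], "l")
        assert exp.var_names == ["a"]

    def test_prediction_rows_clamped(self, rng):
        X = rng.uniform(0, 1, (30, 1))
        exp = FeatureExpander(X, ["a"], "l")
        F = exp.transform(np.array([[100.0], [-100.0]]))
        assert F.max() <= 1.1 and F.min() >= -0.1


class TestDefaultPenalties:
    def test_rm_linearity(self):
        b1 = default_penalties(["l", "q"], 20, [1.0, 2.0], rm=1.0)
        b2 = default_penalties(["l", "q"], 20, [1.0, 2.0], rm=2.0)
        np.testing.assert_allclose(b2, 2 * b1)

    def test_zero_sd_zero_penalty(self):
        b = default_penalties(["l"], 20, [0.0], rm=1.0)
        assert b[0] == 0.0

    def test_schedule_matches_published_tables(self):
        # independent interpolation of the published defaults at n = 28
        lq_expected = np.interp(28, [0, 10, 17, 30, 100], [1.3, 0.8, 0.5, 0.25, 0.05])
        b = default_penalties(["l", "q", "h"], 28, [1.0, 1.0, 1.0], rm=1.0)
        assert b[0] == pytest.approx(lq_expected / np.sqrt(28))
        assert b[1] == pytest.approx(lq_expected / np.sqrt(28))
        assert b[2] == pytest.approx(0.5 / np.sqrt(28))

    def test_linear_only_table(self):
        l_expected = np.interp(28, [0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05])
        b = default_penalties(["l"], 28, [1.0], rm=1.0)
        assert b[0] == pytest.approx(l_expected / np.sqrt(28))

    def test_too_few_presences_rejected(self):
        with pytest.raises(ValueError):
            default_penalties(["l"], 1, [1.0])


class TestFitMaxent:
    def test_full_shrinkage_uniform(self, rng):
        P = rng.normal(size=(20, 2))
        B = rng.normal(size=(150, 2))
        m = fit_maxent(P, B, ModelConfig("l", rm=5.0))
        assert m.k == 0
        raw = predict_model(m, B, type="raw")
        np.testing.assert_allclose(raw, 1 / len(B))
        assert m.entropy == pytest.approx(np.log(len(B)))
        clog = predict_model(m, rng.normal(size=(5, 2)), type="cloglog")
        np.testing.assert_allclose(clog, 1 - np.exp(-1), atol=1e-9)

    def test_moment_matching_unpenalized(self, rng):
        P = rng.normal(1.0, 1.0, size=(40, 1))
        B = rng.normal(0.0, 1.0, size=(400, 1))
        m = fit_maxent(P, B, ModelConfig("l", rm=1.0), penalties=np.zeros(1),
                       tol=1e-12, max_iter=50_000)
        F_p = m.expander.transform(P)
        F_b = m.expander.transform(B)
        raw = predict_model(m, B, type="raw")
        assert raw @ F_b[:, 0] == pytest.approx(F_p[:, 0].mean(), abs=1e-5)

    def test_raw_sums_to_one(self, design42):
        m = fit_maxent(design42.pres_rows, design42.bg_rows, ModelConfig("lq", 1.4),
                       design42.retained)
        raw = predict_model(m, design42.bg_rows, type="raw")
        assert raw.sum() == pytest.approx(1.0, abs=1e-8)

    def test_cloglog_monotone_in_link(self, design42):
        m = fit_maxent(design42.pres_rows, design42.bg_rows, ModelConfig("lq", 1.4),
                       design42.retained)
        link = predict_model(m, design42.bg_rows, type="link")
        clog = predict_model(m, design42.bg_rows, type="cloglog")
        order = np.argsort(link)
        assert np.all(np.diff(clog[order]) >= -1e-12)

    def test_prediction_invariant_to_background_order(self, design42, rng):
        perm = rng.permutation(len(design42.bg_rows))
        m1 = fit_maxent(design42.pres_rows, design42.bg_rows, ModelConfig("lq", 1.4),
                        design42.retained)
        m2 = fit_maxent(design42.pres_rows, design42.bg_rows[perm], ModelConfig("lq", 1.4),
                        design42.retained)
        p1 = predict_model(m1, design42.pres_rows, type="cloglog")
        p2 = predict_model(m2, design42.pres_rows, type="cloglog")
        np.testing.assert_allclose(p1, p2, atol=1e-6)

    def test_model_json_round_trip_fields(self, tmp_path, design42):
        m = fit_maxent(design42.pres_rows, design42.bg_rows, ModelConfig("lq", 1.4),
                       design42.retained)
        path = tmp_path / "model.json"
        m.to_json(path)
        import json

        payload = json.loads(path.read_text())
        assert payload["var_names"] == design42.retained
        assert len(payload["lambdas"]) == m.expander.n_features


class TestPruning:
    def test_monotone_pair_dropped(self, rng):
        x = rng.uniform(1, 2, 100)
        rows = np.column_stack([x, x**2, rng.normal(size=100)])
        kept = spearman_prune(rows, ["x", "x2", "noise"])
        assert len(kept) == 2 and "noise" in kept

    def test_independent_noise_retained(self, rng):
        rows = rng.normal(size=(300, 4))
        kept = spearman_prune(rows, list("abcd"))
        assert kept == list("abcd")

    def test_protected_never_dropped(self, rng):
        x = rng.uniform(size=100)
        rows = np.column_stack([x, x + rng.normal(0, 1e-3, 100)])
        kept = spearman_prune(rows, ["keepme", "other"], protected=["keepme"])
        assert kept == ["keepme"]

    def test_vif_orthogonal_retained(self):
        rows = np.eye(6)[:, :3]
        kept = vif_prune(rows, list("abc"))
        assert kept == list("abc")

    def test_vif_duplicate_dropped(self, rng):
        x = rng.normal(size=(100,))
        rows = np.column_stack([x, x, rng.normal(size=100)])
        kept = vif_prune(rows, ["a", "a_copy", "b"])
        assert len(kept) == 2 and "b" in kept

    def test_vif_sequence_on_known_structure(self, rng):
        x1 = rng.normal(size=200)
        x2 = rng.normal(size=200)
        x3 = x1 + x2 + rng.normal(0, 0.1, 200)  # nearly collinear combination
        x4 = rng.normal(size=200)
        kept = vif_prune(np.column_stack([x1, x2, x3, x4]), ["x1", "x2", "x3", "x4"])
        assert "x4" in kept and len(kept) == 3 and "x3" not in kept


class TestBackgroundDesign:
    def test_reported_realized_ratio(self):
        assert realized_ratio(744, 28) == 26.6

    def test_target_arithmetic(self, design42):
        mask = accessible_mask(design42.dist_map.data, 300.0, design42.stack.valid_mask())
        bg = sample_background(mask, design42.fit_stack, design42.retained,
                               n_presence=28, target_ratio=25.0, seed=1,
                               mask_grid=design42.dist_map)
        assert len(bg.rows) == 700
        assert bg.realized_ratio == 25.0

    def test_mask_nesting(self, design42):
        valid = design42.stack.valid_mask()
        m300 = accessible_mask(design42.dist_map.data, 300.0, valid)
        m450 = accessible_mask(design42.dist_map.data, 450.0, valid)
        m600 = accessible_mask(design42.dist_map.data, 600.0, valid)
        assert np.all(m300 <= m450) and np.all(m450 <= m600)

    def test_deterministic_under_seed(self, design42):
        mask = accessible_mask(design42.dist_map.data, 300.0, design42.stack.valid_mask())
        a = sample_background(mask, design42.fit_stack, design42.retained, 10, 25.0, 7,
                              mask_grid=design42.dist_map)
        b = sample_background(mask, design42.fit_stack, design42.retained, 10, 25.0, 7,
                              mask_grid=design42.dist_map)
        np.testing.assert_array_equal(a.cell_rows, b.cell_rows)
        np.testing.assert_array_equal(a.rows, b.rows)


class TestAicc:
    def test_matches_formula_recomputation(self, design42):
        m = fit_maxent(design42.pres_rows, design42.bg_rows, ModelConfig("lq", 1.4),
                       design42.retained)
        raw = predict_model(m, design42.pres_rows, type="raw")
        ll = np.log(raw).sum()
        n, k = len(design42.pres_rows), m.k
        expected = 2 * k - 2 * ll + 2 * k * (k + 1) / (n - k - 1)
        assert aicc(m, design42.pres_rows) == pytest.approx(expected)

    def test_undefined_when_overparameterized(self, design42):
        m = fit_maxent(design42.pres_rows, design42.bg_rows, ModelConfig("lq", 1.0),
                       design42.retained)
        few = design42.pres_rows[: m.k + 1]
        assert np.isnan(aicc(m, few))


class TestSelectionGrid:
    def test_robustness_formula_and_determinism(self, design42):
        table, chosen = select_model_grid(
            design42.pres_rows, design42.bg_rows, design42.retained,
            classes_grid=("l", "lq"), rm_grid=(1.0, 2.0), folds=4, seed=11,
        )
        np.testing.assert_allclose(
            table["robustness"], table["cv_auc_mean"] - 0.5 * table["cv_auc_sd"]
        )
        assert table["delta_aicc"].min() == pytest.approx(0.0)
        table2, chosen2 = select_model_grid(
            design42.pres_rows, design42.bg_rows, design42.retained,
            classes_grid=("l", "lq"), rm_grid=(1.0, 2.0), folds=4, seed=11,
        )
        assert chosen.feature_classes == chosen2.feature_classes
        assert chosen.rm == chosen2.rm


class TestPartialResponse:
    def test_flat_for_zeroed_model(self, design42, rng):
        P = rng.normal(size=(20, 2))
        B = rng.normal(size=(100, 2))
        m = fit_maxent(P, B, ModelConfig("l", rm=5.0), ["a", "b"])
        _, dlink = partial_response(m, B, "a")
        np.testing.assert_allclose(dlink, 0.0, atol=1e-9)

    def test_unknown_variable_rejected(self, design42, rng):
        P = rng.normal(size=(20, 2))
        B = rng.normal(size=(100, 2))
        m = fit_maxent(P, B, ModelConfig("l", rm=1.0), ["a", "b"])
        with pytest.raises(KeyError):
            partial_response(m, B, "nope")
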