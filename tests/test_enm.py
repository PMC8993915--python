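"""Niche-model evaluation metrics, ensembling, projection and areas."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crypsis import enm
from crypsis import synthetic as syn
from crypsis.enm import (
    EnmError,
    EnvGrid,
    ProjectionResult,
    RidgeLogisticLearner,
    cell_areas_km2,
    ensemble_predict,
    estimate_area,
    evaluate,
    extract_covariates,
    fit_ensemble,
    fit_reference_learner,
    project,
    read_asc,
    variable_importance,
    write_asc,
)


def simple_grid(values=None, shape=(4, 5), name="env_00", **kw):
    if values is None:
        values = np.arange(np.prod(shape), dtype=float).reshape(shape)
    return EnvGrid({name: values}, kw.get("xll", 0.0), kw.get("yll", 40.0),
                   kw.get(" cellsize", kw.get("cellsize", 1.0)))


class TestAsciiGrid:
    def test_round_trip_with_nodata(self, tmp_path):
        arr = np.array([[1.0, np.nan], [3.5, -2.0]])
        p = tmp_path / "layer.asc"
        write_asc(arr, p, xllcorner=-5.0, yllcorner=42.0, cellsize=0.25)
        back, header = read_asc(p)
        assert header["cellsize"] == 0.25
        assert np.isnan(back[0, 1])
        assert back[1, 0] == 3.5


class TestExtraction:
    def test_cell_center_hits_cell(self):
        g = simple_grid()
        pts = pd.DataFrame({"lon": [2.5], "lat": [43.5], "label": ["presence"]})
        occ = extract_covariates(g, pts)
        # row 0 is the northern edge (lat in [43, 44))
        assert occ.covariates.iloc[0, 0] == g.layers["env_00"][0, 2]

    def test_west_north_edges_inclusive(self):
        g = simple_grid()
        assert g.cell_index(0.0, 44.0) == (0, 0)
        assert g.cell_index(1.0, 43.0) == (1, 1)

    def test_nodata_point_flagged(self):
        vals = np.arange(20, dtype=float).reshape(4, 5)
        vals[0, 2] = np.nan
        g = simple_grid(vals)
        pts = pd.DataFrame({"lon": [2.5, 0.5], "lat": [43.5, 43.5],
                            "label": ["presence", "absence"]})
        with pytest.warns(UserWarning, match="excluded"):
            occ = extract_covariates(g, pts)
        assert occ.flagged_nodata.tolist() == [True, False]

    def test_all_points_outside_rejected(self):
        g = simple_grid()
        pts = pd.DataFrame({"lon": [99.0], "lat": [99.0], "label": ["presence"]})
        with pytest.raises(EnmError):
            extract_covariates(g, pts)


class TestEvaluate:
    def test_auc_matches_pair_counting_example(self):
        m = evaluate(np.array([0.9, 0.6, 0.7, 0.4]), np.array([1, 1, 0, 0]))
        assert m.auc == pytest.approx(0.75)

    def test_tss_formula(self):
        # TP=9 FN=1 TN=8 FP=2 at the optimal threshold
        scores = np.array([0.9] * 9 + [0.1] + [0.2] * 8 + [0.9] * 2)
        labels = np.array([1] * 10 + [0] * 10)
        m = evaluate(scores, labels)
        assert m.tss == pytest.approx(0.9 + 0.8 - 1.0)

    def test_kappa_formula(self):
        # TP=40 TN=40 FP=10 FN=10 -> kappa = 0.6
        scores = np.array([0.8] * 40 + [0.2] * 10 + [0.8] * 10 + [0.2] * 40)
        labels = np.array([1] * 50 + [0] * 50)
        m = evaluate(scores, labels)
        assert m.kappa == pytest.approx(0.6)

    def test_perfect_separation_all_metrics_one(self):
        m = evaluate(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        assert (m.auc, m.tss, m.kappa) == (1.0, 1.0, 1.0)

    def test_single_class_rejected(self):
        with pytest.raises(EnmError):
            evaluate(np.array([0.1, 0.9]), np.array([1, 1]))

    @given(
        st.lists(st.floats(0, 1, width=16), min_size=2, max_size=12),
        st.data(),
    )
    @settings(max_examples=60, deadline=None)
    def test_auc_and_tss_match_brute_force(self, scores, data):
        n = len(scores)
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda ls: 0 < sum(ls) < n
            )
        )
        scores = np.array(scores)
        labels = np.array(labels)
        m = evaluate(scores, labels)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        pairs = [(p > q) + 0.5 * (p == q) for p, q in itertools.product(pos, neg)]
        assert m.auc == pytest.approx(np.mean(pairs), rel=1e-9)
        # brute-force TSS/kappa over every candidate threshold
        best_tss = -np.inf
        for t in np.unique(scores):
            pred = scores >= t
            tp = np.sum(pred & (labels == 1))
            fn = np.sum(~pred & (labels == 1))
            tn = np.sum(~pred & (labels == 0))
            fp = np.sum(pred & (labels == 0))
            best_tss = max(best_tss, tp / (tp + fn) + tn / (tn + fp) - 1)
        assert m.tss == pytest.approx(best_tss, rel=1e-9)

    def test_auc_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.uniform(size=60)
        labels = rng.integers(0, 2, size=60)
        labels[0], labels[1] = 0, 1
        assert evaluate(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), rel=1e-12
        )


class TestLearner:
    def test_separable_single_covariate_auc_one(self):
        X = np.linspace(-2, 2, 40)[:, None]
        y = (X[:, 0] > 0).astype(int)
        m = RidgeLogisticLearner(alpha=0.1).fit(X, y)
        assert evaluate(m.predict_proba(X), y).auc == 1.0

    def test_null_labels_cross_validated_auc_near_half(self, rng):
        X = rng.normal(size=(200, 3))
        aucs = []
        for _rep in range(5):
            y = rng.integers(0, 2, size=200)
            for fold in range(4):
                test = np.arange(200) % 4 == fold
                m = RidgeLogisticLearner().fit(X[~test], y[~test])
                aucs.append(evaluate(m.predict_proba(X[test]), y[test]).auc)
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_coefficient_sign_recovery(self, niche_world):
        grid, occ, _ = niche_world
        m = fit_reference_learner(occ)
        true_coef = syn.NicheSimSpec().coefficients
        for j, c in enumerate(true_coef):
            if c != 0:
                assert np.sign(m.coef_[j]) == np.sign(c)

    def test_single_class_rejected(self):
        with pytest.raises(EnmError):
            RidgeLogisticLearner().fit(np.zeros((5, 2)), np.ones(5))

    def test_deterministic_ensemble(self, niche_world):
        _, occ, _ = niche_world
        l1, w1 = fit_ensemble(occ, k=3, seed=42)
        l2, w2 = fit_ensemble(occ, k=3, seed=42)
        assert np.allclose(w1, w2)
        X, _ = occ.fitting_data()
        assert np.allclose(ensemble_predict(l1, X, w1), ensemble_predict(l2, X, w2))


class TestEnsemble:
    def test_single_learner_identity(self, niche_world):
        _, occ, _ = niche_world
        m = fit_reference_learner(occ)
        X, _ = occ.fitting_data()
        assert np.allclose(ensemble_predict([m], X), m.predict_proba(X))

    def test_equal_weight_mean(self):
        class Const:
            def __init__(self, p):
                self.p = p

            def predict_proba(self, X):
                return np.full(len(X), self.p)

        out = ensemble_predict([Const(0.2), Const(0.8)], np.zeros((3, 1)))
        assert np.allclose(out, 0.5)

    def test_bad_weights_rejected(self):
        with pytest.raises(EnmError):
            ensemble_predict([object()], np.zeros((2, 1)), weights=[0.0])

    def test_ensemble_tracks_known_surface(self, niche_world):
        """Ensemble MAE to the true surface is close to the best member's."""
        grid, occ, true_prob = niche_world
        learners, weights = fit_ensemble(occ, k=5, seed=1)
        proj = project(learners, grid, weights)
        valid = ~np.isnan(proj.probability)
        mae_ens = np.abs(proj.probability[valid] - true_prob[valid]).mean()
        member_maes = []
        for m in learners:
            p1 = project([m], grid)
            member_maes.append(np.abs(p1.probability[valid] - true_prob[valid]).mean())
        assert mae_ens <= min(member_maes) + 0.02


class TestProjectionAndArea:
    def test_layer_name_mismatch_names_missing(self, niche_world):
        grid, occ, _ = niche_world
        m = fit_reference_learner(occ)
        other = simple_grid(name="something_else")
        with pytest.raises(EnmError, match="env_"):
            project([m], other)

    def test_projection_transfers_to_second_region(self, niche_world):
        grid, occ, _ = niche_world
        learners, w = fit_ensemble(occ, k=3, seed=2)
        g2, _, _ = syn.gen_niche(syn.NicheSimSpec(seed=99, xllcorner=-120.0, yllcorner=30.0))
        proj = project(learners, g2, w)
        assert proj.probability.shape == g2.shape
        assert np.nanmax(proj.probability) <= 1.0

    def test_nodata_propagates(self, niche_world):
        grid, occ, _ = niche_world
        layers = {nm: a.copy() for nm, a in grid.layers.items()}
        layers["env_00"][0, 0] = np.nan
        holed = EnvGrid(layers, grid.xllcorner, grid.yllcorner, grid.cellsize)
        m = fit_reference_learner(occ)
        proj = project([m], holed)
        assert np.isnan(proj.probability[0, 0])

    def test_no_qualifying_cells_zero_area(self):
        g = simple_grid()
        proj = ProjectionResult(np.zeros(g.shape), g, {})
        assert estimate_area(proj, 0.5) == 0.0

    def test_count_times_median_cell(self):
        g = simple_grid()
        p = np.zeros(g.shape)
        p.flat[:10] = 0.9
        proj = ProjectionResult(p, g, {})
        median_cell = float(np.median(cell_areas_km2(g)))
        assert estimate_area(proj, 0.5) == pytest.approx(10 * median_cell)

    def test_spherical_cell_area_magnitude(self):
        # a 1-degree cell at ~40N is about 9500 km^2
        g = simple_grid()
        areas = cell_areas_km2(g)
        assert 9000 < areas.mean() < 10000

    def test_area_monotone_in_threshold(self, rng, niche_world):
        grid, occ, _ = niche_world
        learners, w = fit_ensemble(occ, k=3, seed=7)
        proj = project(learners, grid, w)
        a = {t: estimate_area(proj, t) for t in (0.2, 0.5, 0.8)}
        assert a[0.8] <= a[0.5] <= a[0.2]
        # and on arbitrary random surfaces
        for _ in range(5):
            p = rng.uniform(size=grid.shape)
            pr = ProjectionResult(p, grid, {})
            vals = [estimate_area(pr, t) for t in (0.2, 0.5, 0.8)]
            assert vals[2] <= vals[1] <= vals[0]

    def test_strict_inequality_convention(self):
        g = simple_grid()
        p = np.full(g.shape, 0.5)
        proj = ProjectionResult(p, g, {})
        assert estimate_area(proj, 0.5) == 0.0  # p > t, not >=


class TestVariableImportance:
    def test_zero_coefficient_near_zero_importance(self, niche_world):
        _, occ, _ = niche_world
        m = fit_reference_learner(occ)
        imp = variable_importance(m, occ, seed=0, reps=10)
        names = sorted(imp)
        true_coef = syn.NicheSimSpec().coefficients
        for nm, c in zip(names, true_coef):
            if c == 0.0:
                assert imp[nm] < 0.05

    def test_informative_covariate_ranks_first(self, niche_world):
        _, occ, _ = niche_world
        m = fit_reference_learner(occ)
        imp = variable_importance(m, occ, seed=0, reps=10)
        assert max(imp, key=imp.get) == "env_00"  # largest true coefficient

    def test_replication_stabilizes(self, niche_world):
        _, occ, _ = niche_world
        m = fit_reference_learner(occ)
        i1 = variable_importance(m, occ, seed=1, reps=1)
        i2 = variable_importance(m, occ, seed=2, reps=1)
        big1 = variable_importance(m, occ, seed=1, reps=60)
        big2 = variable_importance(m, occ, seed=2, reps=60)
        for nm in big1:
            assert abs(big1[nm] - big2[nm]) <= 0.02 + 1e-9
        assert any(abs(i1[nm] - i2[nm]) > abs(big1[nm] - big2[nm]) for nm in i1)
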