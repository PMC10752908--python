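"""Stacking layer: fold plans, out-of-fold PFs, APF assembly, meta-SVM."""

import numpy as np
import pytest

from stackqsar.base import BaseModelSpec
from stackqsar.metrics import evaluate_independent
from stackqsar.stacking import (
    FoldPlan,
    PFMatrix,
    assemble_apf,
    fit_meta,
    fit_stacker,
    make_fold_plan,
    out_of_fold_pf,
)

CART_SPEC = BaseModelSpec("CART", "X", grid={"ccp_alpha": [0.01]}, seed=0)
GLM_SPEC = BaseModelSpec("GLM", "X", grid={"l2": [0.01]}, seed=0)


class TestFoldPlan:
    def test_exact_division(self):
        y = np.array([0, 1] * 50)
        plan = make_fold_plan(y, k=10, seed=0)
        sizes = np.bincount(plan.assignment)
        assert list(sizes) == [10] * 10

    def test_remainder_distribution(self):
        y = np.array([0, 1] * 11 + [1])
        plan = make_fold_plan(y, k=10, seed=0)
        sizes = np.bincount(plan.assignment)
        assert set(sizes) <= {2, 3} and sizes.sum() == 23

    def test_stratified_within_class(self):
        y = np.array([1] * 40 + [0] * 60)
        plan = make_fold_plan(y, k=10, seed=1)
        a = np.asarray(plan.assignment)
        for fold in range(10):
            assert np.sum(y[a == fold]) == 4  # 40 actives over 10 folds

    def test_deterministic(self):
        y = np.array([0, 1] * 30)
        assert make_fold_plan(y, 10, 7) == make_fold_plan(y, 10, 7)

    def test_k_exceeding_n(self):
        with pytest.raises(ValueError):
            make_fold_plan(np.array([0, 1, 0, 1]), k=10, seed=0)


class TestOutOfFoldPF:
    def test_probability_contract_and_coverage(self, separable_block):
        X, y = separable_block
        plan = make_fold_plan(y, k=5, seed=0)
        pf = out_of_fold_pf(CART_SPEC, X, y, plan)
        assert pf.shape == (len(y),)
        assert np.all((pf >= 0) & (pf <= 1))

    def test_no_leakage_row_exclusion(self, separable_block):
        """Garbling a row's features must not change the model of its own fold
        (that model never saw the row), hence identical predictions for the
        rest of the fold and for the original feature vector."""
        X, y = separable_block
        plan = make_fold_plan(y, k=5, seed=1)
        pf, models = out_of_fold_pf(GLM_SPEC, X, y, plan, return_models=True)
        rng = np.random.default_rng(0)
        for fold, tr, est in models[:2]:
            te = plan.indices(fold)
            i = te[0]  # row in the held-out fold
            assert i not in tr
            X_garbled = X.copy()
            X_garbled[i] = rng.random(X.shape[1])
            _, models2 = out_of_fold_pf(GLM_SPEC, X_garbled, y, plan,
                                        return_models=True)
            est2 = dict((f, m) for f, _, m in models2)[fold]
            # prediction on the ORIGINAL row i agrees: training ignored row i
            p1 = est.predict_proba(X[[i]])[:, 1]
            p2 = est2.predict_proba(X[[i]])[:, 1]
            assert np.allclose(p1, p2, atol=1e-8)

    def test_average_mode_pools_fold_models(self, separable_block):
        X, y = separable_block
        plan = make_fold_plan(y, k=5, seed=0)
        pf_avg = out_of_fold_pf(CART_SPEC, X, y, plan, mode="average")
        assert np.all((pf_avg >= 0) & (pf_avg <= 1))

    def test_permutation_consistency(self, separable_block):
        X, y = separable_block
        plan = make_fold_plan(y, k=5, seed=0)
        pf = out_of_fold_pf(GLM_SPEC, X, y, plan)
        perm = np.random.default_rng(3).permutation(len(y))
        plan_p = FoldPlan(k=5, assignment=tuple(np.asarray(plan.assignment)[perm]),
                          seed=plan.seed)
        pf_p = out_of_fold_pf(GLM_SPEC, X[perm], y[perm], plan_p)
        assert np.allclose(pf_p, pf[perm], atol=1e-6)

    def test_misaligned_inputs_rejected(self, separable_block):
        X, y = separable_block
        plan = make_fold_plan(y[:-2], k=5, seed=0)
        with pytest.raises(ValueError):
            out_of_fold_pf(CART_SPEC, X, y, plan)


class TestAssembleAPF:
    def _plan(self, n):
        y = np.array([0, 1] * (n // 2))
        return make_fold_plan(y, k=5, seed=0), y

    def test_width_equals_number_of_columns(self):
        plan, y = self._plan(40)
        cols = {f"A{i}__D{j}": np.full(40, 0.5) for i in range(2) for j in range(3)}
        apf = assemble_apf(cols, plan)
        assert apf.width == 6

    def test_length_mismatch_rejected(self):
        plan, _ = self._plan(40)
        cols = {"a": np.full(40, 0.5), "b": np.full(39, 0.5)}
        with pytest.raises(ValueError):
            assemble_apf(cols, plan)

    def test_out_of_range_probabilities_rejected(self):
        plan, _ = self._plan(40)
        with pytest.raises(ValueError):
            assemble_apf({"a": np.full(40, 1.5)}, plan)


class TestFitMeta:
    def _pf(self, n=60):
        y = np.array([1] * (n // 2) + [0] * (n // 2))
        plan = make_fold_plan(y, k=5, seed=0)
        perfect = y * 0.8 + 0.1
        noise = np.random.default_rng(0).random(n)
        pf = PFMatrix(np.column_stack([perfect, noise]), ["perfect", "noise"], plan)
        return pf, y

    def test_perfect_feature_reaches_training_mcc_one(self):
        pf, y = self._pf()
        meta, params, cv_mcc = fit_meta(pf, y, ["perfect"], k=5, seed=0)
        pred = (meta.predict_proba(pf.columns(["perfect"]))[:, 1] >= 0.5).astype(int)
        assert np.array_equal(pred, y)
        assert cv_mcc == 1.0

    def test_empty_selection_rejected(self):
        pf, y = self._pf()
        with pytest.raises(ValueError):
            fit_meta(pf, y, [], k=5, seed=0)

    def test_deterministic(self):
        pf, y = self._pf()
        out = [fit_meta(pf, y, ["perfect", "noise"], k=5, seed=4)[1:] for _ in range(2)]
        assert out[0] == out[1]


TINY_GRIDS = {
    "RF": {"max_features_mult": [1.0], "n_estimators": [50]},
    "GLM": {"l2": [0.01]},
    "CART": {"ccp_alpha": [0.01]},
}


@pytest.fixture(scope="module")
def fitted(small_split, small_blocks):
    from stackqsar.selection import SelectionGrid

    train, _ = small_split
    return fit_stacker(
        train, small_blocks["train"],
        algorithms=["RF", "GLM", "CART"],
        grids=TINY_GRIDS, k=5,
        selection_grid=SelectionGrid(2, 9, 2),
        random_state=11,
    )


class TestStackedEnsemble:
    def test_base_model_count_is_product(self, fitted):
        assert len(fitted.base_models_) == 3 * 3
        assert fitted.pf_matrix_.width == 9

    def test_selected_columns_subset_of_apf(self, fitted):
        assert set(fitted.selected_columns_) <= set(fitted.pf_matrix_.column_names)
        assert 0 < len(fitted.selected_columns_) <= 9

    def test_pf_entries_out_of_fold(self, fitted):
        m = fitted.pf_matrix_.matrix
        assert np.all((m >= 0) & (m <= 1))

    def test_predict_contract_and_stability(self, fitted, small_split, small_blocks):
        _, test = small_split
        p1 = fitted.predict_proba(small_blocks["test"])[:, 1]
        p2 = fitted.predict_proba(small_blocks["test"])[:, 1]
        assert np.array_equal(p1, p2)
        assert np.all((p1 >= 0) & (p1 <= 1))

    def test_motif_carrier_scored_active(self, fitted, small_split, small_blocks):
        """Compounds carrying the planted active motif score above 0.5."""
        _, test = small_split
        proba = fitted.predict_proba(small_blocks["test"])[:, 1]
        actives = test.y == 1
        assert proba[actives].mean() > 0.5 > proba[~actives].mean()

    def test_independent_evaluation(self, fitted, small_split, small_blocks):
        _, test = small_split
        rep = evaluate_independent(fitted, test, small_blocks["test"])
        assert rep.MCC > 0.5  # strong planted signal

    def test_missing_block_rejected(self, fitted, small_blocks):
        incomplete = {k: v for k, v in small_blocks["test"].items() if k != "FP4"}
        needs_fp4 = any("FP4" in c for c in fitted.selected_columns_)
        if needs_fp4:
            with pytest.raises(KeyError):
                fitted.predict_proba(incomplete)
        else:
            fitted.predict_proba(incomplete)

    def test_empty_training_rejected(self):
        from stackqsar.stacking import StackedEnsembleClassifier

        with pytest.raises(ValueError):
            StackedEnsembleClassifier().fit({}, np.array([]))

    def test_get_set_params_round_trip(self):
        from stackqsar.stacking import StackedEnsembleClassifier

        model = StackedEnsembleClassifier(k=5, random_state=3)
        params = model.get_params()
        clone = StackedEnsembleClassifier(**params)
        assert clone.get_params() == params
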