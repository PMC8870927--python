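"""Training loop determinism, checkpointing, convergence-epoch selection,
and the cross-validated grid search."""

import numpy as np
import pytest

from enoseml import (
    GridSpec,
    RFR_GRID,
    SVR_GRID,
    TrainHyper,
    assemble_hybrid,
    build_1dcnn,
    build_sv_matrix,
    grid_search_cv,
    nearest_checkpoint,
    select_convergence_epoch,
    to_multichannel,
    train_1dcnn,
)
from enoseml.training import TrainHistory


@pytest.fixture(scope="module")
def tiny_inputs(small_dataset):
    return to_multichannel(small_dataset)


def _short_hyper(**kw):
    kw.setdefault("n_epochs", 40)
    kw.setdefault("batch_size", 7)
    kw.setdefault("checkpoint_every", 10)
    kw.setdefault("seed", 0)
    return TrainHyper(**kw)


class TestTrainLoop:
    def test_zero_learning_rate_freezes_the_loss(self, tiny_inputs):
        # full-batch so batch-norm sees the same batch statistics every
        # epoch; with lr = 0 nothing can change the loss
        n = len(tiny_inputs.labels)
        hist = train_1dcnn(build_1dcnn(seed=0), tiny_inputs,
                           _short_hyper(initial_lr=0.0, n_epochs=10,
                                        batch_size=n))
        assert np.allclose(hist.losses, hist.losses[0])

    def test_same_seed_gives_bitwise_identical_loss_curves(self, tiny_inputs):
        h1 = train_1dcnn(build_1dcnn(seed=3), tiny_inputs, _short_hyper(seed=3))
        h2 = train_1dcnn(build_1dcnn(seed=3), tiny_inputs, _short_hyper(seed=3))
        assert np.array_equal(h1.losses, h2.losses)

    def test_checkpoint_restore_reproduces_forward_outputs(self, tiny_inputs):
        model = build_1dcnn(seed=1)
        hist = train_1dcnn(model, tiny_inputs, _short_hyper(seed=1))
        at_end = model.predict(tiny_inputs)
        model.load_state_dict(hist.checkpoints[20])
        mid = model.predict(tiny_inputs)
        assert not np.array_equal(mid, at_end)
        model.load_state_dict(hist.checkpoints[40])
        assert np.array_equal(model.predict(tiny_inputs), at_end)

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_divergence_aborts_with_diagnostic(self, tiny_inputs):
        with pytest.raises(FloatingPointError, match="learning rate"):
            train_1dcnn(build_1dcnn(seed=0), tiny_inputs,
                        _short_hyper(initial_lr=50.0))

    def test_checkpoint_cadence_includes_final_epoch(self, tiny_inputs):
        hist = train_1dcnn(build_1dcnn(seed=0), tiny_inputs,
                           _short_hyper(n_epochs=25, checkpoint_every=10))
        assert hist.available_epochs() == [10, 20, 25]


class TestConvergenceSelection:
    def _hist(self, losses):
        return TrainHistory(losses=np.asarray(losses, float), checkpoints={},
                            hyper=TrainHyper())

    def test_plateau_start_is_found(self):
        losses = np.concatenate([np.linspace(1.0, 0.1, 50), np.full(150, 0.1)])
        epoch = select_convergence_epoch(self._hist(losses), window=10,
                                         rel_tol=0.02)
        # smoothing delays detection by at most one window
        assert 50 <= epoch <= 60

    def test_constant_history_returns_first_valid_epoch(self):
        epoch = select_convergence_epoch(self._hist(np.ones(100)), window=10)
        assert epoch == 10

    def test_selected_epoch_non_increasing_in_tolerance(self):
        rng = np.random.default_rng(0)
        losses = 0.1 + 1.0 / np.arange(1, 301) + rng.normal(0, 0.01, 300)
        hist = self._hist(np.abs(losses))
        picks = [select_convergence_epoch(hist, window=20, rel_tol=t)
                 for t in (0.01, 0.05, 0.1, 0.3)]
        assert all(a >= b for a, b in zip(picks, picks[1:]))

    def test_nonfinite_history_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            select_convergence_epoch(self._hist([1.0, np.nan] * 30))

    def test_nearest_checkpoint_snapping(self, tiny_inputs):
        hist = train_1dcnn(build_1dcnn(seed=0), tiny_inputs,
                           _short_hyper(n_epochs=40, checkpoint_every=20))
        assert nearest_checkpoint(hist, 23) == 20
        assert nearest_checkpoint(hist, 31) == 40
        assert nearest_checkpoint(hist, 30) == 20  # tie -> earlier


class TestGridSearch:
    def test_printed_grids_have_48_and_36_combinations(self):
        assert len(GridSpec(SVR_GRID).combinations()) == 48
        assert len(GridSpec(RFR_GRID).combinations()) == 36

    def test_single_combination_grid_returns_it(self, small_dataset):
        sv = build_sv_matrix(small_dataset)
        gs = grid_search_cv("svr", GridSpec({"C": (10,), "gamma": (0.1,)}),
                            sv.rows, sv.labels)
        assert gs.best_params == {"C": 10, "gamma": 0.1}
        assert len(gs.table) == 1

    def test_ties_break_toward_earlier_grid_entry(self, small_dataset):
        sv = build_sv_matrix(small_dataset)

        class Mean:
            def fit(self, X, y):
                self.mu = float(np.mean(y))
                return self

            def predict(self, X):
                return np.full(len(X), self.mu)

        gs = grid_search_cv(lambda p, X: Mean(),
                            GridSpec({"a": (1, 2, 3)}), sv.rows, sv.labels)
        assert gs.best_params == {"a": 1}

    def test_folds_are_stratified_by_proportion(self, dataset_a):
        from enoseml.training import _make_folds
        sv = build_sv_matrix(dataset_a.subset(range(42)))  # 2 days
        folds = _make_folds(sv.labels, 3, seed=0, groups=None)
        for train_idx, test_idx in folds:
            assert set(np.round(sv.labels[test_idx], 6)) == \
                set(np.round(sv.labels, 6))

    def test_group_folds_block_by_day(self, dataset_a):
        sub = dataset_a.subset(range(63))  # 3 days
        sv = build_sv_matrix(sub)
        days = np.repeat([s.day for s in sub], 10)
        gs = grid_search_cv("rfr",
                            GridSpec({"max_depth": (3,),
                                      "min_samples_split": (7,)}),
                            sv.rows, sv.labels, groups=days)
        assert len(gs.table) == 1  # runs without label leakage errors

    def test_planted_tree_depth_is_recovered(self):
        # labels generated by a depth-3 axis-aligned tree: the depth grid
        # should select 3 in most repetitions (all features available per
        # node, so depth is the only capacity knob)
        from enoseml.models import RFRParams, make_rfr

        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            X = rng.uniform(0, 1, (240, 3))
            y = (4 * (X[:, 0] > 0.5).astype(float)
                 + 2 * (X[:, 1] > 0.5)
                 + 1 * (X[:, 2] > 0.5)
                 + rng.normal(0, 0.35, 240))
            gs = grid_search_cv(
                lambda p, X_: make_rfr(
                    RFRParams(max_depth=p["max_depth"],
                              max_features_frac=1.0, seed=seed),
                    X_.shape[1]),
                GridSpec({"max_depth": (3, 5, 7, 9, 11, 13)}, seed=seed),
                X, y)
            hits += gs.best_params["max_depth"] == 3
        assert hits >= 16

    def test_empty_grid_rejected(self, small_dataset):
        sv = build_sv_matrix(small_dataset)
        with pytest.raises(ValueError, match="empty"):
            grid_search_cv("svr", GridSpec({}), sv.rows, sv.labels)


class TestAssembleHybrid:
    def test_missing_checkpoint_error_lists_available(self, tiny_inputs):
        hist = train_1dcnn(build_1dcnn(seed=0), tiny_inputs,
                           _short_hyper(n_epochs=20, checkpoint_every=10))
        with pytest.raises(ValueError, match=r"\[10, 20\]"):
            assemble_hybrid(hist, 15,
                            GridSpec({"max_depth": (3,),
                                      "min_samples_split": (7,)}),
                            tiny_inputs)

    def test_hybrid_forest_sees_128_features(self, tiny_inputs):
        hist = train_1dcnn(build_1dcnn(seed=0), tiny_inputs,
                           _short_hyper(n_epochs=20, checkpoint_every=10))
        hyb = assemble_hybrid(hist, 20,
                              GridSpec({"max_depth": (3,),
                                        "min_samples_split": (7,)}),
                              tiny_inputs)
        assert hyb.forest.n_features_in_ == 128
        pred = hyb.predict(tiny_inputs)
        assert pred.shape == (len(tiny_inputs.labels),)
        y = tiny_inputs.labels
        assert pred.min() >= y.min() - 1e-12
        assert pred.max() <= y.max() + 1e-12
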