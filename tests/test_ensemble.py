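"""Monte Carlo ensemble mechanics and the structural analyses."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mothprune.ensemble import (
    EnsembleConfig,
    EnsembleResult,
    NetworkResult,
    breakdown_summary,
    input_connectivity,
    layer_sparsity_table,
    optimal_sparsity,
    residual_summary,
    rollout_error,
    run_ensemble,
)
from mothprune.network import Architecture, TrainConfig, init_params
from mothprune.pruning import (
    MaskSet,
    PruneSchedule,
    masked_prune_run,
    remaining_count,
    select_mask,
)

ARCH = Architecture((10, 12, 7))
SCHED = PruneSchedule((0.4, 0.8))
CFG = TrainConfig(max_epochs=1, seed=0)


@pytest.fixture(scope="module")
def small_ensemble(scaled_small):
    cfg = EnsembleConfig(n_networks=3, base_seed=10, arch=ARCH,
                         train_config=CFG, schedule=SCHED, threshold=1e-2)
    X, Y = scaled_small["X"][:1024], scaled_small["Y"][:1024]
    return run_ensemble(cfg, X, Y), (X, Y), cfg


class TestOptimalSparsity:
    def test_direct_definition(self):
        losses = {0.85: 8e-4, 0.93: 9.5e-4, 0.94: 5e-3}
        assert optimal_sparsity(losses, 1e-3) == 0.93

    def test_none_when_never_below(self):
        assert optimal_sparsity({0.5: 2e-3, 0.9: 5e-3}, 1e-3) is None

    def test_infinite_threshold_gives_last_entry(self):
        losses = {s: 10.0 ** -i for i, s in enumerate((0.1, 0.5, 0.9))}
        assert optimal_sparsity(losses, np.inf) == 0.9

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            optimal_sparsity({}, 1e-3)

    @given(st.lists(st.floats(1e-6, 1e-1), min_size=1, max_size=10),
           st.floats(1e-5, 1e-1), st.floats(1.0, 10.0))
    @settings(max_examples=60, derandomize=True)
    def test_monotone_in_threshold(self, losses, thr, factor):
        mapping = {round(0.1 + 0.08 * i, 3): l for i, l in enumerate(losses)}
        lo = optimal_sparsity(mapping, thr)
        hi = optimal_sparsity(mapping, thr * factor)
        if lo is not None:
            assert hi is not None and hi >= lo


class TestRunEnsemble:
    def test_row_count_and_distinct_seeds(self, small_ensemble):
        result, _, cfg = small_ensemble
        assert len(result.networks) == 3
        assert sorted(nr.seed for nr in result.networks) == [10, 11, 12]

    def test_determinism(self, small_ensemble, scaled_small):
        result, (X, Y), cfg = small_ensemble
        again = run_ensemble(cfg, X, Y)
        for a, b in zip(result.networks, again.networks):
            assert a.losses == b.losses
            assert a.per_layer_remaining == b.per_layer_remaining

    def test_single_network_matches_prune_run(self, scaled_small):
        """count=1 ensembles reduce to one masked prune run with that seed."""
        X, Y = scaled_small["X"][:1024], scaled_small["Y"][:1024]
        cfg = EnsembleConfig(n_networks=1, base_seed=5, arch=ARCH,
                             train_config=CFG, schedule=SCHED, threshold=1e-2)
        result = run_ensemble(cfg, X, Y)
        nr = result.networks[0]

        from mothprune.network import train

        tc = CFG.replace(seed=5)
        p = init_params(ARCH, 5)
        p, hist = train(p, None, X, Y, None, None, tc)
        p2, masks, recs = masked_prune_run(p, X, Y, SCHED, tc)
        assert [nr.per_layer_remaining[s] for s in SCHED] == \
            [r.per_layer_remaining for r in recs]
        for s, r in zip(SCHED, recs):
            assert nr.losses[s] == pytest.approx(r.loss, rel=1e-12)

    def test_summary_renders(self, small_ensemble):
        result, _, _ = small_ensemble
        text = result.summary()
        assert "median pre-prune loss" in text
        assert "sparsity" in text


class TestStructureAnalyses:
    def test_layer_table_all_ones(self):
        p = init_params(ARCH, 0)
        tab = layer_sparsity_table(MaskSet.ones_like(p))
        assert np.all(tab["fraction_remaining"] == 1.0)

    def test_layer_table_per_layer_construction(self):
        p = init_params(Architecture((6, 10, 4)), 1)
        masks = select_mask(p, 0.55, scope="per_layer")
        tab = layer_sparsity_table(masks)
        for _, row in tab.iterrows():
            assert row["remaining"] == remaining_count(int(row["size"]), 0.55)

    def test_layer1_fraction_arithmetic(self):
        """280 remaining of the default 400x10 input layer is 7%."""
        m = np.zeros((400, 10))
        m.ravel()[:280] = 1.0
        tab = layer_sparsity_table(MaskSet([m]))
        assert tab["fraction_remaining"][0] == pytest.approx(280 / 4000)
        assert 280 / 4000 == pytest.approx(0.07)

    def test_input_connectivity_counts(self):
        m = np.ones((400, 10))
        counts = input_connectivity(m)
        assert np.all(counts == 400)
        m[:, 3] = 0.0  # input 3 fully pruned
        counts = input_connectivity(m)
        assert counts[3] == 0
        assert counts.sum() == m.sum()

    def test_breakdown_conservation(self, small_ensemble):
        result, _, cfg = small_ensemble
        summary = breakdown_summary(result)
        total = (sum(summary["histogram"].values()) + summary["never_below"]
                 + summary["failed"])
        assert total == len(result.networks)

    def test_breakdown_medians_match_sort_oracle(self, small_ensemble):
        result, _, _ = small_ensemble
        ss, arr = result.loss_matrix()
        summary = breakdown_summary(result)
        for j, stats in enumerate(summary["box_stats"]):
            col = sorted(arr[:, j])
            n = len(col)
            med = col[n // 2] if n % 2 else 0.5 * (col[n // 2 - 1] + col[n // 2])
            assert stats["median"] == pytest.approx(med)

    def test_single_network_histogram(self, scaled_small):
        X, Y = scaled_small["X"][:512], scaled_small["Y"][:512]
        cfg = EnsembleConfig(n_networks=1, base_seed=0, arch=ARCH,
                             train_config=CFG, schedule=SCHED, threshold=np.inf)
        result = run_ensemble(cfg, X, Y)
        summary = breakdown_summary(result)
        assert sum(summary["histogram"].values()) == 1
        assert summary["histogram"][max(SCHED)] == 1


class TestResiduals:
    def test_constant_zero_predictor(self):
        """An all-zero network predicts 0 for everything, so with an
        identity scaler the residual mean equals the target mean."""
        from mothprune.datagen import ScalerParams

        arch = Architecture((10, 4, 7))
        p = init_params(arch, 0)
        for w in p.weights:
            w[:] = 0.0
        identity = ScalerParams(minimum=np.full(7, -0.5),
                                maximum=np.full(7, 0.5))
        rng = np.random.default_rng(0)
        X = rng.uniform(-0.5, 0.5, size=(30, 10))
        Y = rng.uniform(-0.5, 0.5, size=(30, 7))
        tab = residual_summary(p, None, X, Y, identity)
        assert np.allclose(tab["mean"], Y.mean(axis=0))
        assert list(tab["output"]) == [
            "F_x", "F_y", "tau", "xdot_f", "ydot_f", "phidot_f", "thetadot_f"]

    def test_vectorized_matches_loop(self, scaled_small, tiny_trained):
        from mothprune.datagen import apply_scaler, invert_scaler
        from mothprune.network import forward

        ds = scaled_small["dataset"]
        model = tiny_trained.model
        X = apply_scaler(ds.inputs[:20], model.input_scaler)
        preds = forward(tiny_trained.params, X)
        loop = np.array([forward(tiny_trained.params, X[i]) for i in range(20)])
        assert np.allclose(preds, loop)
        res = residual_summary(tiny_trained.params, None, X,
                               apply_scaler(ds.targets[:20], model.target_scaler),
                               model.target_scaler)
        actual = ds.targets[:20]
        predicted = invert_scaler(preds, model.target_scaler)
        assert np.allclose(res["mean"], (actual - predicted).mean(axis=0))


class TestRollout:
    def test_oracle_controls_close_the_loop(self, scaled_small, body_params):
        """Driving the simulator with the dataset's true controls reproduces
        the requested final state to integrator tolerance."""
        ds = scaled_small["dataset"]
        cases = ds.inputs[:25]
        controls = np.column_stack([
            np.hypot(ds.targets[:25, 0], ds.targets[:25, 1]),
            np.arctan2(ds.targets[:25, 1], ds.targets[:25, 0]),
            ds.targets[:25, 2]])
        out = rollout_error(None, None, None, None, body_params, cases,
                            controls_override=controls)
        assert out["n_failed"] == 0
        assert out["max"] < 1e-6

    def test_empty_case_list(self, body_params):
        out = rollout_error(None, None, None, None, body_params,
                            np.empty((0, 10)))
        assert out["n"] == 0 and out["n_failed"] == 0

    def test_trained_beats_untrained(self, scaled_small, tiny_trained,
                                     body_params):
        ds = scaled_small["dataset"]
        cases = ds.inputs[:40]
        model = tiny_trained.model
        trained = rollout_error(tiny_trained.params, None, model.input_scaler,
                                model.target_scaler, body_params, cases)
        from mothprune.network import init_params as ip

        untrained = ip(tiny_trained.params.arch, 999)
        base = rollout_error(untrained, None, model.input_scaler,
                             model.target_scaler, body_params, cases)
        assert trained["median"] < base["median"]


def test_emergent_hidden_layer_uniformity(ranges, body_params):
    """Global magnitude pruning at high sparsity drives the wide hidden
    layers to the overall remaining fraction (within 2 percentage points),
    without any per-layer constraint.  The small input/output layers keep
    disproportionately more at this reduced training scale; their full
    uniformity requires full-scale training, so they are reported only."""
    from mothprune import datagen
    from mothprune.datagen import apply_scaler, fit_scaler
    from mothprune.network import train

    ds = datagen.generate_dataset(20_000, ranges, body_params, seed=3)
    X = apply_scaler(ds.inputs, fit_scaler(ds.inputs))
    Y = apply_scaler(ds.targets, fit_scaler(ds.targets))
    arch = Architecture()  # full 10-400-400-400-16-7
    p = init_params(arch, 0)
    cfg = TrainConfig(max_epochs=5, seed=0)
    p, _ = train(p, None, X, Y, None, None, cfg)
    retrain = cfg.replace(max_epochs=2)
    s_top = 0.93
    _, masks, _ = masked_prune_run(p, X, Y, PruneSchedule((0.5, 0.8, s_top)),
                                   retrain)
    fractions = [m.sum() / m.size for m in masks.matrices]
    overall = sum(m.sum() for m in masks.matrices) / sum(
        m.size for m in masks.matrices)
    # wide hidden layers (400x400) dominate the count and prune uniformly
    for frac in fractions[1:3]:
        assert abs(frac - overall) < 0.02
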