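"""Candidate training, acceptance gating, ensemble prediction and diagnostics."""

import numpy as np
import pandas as pd
import pytest

from sigscreen.data import DESCRIPTOR_COLUMNS, generate_synthetic_dataset
from sigscreen.ensemble import (
    Ensemble,
    EnsembleError,
    GateThresholds,
    NetworkConfig,
    accept_network,
    build_ensemble,
    convergence_trace,
    ensemble_from_json,
    ensemble_to_json,
    predict,
    sensitivity_analysis,
    train_candidate,
)


def _constant_member(value, template):
    """A copy of a trained net rigged to predict a constant log10 x."""
    import copy
    from dataclasses import replace

    net = copy.deepcopy(template)
    net.config = replace(net.config, output_activation="linear")
    net.W1 = np.zeros_like(net.W1)
    net.b1 = np.zeros_like(net.b1)
    net.w2 = np.zeros_like(net.w2)
    net.b2 = (value - net.y_min) / net.y_range
    return net


class TestTraining:
    def test_same_seed_gives_identical_weights(self, small_dataset):
        cfg = NetworkConfig(hidden_units=5, seed=17)
        a = train_candidate(small_dataset, cfg)
        b = train_candidate(small_dataset, cfg)
        assert np.array_equal(a.W1, b.W1) and np.array_equal(a.w2, b.w2)
        assert a.rmsd == b.rmsd

    def test_noiseless_target_is_learnable_to_gate_accuracy(self):
        ds = generate_synthetic_dataset(120, 0.0, seed=8, n_base_solvents=6)
        net = train_candidate(ds, NetworkConfig(hidden_units=9, seed=1))
        assert net.rmsd < 0.035

    def test_sklearn_agrees_target_is_learnable(self):
        """Cross-check with an independent trainer that the synthetic
        target is fittable to comparable accuracy."""
        from sklearn.neural_network import MLPRegressor

        ds = generate_synthetic_dataset(120, 0.0, seed=8, n_base_solvents=6)
        X = ds.X.to_numpy()
        Xs = (X - X.min(0)) / (X.max(0) - X.min(0))
        reg = MLPRegressor(
            hidden_layer_sizes=(9,), activation="tanh", solver="lbfgs",
            max_iter=5000, random_state=0,
        ).fit(Xs, ds.y)
        rmsd = float(np.sqrt(np.mean((reg.predict(Xs) - ds.y) ** 2)))
        assert rmsd < 0.05

    def test_constant_target_rejected(self, small_dataset):
        y = np.zeros(len(small_dataset)) - 3.0
        with pytest.raises(ValueError, match="zero range"):
            train_candidate((small_dataset.X, y), NetworkConfig(seed=0))

    def test_degenerate_descriptor_column_rejected(self, small_dataset):
        X = small_dataset.X.copy()
        X["spot3"] = 1.0
        with pytest.raises(ValueError, match="degenerate"):
            train_candidate((X, small_dataset.y), NetworkConfig(seed=0))

    def test_too_few_records_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 6)), columns=DESCRIPTOR_COLUMNS)
        with pytest.raises(ValueError, match="30"):
            train_candidate((X, np.arange(10.0)), NetworkConfig(seed=0))


class TestGates:
    def test_inaccurate_network_rejected_for_accuracy(self, small_dataset, synth_ensemble):
        bad = _constant_member(-3.0, synth_ensemble.networks[0])
        verdict = accept_network(bad, small_dataset)
        assert not verdict.accuracy and "accuracy" in verdict.reasons

    def test_good_network_passes_all_gates(self, synth_dataset, synth_ensemble):
        verdict = accept_network(synth_ensemble.networks[0], synth_dataset)
        assert verdict.accepted
        assert verdict.accuracy and verdict.precision and verdict.reliability

    def test_out_of_range_predictions_fail_reliability(self, synth_dataset, synth_ensemble):
        """One record pushed far outside the scaled range on a 50-record
        set is a 2 percent violation, above the 1 percent allowance."""
        import copy
        from dataclasses import replace

        # net whose output saturates above 1 for an extreme spot1 value but
        # stays inside [0, 1] over the normal training span
        net = copy.deepcopy(synth_ensemble.networks[0])
        net.config = replace(
            net.config, hidden_units=1, hidden_activation="tanh", output_activation="linear"
        )
        net.W1 = np.array([[0.01], [0.0], [0.0], [0.0], [0.0], [0.0]])
        net.b1 = np.zeros(1)
        net.w2 = np.array([10.0])
        net.b2 = 0.5
        X = synth_dataset.X.iloc[:50].copy()
        y = synth_dataset.y[:50].copy()
        X.iloc[0, 0] = X.iloc[0, 0] + 1e6  # spot1 far outside training span
        verdict = accept_network(net, (X, y), gates=GateThresholds(rmsd=1e9, max_outliers=50))
        assert verdict.inside_range_fraction <= 0.98
        assert not verdict.reliability and not verdict.accepted

    def test_gate_thresholds_validated(self):
        with pytest.raises(ValueError):
            GateThresholds(rmsd=-1.0)


class TestBuild:
    def test_noiseless_data_fills_target_size(self):
        ds = generate_synthetic_dataset(120, 0.0, seed=5, n_base_solvents=6)
        ens = build_ensemble(ds, target_size=5, max_candidates=40, seed=3)
        assert len(ens) == 5
        assert all(n.rmsd < 0.035 for n in ens.networks)

    def test_every_member_passes_all_gates(self, synth_dataset, synth_ensemble):
        for net in synth_ensemble.networks:
            assert accept_network(net, synth_dataset).accepted

    def test_members_sorted_by_rmsd(self, synth_ensemble):
        rmsds = [n.rmsd for n in synth_ensemble.networks]
        assert rmsds == sorted(rmsds)

    def test_impossible_gate_exhausts_candidates(self, small_dataset):
        with pytest.raises(EnsembleError) as err:
            build_ensemble(
                small_dataset, target_size=5, max_candidates=6, seed=1,
                gates=GateThresholds(rmsd=1e-9),
            )
        assert len(err.value.acceptance_log) == 6
        assert not any(e["accepted"] for e in err.value.acceptance_log)

    def test_same_master_seed_gives_identical_log(self, small_dataset):
        kw = dict(target_size=3, max_candidates=30, seed=9,
                  gates=GateThresholds(rmsd=0.08))
        a = build_ensemble(small_dataset, **kw)
        b = build_ensemble(small_dataset, **kw)
        assert a.acceptance_log == b.acceptance_log


class TestPredict:
    def test_single_member_mean_and_zero_sd(self, synth_dataset, synth_ensemble):
        one = Ensemble(networks=[synth_ensemble.networks[0]])
        x = synth_dataset.X.iloc[[0]]
        mean, sd = predict(one, x)
        assert mean == pytest.approx(float(synth_ensemble.networks[0].predict(x.to_numpy())[0]))
        assert sd == 0.0

    def test_member_mean_arithmetic(self, synth_ensemble, synth_dataset):
        tmpl = synth_ensemble.networks[0]
        ens = Ensemble(networks=[_constant_member(-2.0, tmpl), _constant_member(-4.0, tmpl)])
        mean, sd = predict(ens, synth_dataset.X.iloc[[0]])
        assert mean == pytest.approx(-3.0)
        assert sd == pytest.approx(1.0)

    def test_training_point_error_within_gate_bound(self):
        ds = generate_synthetic_dataset(120, 0.0, seed=5, n_base_solvents=6)
        ens = build_ensemble(ds, target_size=5, max_candidates=40, seed=3)
        mean, _ = predict(ens, ds.X.iloc[[7]])
        assert abs(mean - ds.y[7]) < 0.035

    def test_prediction_invariant_to_member_order(self, synth_dataset, synth_ensemble):
        x = synth_dataset.X.iloc[[3]]
        mean, sd = predict(synth_ensemble, x)
        shuffled = Ensemble(networks=list(reversed(synth_ensemble.networks)))
        mean2, sd2 = predict(shuffled, x)
        assert mean == pytest.approx(mean2) and sd == pytest.approx(sd2)

    def test_empty_ensemble_rejected(self, synth_dataset):
        with pytest.raises(EnsembleError):
            predict(Ensemble(networks=[]), synth_dataset.X.iloc[[0]])


class TestTrace:
    def test_trace_is_running_mean_sorted_by_rmsd(self, synth_dataset, synth_ensemble):
        x = synth_dataset.X.iloc[[5]]
        trace = convergence_trace(synth_ensemble, x)
        assert len(trace) == len(synth_ensemble)
        member_preds = [float(n.predict(x.to_numpy())[0]) for n in synth_ensemble.networks]
        expected = np.cumsum(member_preds) / np.arange(1, len(member_preds) + 1)
        assert np.allclose(trace, expected)
        mean, _ = predict(synth_ensemble, x)
        assert trace[-1] == pytest.approx(mean)

    def test_single_member_trace(self, synth_dataset, synth_ensemble):
        one = Ensemble(networks=[synth_ensemble.networks[0]])
        x = synth_dataset.X.iloc[[0]]
        trace = convergence_trace(one, x)
        assert len(trace) == 1
        assert trace[0] == pytest.approx(predict(one, x)[0])


class TestSensitivity:
    def test_planted_single_descriptor_signal_is_recovered(self):
        ds = generate_synthetic_dataset(
            80, 0.0, seed=21, active_descriptors=[4], n_base_solvents=6
        )
        ens = build_ensemble(ds, target_size=5, max_candidates=60, seed=2)
        imp = sensitivity_analysis(ens, ds, repeats=5, seed=0)
        assert imp.idxmax() == "spot5"
        assert imp["spot5"] > 2.0

    def test_uninformative_column_has_unit_importance(self):
        ds = generate_synthetic_dataset(
            80, 0.0, seed=21, active_descriptors=[4], n_base_solvents=6
        )
        ens = build_ensemble(ds, target_size=5, max_candidates=60, seed=2)
        imp = sensitivity_analysis(ens, ds, repeats=5, seed=0)
        inactive = imp.drop("spot5")
        assert np.all(inactive < imp["spot5"])

    def test_zero_repeats_rejected(self, synth_dataset, synth_ensemble):
        with pytest.raises(ValueError):
            sensitivity_analysis(synth_ensemble, synth_dataset, repeats=0)


class TestSerialization:
    def test_json_round_trip_is_lossless(self, synth_ensemble, synth_dataset):
        text = ensemble_to_json(synth_ensemble)
        back = ensemble_from_json(text)
        assert ensemble_to_json(back) == text
        x = synth_dataset.X.iloc[[2]]
        assert predict(back, x)[0] == pytest.approx(predict(synth_ensemble, x)[0])
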