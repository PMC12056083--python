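"""Condition presets, ensembles, classification and the bifurcation scan."""

import numpy as np
import pytest
import yaml

from rnmkit import (
    ClassificationRule,
    ConditionPreset,
    NetworkError,
    NoCrossingError,
    SteadyStateEnsemble,
    builtin_presets,
    classify_state,
    find_critical_clamp,
    get_preset,
    make_benchmark_network,
    predict_condition_deltas,
    run_ensemble,
)
from rnmkit.synthetic import SyntheticNetworkSpec


class TestPresets:
    def test_ten_presets(self):
        presets = builtin_presets()
        assert len(presets) == 10
        assert len({p.name for p in presets}) == 10

    @pytest.mark.parametrize(
        "name, clamps",
        [
            ("lit_day0", {"α5β1": 0.5, "αvβ3": 0.5, "TRPV4": 0.5}),
            ("lit_control_unloaded", {"α5β1": 0.5, "αvβ3": 0.5, "TRPV4": 0.5}),
            ("lit_control_dynamic", {"α5β1": 1.0, "αvβ3": 1.0, "TRPV4": 1.0}),
            ("lit_TNF_unloaded", {"α5β1": 0.5, "αvβ3": 0.5, "TRPV4": 0.5, "TNF": 1.0}),
            ("lit_TNF_dynamic", {"α5β1": 1.0, "αvβ3": 1.0, "TRPV4": 1.0, "TNF": 1.0}),
            ("exp_day0", {"α5β1": 0.5, "TRPV4": 1.0, "Actin": 0.0, "IL4": 0.2585}),
            ("exp_control_unloaded", {"α5β1": 0.5, "TRPV4": 0.5, "Actin": 0.0, "IL4": 0.2585}),
            ("exp_TNF_unloaded", {"α5β1": 0.5, "TRPV4": 0.25, "Actin": 0.0, "IL4": 0.2585, "TNF": 1.0}),
        ],
    )
    def test_clamp_values(self, name, clamps):
        assert dict(get_preset(name).clamps) == clamps

    def test_experiment_dynamic_same_as_unloaded(self):
        for treatment in ("control", "TNF"):
            dyn = get_preset(f"exp_{treatment}_dynamic")
            unl = get_preset(f"exp_{treatment}_unloaded")
            assert dict(dyn.clamps) == dict(unl.clamps)

    def test_yaml_round_trip_preserves_decimals(self):
        """Config serialization keeps 0.25, 0.2585, 0.5 and 1 exact."""
        for preset in builtin_presets():
            dumped = yaml.safe_dump({"clamps": dict(preset.clamps)}, allow_unicode=True)
            back = yaml.safe_load(dumped)["clamps"]
            assert back == dict(preset.clamps)

    def test_unknown_preset(self):
        with pytest.raises(KeyError, match="lit_day0"):
            get_preset("nope")


class TestClassification:
    @pytest.mark.parametrize(
        "value, label",
        [(0.5, "pro-anabolic"), (0.49, "pro-catabolic"), (1.0, "pro-anabolic"), (0.0, "pro-catabolic")],
    )
    def test_threshold_inclusive(self, value, label):
        assert classify_state({"ACAN": value}, ClassificationRule()) == label

    def test_missing_readout(self):
        with pytest.raises(NetworkError, match="ACAN"):
            classify_state({"IL6": 1.0}, ClassificationRule())

    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            ClassificationRule(threshold=1.0)


class TestEnsembles:
    def test_tnf_forces_catabolic(self, benchmark):
        """TNF = 1 drives IL6 high and the readout to the catabolic state
        from every initial condition."""
        net, truth = benchmark
        ens = run_ensemble(net, get_preset("lit_TNF_unloaded"), n=100, seed=2)
        assert ens.n_converged == 100
        assert ens.pct_catabolic == 100.0
        assert ens.attractor_count == 1

    def test_determinism(self, benchmark):
        net, _ = benchmark
        a = run_ensemble(net, get_preset("lit_control_dynamic"), n=100, seed=9)
        b = run_ensemble(net, get_preset("lit_control_dynamic"), n=100, seed=9)
        assert a == b

    def test_fraction_conservation(self, benchmark):
        net, _ = benchmark
        for seed in range(3):
            ens = run_ensemble(net, get_preset("exp_TNF_unloaded"), n=40, seed=seed)
            assert ens.pct_anabolic + ens.pct_catabolic == pytest.approx(100.0)

    def test_missing_clamp_node_listed(self, toggle):
        net, _ = toggle  # no Actin node
        with pytest.raises(NetworkError, match="Actin"):
            run_ensemble(net, get_preset("exp_control_unloaded"), n=5, seed=0)

    def test_toggle_basin_fraction_matches_analytic_oracle(self, toggle):
        """Basin fractions match the exact diagonal rule: an initial state
        converges anabolic iff its readout component is the larger one."""
        net, truth = toggle
        free = ConditionPreset("free", "experiment", "control", "unloaded", {})
        ens = run_ensemble(net, free, n=2000, seed=13)
        # independent oracle: uniform measure of {a0 > m0} is exactly 1/2
        assert abs(ens.pct_anabolic - 100.0 * truth["basin_fraction_anabolic"]) <= 3.0
        assert 0.0 < ens.pct_anabolic < 100.0
        # per-run check of the basin rule against the sampled initials
        rng = np.random.default_rng(13)
        draws = rng.uniform(size=(2000, 2))  # node order: ACAN, MMP13
        expect = np.where(draws[:, 0] > draws[:, 1], "pro-anabolic", "pro-catabolic")
        mismatch = np.mean(expect != np.array(ens.labels))
        assert mismatch < 0.01  # only near-diagonal draws may disagree

    def test_mean_activation_bounds(self, benchmark):
        net, _ = benchmark
        ens = run_ensemble(net, get_preset("lit_control_unloaded"), n=30, seed=1)
        assert all(0.0 <= v <= 1.0 for v in ens.mean_activation.values())


class TestConditionDeltas:
    def test_identical_ensembles_zero_delta(self, benchmark):
        net, _ = benchmark
        ens = run_ensemble(net, get_preset("lit_control_unloaded"), n=20, seed=4)
        frame = predict_condition_deltas(ens, ens)
        assert np.allclose(frame["delta"], 0.0)

    def test_tnf_signs(self, benchmark):
        """TNF stimulation lowers the readout and raises the inflammatory
        hub relative to the matched control."""
        net, truth = benchmark
        ctrl = run_ensemble(net, get_preset("lit_control_unloaded"), n=50, seed=6)
        tnf = run_ensemble(net, get_preset("lit_TNF_unloaded"), n=50, seed=6)
        frame = predict_condition_deltas(ctrl, tnf).set_index("node")
        assert frame.loc[truth["readout"], "delta"] < 0
        assert frame.loc[truth["inflammatory_node"], "delta"] > 0

    def test_zero_denominator_guard(self):
        ens = SteadyStateEnsemble(
            preset_name="p", n_runs=1, seed=0, node_names=["ACAN"],
            states=[{"ACAN": 0.0}], converged=[True], labels=["pro-catabolic"],
            iterations=[1], mean_activation={"ACAN": 0.0},
            pct_anabolic=0.0, pct_catabolic=100.0, n_converged=1, attractors=[],
        )
        ens2 = SteadyStateEnsemble(**{**ens.to_dict(), "mean_activation": {"ACAN": 0.4}})
        frame = predict_condition_deltas(ens, ens2)
        row = frame.iloc[0]
        assert row["delta"] == pytest.approx(0.4)
        assert not row["rel_defined"] and np.isnan(row["rel_change_pct"])

    def test_absent_nodes_skipped_with_warning_list(self, benchmark):
        net, _ = benchmark
        ens = run_ensemble(net, get_preset("lit_control_unloaded"), n=10, seed=0)
        frame = predict_condition_deltas(ens, ens, nodes=["ACAN", "NOT_A_NODE"])
        assert frame.attrs["skipped"] == ["NOT_A_NODE"]
        assert frame["node"].tolist() == ["ACAN"]


class TestCriticalClamp:
    def test_planted_flip_recovered(self, benchmark):
        net, truth = benchmark
        c = find_critical_clamp(
            net, truth["flip_node"], truth["flip_base_clamps"], tol=1e-3, seed=1
        )
        assert c == pytest.approx(truth["flip_value"], abs=1e-3)

    def test_monotone_network_no_crossing(self, benchmark):
        """With TNF clamped on, the readout is catabolic for every IL4 level."""
        net, truth = benchmark
        with pytest.raises(NoCrossingError):
            find_critical_clamp(
                net, "IL4", {**truth["flip_base_clamps"], "TNF": 1.0}, seed=1
            )

    def test_repeatability(self, benchmark):
        net, truth = benchmark
        kwargs = dict(tol=1e-4, seed=5)
        a = find_critical_clamp(net, "IL4", truth["flip_base_clamps"], **kwargs)
        b = find_critical_clamp(net, "IL4", truth["flip_base_clamps"], **kwargs)
        assert a == b
        assert a == pytest.approx(0.2585, abs=1e-4)


def test_monotone_clamp_response(benchmark):
    """Raising the clamp of a net-activating regulator (IL4 -> ACAN) never
    lowers the ensemble-mean readout."""
    net, truth = benchmark
    base = truth["flip_base_clamps"]
    means = []
    for v in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0):
        preset = ConditionPreset("probe", "experiment", "control", "unloaded", {**base, "IL4": v})
        ens = run_ensemble(net, preset, n=20, seed=8)
        means.append(ens.mean_activation["ACAN"])
    assert all(b >= a - 1e-9 for a, b in zip(means, means[1:]))


def test_bifurcation_recovery_multiple_planted_values():
    """find_critical_clamp recovers planted flips across the interval."""
    for c in (0.2, 0.6):
        net, truth = make_benchmark_network(SyntheticNetworkSpec(flip_value=c))
        got = find_critical_clamp(
            net, "IL4", truth["flip_base_clamps"], tol=1e-3, seed=3
        )
        assert got == pytest.approx(c, abs=1e-3)
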