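"""NARX simulation, cascades and transfer-function characteristics."""

import math

import numpy as np
import pytest

from narxid.analysis import (
    gain_phase_report,
    simulate_arx,
    simulate_cascade,
    simulate_narx,
    transfer_characteristics,
)
from narxid.hankel import ARXParams
from narxid.hill import HillParams, hill_transform
from narxid.model import IdentifiedModel


def make_model(output="y", inputs=("u",), a=(0.5,), b=(0.5,), n=2.0, K=0.3):
    arx = ARXParams(
        a=np.asarray(a, dtype=float),
        b={name: np.asarray(b, dtype=float) for name in inputs},
        m_y=len(a),
        m_u=len(b),
        inputs=list(inputs),
    )
    hill = {name: HillParams(n=n, K=K) for name in inputs}
    return IdentifiedModel(output=output, inputs=sorted(inputs), hill=hill, arx=arx)


class TestSimulateNarx:
    def test_zero_input_zero_output(self):
        model = make_model()
        y = simulate_narx(model, {"u": np.zeros(10)})
        np.testing.assert_array_equal(y, np.zeros(10))

    def test_step_input_fixed_point(self):
        """A step at u = K drives the output to 0.5 * sum(b) / (1 - sum(a))."""
        model = make_model(a=(0.6,), b=(0.3,), n=8.0, K=0.4)
        y = simulate_narx(model, {"u": np.full(400, 0.4)})
        expected = 0.5 * 0.3 / (1 - 0.6)
        assert y[-1] == pytest.approx(expected, rel=1e-6)

    def test_superposition_of_transformed_inputs(self):
        """The ARX stage is linear in the transformed inputs."""
        arx = ARXParams(
            a=np.array([0.7]), b={"u": np.array([0.4])}, m_y=1, m_u=1, inputs=["u"]
        )
        rng = np.random.default_rng(0)
        x1, x2 = rng.random(30), rng.random(30)
        y12 = simulate_arx(arx, {"u": x1 + x2})
        y1 = simulate_arx(arx, {"u": x1})
        y2 = simulate_arx(arx, {"u": x2})
        np.testing.assert_allclose(y12, y1 + y2, atol=1e-12)

    def test_output_zero_before_time_zero(self):
        model = make_model()
        y = simulate_narx(model, {"u": np.ones(5)})
        assert y[0] == 0.0

    def test_divergence_warns_but_continues(self):
        model = make_model(a=(1.6,), b=(1.0,), n=1.0, K=0.5)
        with pytest.warns(RuntimeWarning, match="unstable"):
            y = simulate_narx(model, {"u": np.ones(60)})
        assert len(y) == 60


class TestSimulateCascade:
    def test_single_model_equals_simulate_narx(self):
        model = make_model()
        u = np.linspace(0, 1, 20)
        out = simulate_cascade([model], {"u": u})
        np.testing.assert_array_equal(out["y"], simulate_narx(model, {"u": u}))

    def test_two_layer_composition_consistency(self):
        m1 = make_model(output="mid", inputs=("u",))
        m2 = make_model(output="top", inputs=("mid",), a=(0.3,), b=(0.8,), n=1.5, K=0.4)
        u = np.linspace(0, 1, 25)
        out = simulate_cascade([m2, m1], {"u": u})  # order should not matter
        mid = simulate_narx(m1, {"u": u})
        np.testing.assert_array_equal(out["mid"], mid)
        np.testing.assert_array_equal(out["top"], simulate_narx(m2, {"mid": mid}))

    def test_ablation_zeroes_reachable_descendants_only(self):
        mA = make_model(output="a1", inputs=("uA",))
        mB = make_model(output="b1", inputs=("uB",))
        mC = make_model(output="c2", inputs=("a1",))
        u = np.linspace(0, 1, 30)
        out = simulate_cascade([mA, mB, mC], {"uA": u, "uB": u}, ablate=["uA"])
        np.testing.assert_array_equal(out["a1"], np.zeros(30))
        np.testing.assert_array_equal(out["c2"], np.zeros(30))
        assert np.any(out["b1"] != 0)

    def test_override_replaces_simulated_intermediate(self):
        m1 = make_model(output="mid", inputs=("u",))
        m2 = make_model(output="top", inputs=("mid",))
        u = np.linspace(0, 1, 20)
        forced = np.full(20, 0.25)
        out = simulate_cascade([m1, m2], {"u": u}, overrides={"mid": forced})
        np.testing.assert_array_equal(out["top"], simulate_narx(m2, {"mid": forced}))
        # the cascade still reports its own simulation of the intermediate
        np.testing.assert_array_equal(out["mid"], simulate_narx(m1, {"u": u}))

    def test_cycle_detected(self):
        m1 = make_model(output="x", inputs=("y",))
        m2 = make_model(output="y", inputs=("x",))
        with pytest.raises(ValueError, match="cycle"):
            simulate_cascade([m1, m2], {})

    def test_missing_input_named(self):
        m = make_model(output="y", inputs=("ghost",))
        with pytest.raises(ValueError, match="ghost"):
            simulate_cascade([m], {})

    def test_near_linear_regime_scales_linearly(self):
        """With gentle transforms and small inputs, doubling the root input
        approximately doubles every downstream amplitude."""
        m1 = make_model(output="mid", inputs=("u",), n=1.0, K=1.0)
        m2 = make_model(output="top", inputs=("mid",), n=1.0, K=1.0)
        t = np.linspace(0, 1, 40)
        u = 0.01 * t * np.exp(1 - t)
        lo = simulate_cascade([m1, m2], {"u": u})
        hi = simulate_cascade([m1, m2], {"u": 2 * u})
        for mol in ("mid", "top"):
            ratio = hi[mol][5:] / lo[mol][5:]
            assert np.all(np.abs(ratio - 2) < 0.1)


class TestTransferCharacteristics:
    def test_steady_state_gain_formula(self):
        arx = ARXParams(
            a=np.array([0.5]), b={"u": np.array([0.5])}, m_y=1, m_u=1, inputs=["u"]
        )
        fc = transfer_characteristics(arx, "u")
        assert fc.steady_state_gain == pytest.approx(1.0)

    def test_pure_gain_channel_has_no_cutoff(self):
        """b only, no autoregression: flat response, no crossing, tau undefined."""
        arx = ARXParams(
            a=np.empty(0), b={"u": np.array([0.8])}, m_y=0, m_u=1, inputs=["u"]
        )
        fc = transfer_characteristics(arx, "u", convention="discrete")
        assert fc.tau is None
        np.testing.assert_allclose(fc.gain_curve, 0.8, rtol=1e-9)

    def test_integrator_flagged_infinite(self):
        arx = ARXParams(
            a=np.array([1.0]), b={"u": np.array([0.5])}, m_y=1, m_u=1, inputs=["u"]
        )
        fc = transfer_characteristics(arx, "u")
        assert fc.infinite_gain
        assert fc.tau is None

    def test_tau_matches_continuous_first_order_limit(self):
        """For slow poles the discrete-convention cutoff reproduces the
        continuous first-order time constant tau = -dt/ln(a) within 5%."""
        dt = 1.0
        for a1 in (0.9, 0.95):
            arx = ARXParams(
                a=np.array([a1]), b={"u": np.array([1 - a1])}, m_y=1, m_u=1,
                inputs=["u"],
            )
            fc = transfer_characteristics(
                arx, "u", cutoff_fraction=1 / math.sqrt(2), convention="discrete",
                dt=dt,
            )
            tau_cont = -dt / math.log(a1)
            assert fc.tau == pytest.approx(tau_cont, rel=0.05)

    def test_dc_limit_matches_steady_state_gain(self):
        """Gain at the lowest scanned frequency equals the z=1 gain (0.1%)."""
        arx = ARXParams(
            a=np.array([0.6, 0.1]), b={"u": np.array([0.2, 0.1])}, m_y=2, m_u=2,
            inputs=["u"],
        )
        fc = transfer_characteristics(arx, "u", convention="discrete", dt=1.0)
        assert fc.gain_curve[0] == pytest.approx(fc.steady_state_gain, rel=1e-3)

    def test_tau_fcutoff_relation_exact(self):
        arx = ARXParams(
            a=np.array([0.8]), b={"u": np.array([0.2])}, m_y=1, m_u=1, inputs=["u"]
        )
        fc = transfer_characteristics(arx, "u", convention="discrete")
        assert fc.tau == pytest.approx(1.0 / (2 * math.pi * fc.f_cutoff))

    def test_substitution_convention_differs_from_discrete(self):
        arx = ARXParams(
            a=np.array([0.8]), b={"u": np.array([0.2])}, m_y=1, m_u=1, inputs=["u"]
        )
        sub = transfer_characteristics(arx, "u", convention="substitution")
        dis = transfer_characteristics(arx, "u", convention="discrete", dt=1.0)
        assert sub.tau != pytest.approx(dis.tau, rel=1e-3)

    def test_multi_input_per_channel_gains(self):
        arx = ARXParams(
            a=np.array([0.5]),
            b={"u1": np.array([0.5]), "u2": np.array([0.1])},
            m_y=1,
            m_u=1,
            inputs=["u1", "u2"],
        )
        g1 = transfer_characteristics(arx, "u1").steady_state_gain
        g2 = transfer_characteristics(arx, "u2").steady_state_gain
        assert g1 == pytest.approx(1.0)
        assert g2 == pytest.approx(0.2)


class TestGainPhaseReport:
    def test_row_per_channel_and_values(self):
        m1 = make_model(output="y1", inputs=("u1", "u2"), a=(0.5,), b=(0.5,))
        m2 = make_model(output="y2", inputs=("u1",), a=(0.2,), b=(0.4,))
        rep = gain_phase_report([m1, m2], convention="discrete", dt=1.0)
        assert len(rep) == 3
        row = rep[(rep.input == "u1") & (rep.output == "y1")].iloc[0]
        assert row.gain == pytest.approx(1.0)
        assert row.K == pytest.approx(0.3)
        assert row.n == pytest.approx(2.0)

    def test_low_pass_gain_curves_non_increasing(self):
        """Identified-style first-order channels behave as low-pass filters."""
        for a1, b1 in ((0.9, 0.3), (0.7, 0.5), (0.5, 1.0)):
            arx = ARXParams(
                a=np.array([a1]), b={"u": np.array([b1])}, m_y=1, m_u=1, inputs=["u"]
            )
            fc = transfer_characteristics(
                arx, "u", convention="discrete", dt=1.0,
                omega_band=(1e-6, math.pi), n_omega=500,
            )
            assert np.all(np.diff(fc.gain_curve) <= 1e-12)


def test_simulated_output_matches_manual_hill_then_arx():
    """simulate_narx is exactly Hill transform followed by the ARX recursion."""
    model = make_model(a=(0.6,), b=(0.3,), n=3.0, K=0.5)
    u = np.linspace(0, 1, 15)
    manual = simulate_arx(model.arx, {"u": hill_transform(u, model.hill["u"])})
    np.testing.assert_array_equal(simulate_narx(model, {"u": u}), manual)
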