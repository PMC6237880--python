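"""Point-neuron dynamics: activation, membrane integration, kWTA inhibition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hippoctx.netcore import (
    LayerParams,
    LayerState,
    activation,
    kwta_inhibition,
    kwta_thresholds,
    net_excitation,
    settle,
    step_vm,
    vm_fixed_point,
)
from hippoctx.plasticity import Projection


def make_params(size=10, kwta_frac=0.2, **kw):
    return LayerParams(size=size, kwta_frac=kwta_frac, **kw)


class TestActivation:
    @pytest.mark.parametrize(
        "vm,expected",
        [(0.5, 0.0), (0.51, 0.5), (0.3, 0.0)],
    )
    def test_reference_points(self, vm, expected):
        # at threshold chi=0; 10 mV above threshold chi=1 forces y=1/2
        y = activation(np.array([vm]), gamma=100.0, theta=0.5)
        assert y[0] == pytest.approx(expected, abs=1e-12)

    @given(st.floats(min_value=-1.0, max_value=2.0))
    @settings(deadline=None, max_examples=50)
    def test_bounded_and_rectified(self, vm):
        y = activation(np.array([vm]), 100.0, 0.5)
        assert 0.0 <= y[0] < 1.0
        if vm <= 0.5:
            assert y[0] == 0.0

    def test_monotone_in_vm(self):
        vm = np.linspace(0.0, 1.5, 200)
        y = activation(vm, 100.0, 0.5)
        assert np.all(np.diff(y) >= 0)


class TestMembrane:
    def test_leak_only_fixed_point_is_el(self):
        p = make_params()
        vm = np.full(p.size, 0.8)
        for _ in range(1000):
            vm = step_vm(vm, np.zeros(p.size), 0.0, p)
        assert np.allclose(vm, p.El, atol=1e-9)

    def test_mixed_drive_fixed_point(self):
        # ge*ge_bar = 0.1 against the 0.1 leak: analytic equilibrium 0.65
        p = make_params()
        ge = np.full(p.size, 0.1)
        vm = np.full(p.size, p.Vrest)
        for _ in range(600):
            vm = step_vm(vm, ge, 0.0, p)
        expected = (0.1 * 0.3 + 0.1 * 1.0) / 0.2
        assert expected == pytest.approx(0.65)
        assert np.allclose(vm, expected, atol=1e-9)

    def test_tau_zero_freezes_dynamics(self):
        p = make_params(tau=0.0)
        vm = np.full(p.size, 0.42)
        out = step_vm(vm, np.full(p.size, 0.7), 2.0, p)
        assert np.array_equal(out, vm)

    def test_rejects_nonfinite_conductance(self):
        p = make_params()
        with pytest.raises(ValueError):
            step_vm(np.zeros(p.size), np.full(p.size, np.nan), 0.0, p)

    @given(
        st.floats(min_value=0.0, max_value=3.0),
        st.floats(min_value=0.0, max_value=3.0),
        st.floats(min_value=0.05, max_value=1.0),
    )
    @settings(deadline=None, max_examples=30)
    def test_converges_to_closed_form(self, ge_val, gi_val, tau):
        """Iterated integration reaches the closed-form equilibrium to 1e-6."""
        p = make_params(tau=tau)
        ge = np.full(p.size, ge_val)
        vm = np.full(p.size, p.Vrest)
        for _ in range(3000):
            vm = step_vm(vm, ge, gi_val, p)
        assert np.allclose(vm, vm_fixed_point(ge, gi_val, p), atol=1e-6)


def _proj(w, r=1.0, a=1.0, norm=1.0):
    w = np.atleast_2d(np.asarray(w, dtype=float))
    return Projection(
        name="t", src="s", dst="d", w=w, mask=(w >= 0).astype(int),
        r=r, a=a, recv_norm=norm,
    )


class TestNetExcitation:
    def test_single_projection_passthrough(self):
        ge = net_excitation([(np.array([1.0]), _proj([[0.4]]))])
        assert ge[0] == pytest.approx(0.4)

    def test_relative_weight_normalization(self):
        # r=(1,3) at equal raw drives: 0.25*1 + 0.75*1 = 1
        p1 = _proj([[1.0]], r=1.0)
        p2 = _proj([[1.0]], r=3.0)
        ge = net_excitation([(np.array([1.0]), p1), (np.array([1.0]), p2)])
        assert ge[0] == pytest.approx(1.0)

    def test_silent_senders_contribute_nothing(self):
        ge = net_excitation([(np.zeros(3), _proj(np.full((3, 2), 0.5)))])
        assert np.all(ge == 0)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            net_excitation([(np.ones(2), _proj([[0.5]]))])

    def test_zero_relative_weight_sum_raises(self):
        with pytest.raises(ValueError):
            net_excitation([(np.ones(1), _proj([[0.5]], r=0.0))])


class TestKwta:
    @pytest.mark.parametrize(
        "ge,expected",
        [(0.2, 0.32), (0.1, 0.12), (0.04, 0.0)],
    )
    def test_threshold_reference_values(self, ge, expected):
        p = make_params()
        g = kwta_thresholds(np.array([ge]), p)
        assert g[0] == pytest.approx(expected, abs=1e-12)

    def test_composite_inhibition_value(self):
        # k=2 of 5; second/third largest thresholds 0.32 and 0.12 -> 0.17
        p = make_params(size=5, kwta_frac=0.4)
        ge = np.array([0.25, 0.2, 0.1, 0.05, 0.0])
        assert kwta_inhibition(ge, p) == pytest.approx(0.17, abs=1e-12)

    def test_all_equal_drives_gives_common_threshold(self):
        p = make_params(size=6, kwta_frac=0.5)
        ge = np.full(6, 0.2)
        assert kwta_inhibition(ge, p) == pytest.approx(0.32, abs=1e-12)

    def test_q_interpolation_endpoints(self):
        ge = np.array([0.25, 0.2, 0.1, 0.05, 0.0])
        lo = kwta_inhibition(ge, make_params(size=5, kwta_frac=0.4, q=1e-9))
        hi = kwta_inhibition(ge, make_params(size=5, kwta_frac=0.4, q=1 - 1e-9))
        assert lo == pytest.approx(0.12, abs=1e-6)
        assert hi == pytest.approx(0.32, abs=1e-6)

    def test_layer_too_small_raises(self):
        p = make_params(size=2, kwta_frac=1.0)
        with pytest.raises(ValueError):
            kwta_inhibition(np.array([0.1, 0.2]), p)

    def test_per_unit_ranking_divides_by_gi_bar(self):
        p = make_params(size=4, kwta_frac=0.5,
                        gi_bar=np.array([1.0, 5.0, 1.0, 1.0]))
        ge = np.array([0.2, 0.2, 0.1, 0.05])
        g = kwta_thresholds(ge, p, per_unit_gi_bar=True)
        assert g[1] == pytest.approx(g[0] / 5.0)


class TestSettle:
    def test_exact_k_winners_with_distinct_drives(self):
        p = make_params(size=40, kwta_frac=0.25)
        rng = np.random.default_rng(0)
        w = rng.uniform(0.1, 0.9, size=(1, 40))
        proj = _proj(w)
        state = LayerState.resting(p)
        settle(state, p, [(np.array([1.0]), proj)], n_steps=300)
        assert int((state.y > 0).sum()) == p.k

    def test_converges_to_fixed_point_activity(self):
        p = make_params(size=12, kwta_frac=0.25)
        w = np.linspace(0.1, 0.9, 12)[None, :]
        state = LayerState.resting(p)
        settle(state, p, [(np.array([1.0]), _proj(w))], n_steps=500)
        vm_eq = vm_fixed_point(state.ge, state.gi, p)
        y_eq = activation(vm_eq, p.gamma, p.theta)
        assert np.allclose(state.y, y_eq, atol=1e-3)

    def test_zero_input_silences_layer(self):
        p = make_params(size=8, kwta_frac=0.25)
        state = LayerState.resting(p)
        settle(state, p, [], n_steps=50)
        assert np.all(state.y == 0)

    def test_clamped_layer_bypasses_dynamics(self):
        p = make_params(size=4, kwta_frac=0.5)
        state = LayerState.resting(p)
        pattern = np.array([1.0, 0.0, 1.0, 0.0])
        state.clamp(pattern)
        settle(state, p, [(np.ones(1), _proj(np.full((1, 4), 0.9)))], n_steps=10)
        assert np.array_equal(state.y, pattern)

    def test_monotone_in_own_drive(self):
        """Raising one unit's drive never lowers its settled activity."""
        p = make_params(size=10, kwta_frac=0.3)
        base = np.linspace(0.1, 0.55, 10)
        ys = []
        for bump in (0.0, 0.1, 0.2):
            w = base.copy()
            w[4] = min(0.9, base[4] + bump)
            state = LayerState.resting(p)
            settle(state, p, [(np.array([1.0]), _proj(w[None, :]))], n_steps=300)
            ys.append(state.y[4])
        assert ys[0] <= ys[1] <= ys[2]

    def test_raised_gi_bar_lowers_equilibrium_vm(self):
        p1 = make_params(size=10, kwta_frac=0.3)
        gi_bar = np.ones(10)
        gi_bar[2] = 5.0
        p5 = make_params(size=10, kwta_frac=0.3, gi_bar=gi_bar)
        w = np.linspace(0.2, 0.8, 10)[None, :]
        out = {}
        for tag, p in (("flat", p1), ("suppressed", p5)):
            state = LayerState.resting(p)
            settle(state, p, [(np.array([1.0]), _proj(w))], n_steps=300)
            assert state.gi > 0
            out[tag] = state.Vm[2]
        assert out["suppressed"] < out["flat"]
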