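"""Network assembly, contextual gating, theta-phase trials, lesions."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats as sps

from hippoctx.circuit import NetworkConfig, TrialInput, build_network, default_pathways
from hippoctx.stimuli import make_experiment_stimuli
from hippoctx.protocols import performance_from_rmse, rmse

from conftest import tiny_network_config


def trial_of(problem, mode="encode"):
    return TrialInput(
        x_pattern=problem.odor_pair[0].vector,
        y_pattern=problem.odor_pair[1].vector,
        r_target=problem.rewarded_odor.vector,
        mode=mode,
    )


class TestAssembly:
    def test_connection_probabilities_within_binomial_bounds(self, tiny_net):
        for name, p_expect in (("DG->CA3", 0.04), ("CA3->CA1", None)):
            proj = tiny_net.projections[name]
            if p_expect is None:
                assert proj.mask.all()
            else:
                n = proj.mask.size
                frac = proj.mask.sum() / n
                se = np.sqrt(p_expect * (1 - p_expect) / n)
                assert abs(frac - p_expect) < 5 * se

    def test_perforant_path_samples_cue_fields_only(self, tiny_net):
        cfg = tiny_net.cfg
        r_field = slice(2 * cfg.field_size, 3 * cfg.field_size)
        for name in ("ECin->DG", "ECin->CA3"):
            assert tiny_net.projections[name].mask[r_field].sum() == 0
            assert tiny_net.projections[name].mask[: 2 * cfg.field_size].sum() > 0
        # probability within the sampled fields stays ~25%
        sub = tiny_net.projections["ECin->DG"].mask[: 2 * cfg.field_size]
        frac = sub.sum() / sub.size
        assert abs(frac - 0.25) < 5 * np.sqrt(0.25 * 0.75 / sub.size)

    def test_one_to_one_feedback_is_identity(self, tiny_net):
        mask = tiny_net.projections["ECout->ECin"].mask
        assert np.array_equal(mask, np.eye(mask.shape[0], dtype=mask.dtype))

    def test_same_seed_rebuilds_identical_network(self, tiny_cfg):
        n1 = build_network(tiny_cfg, seed=123)
        n2 = build_network(tiny_cfg, seed=123)
        for name in n1.projections:
            assert np.array_equal(n1.projections[name].w, n2.projections[name].w)
            assert np.array_equal(n1.projections[name].mask, n2.projections[name].mask)

    def test_pathway_table_default_values(self):
        table = {s.name: s for s in default_pathways()}
        assert table["DG->CA3"].a == 10.0 and table["DG->CA3"].r == 3.5
        assert table["CA3->CA1"].a == 5.0
        assert table["CA1->ECout"].r == 2.0 and table["CA1->ECout"].k_hebb == 0.05
        assert table["ECin->DG"].k_hebb == 1.0
        assert table["ECout->ECin"].p == "one_to_one"


class TestContextControl:
    def test_context_suppresses_three_quarters_of_dg(self, tiny_net):
        tiny_net.set_context("A")
        gi = tiny_net.params["DG"].gi_bar
        assert (gi == 5.0).sum() == 3 * tiny_net.cfg.dg_ensemble_size
        assert (gi == 1.0).sum() == tiny_net.cfg.dg_ensemble_size

    def test_inactivation_levels_all_excitability(self, tiny_net):
        tiny_net.set_pfc_inactivated()
        assert np.all(tiny_net.params["DG"].gi_bar == 1.0)

    def test_context_toggle_is_idempotent(self, tiny_net):
        tiny_net.set_context("B")
        gi1 = tiny_net.params["DG"].gi_bar.copy()
        tiny_net.set_context("C")
        tiny_net.set_context("B")
        assert np.array_equal(gi1, tiny_net.params["DG"].gi_bar)

    def test_unknown_context_rejected(self, tiny_net):
        with pytest.raises(ValueError):
            tiny_net.set_context("Z")

    def test_trial_requires_context_in_normal_mode(self, tiny_cfg, stimuli_set):
        net = build_network(tiny_cfg, seed=1)
        with pytest.raises(RuntimeError):
            net.run_trial(trial_of(stimuli_set.list1[0]))


class TestPhaseGating:
    def test_monosynaptic_path_silenced_during_recall_phase(self, tiny_net):
        drives = tiny_net._phase_drives(2)
        ca1_senders = [src for src, _, _ in drives["CA1"]]
        assert "ECin" not in ca1_senders and "CA3" in ca1_senders

    def test_ca3_recall_blocked_from_output_in_encoding_phases(self, tiny_net):
        for phase in (1, 3):
            drives = tiny_net._phase_drives(phase)
            ca1_senders = [src for src, _, _ in drives["CA1"]]
            assert "CA3" not in ca1_senders and "ECin" in ca1_senders

    def test_full_trisynaptic_gate_option(self):
        cfg = tiny_network_config(full_trisynaptic_gate=True)
        net = build_network(cfg, seed=3)
        drives = net._phase_drives(1)
        assert "CA3" not in drives and "DG" not in drives


class TestTrial:
    def test_learn_off_leaves_weights_untouched(self, tiny_net, stimuli_set):
        tiny_net.set_context("A")
        before = {k: p.w.copy() for k, p in tiny_net.projections.items()}
        tiny_net.run_trial(trial_of(stimuli_set.list1[0]), learn=False)
        for k, p in tiny_net.projections.items():
            assert np.array_equal(before[k], p.w)

    def test_encode_trial_updates_only_masked_weights(self, tiny_net, stimuli_set):
        tiny_net.set_context("A")
        tiny_net.run_trial(trial_of(stimuli_set.list1[0]), learn=True)
        for p in tiny_net.projections.values():
            assert np.all(p.w[p.mask == 0] == 0)
            assert p.w.min() >= 0 and p.w.max() <= 1

    def test_normal_mode_activity_confined_to_selected_ensemble(self, tiny_cfg, stimuli_set):
        net = build_network(tiny_cfg, seed=11)
        net.set_context("A")
        ens = net.cfg.ensemble_slice("A")
        for problem in stimuli_set.list1:
            res = net.run_trial(trial_of(problem), learn=True)
            assert np.all((res.dg_active_units >= ens.start) & (res.dg_active_units < ens.stop))

    def test_inactivation_recruits_more_dg_cells(self, tiny_cfg, stimuli_set):
        net = build_network(tiny_cfg, seed=11)
        normal, inact = [], []
        for problem in stimuli_set.list1:
            net.set_context("A")
            normal.append(net.run_trial(trial_of(problem), learn=False).dg_active)
            net.set_pfc_inactivated()
            inact.append(net.run_trial(trial_of(problem), learn=False).dg_active)
        assert np.mean(inact) > np.mean(normal)

    def test_same_seed_reproduces_trajectories_bitwise(self, tiny_cfg, stimuli_set):
        outs = []
        for _ in range(2):
            net = build_network(tiny_cfg, seed=21)
            net.set_context("A")
            r = net.run_trial(trial_of(stimuli_set.list1[0]), learn=True)
            r = net.run_trial(trial_of(stimuli_set.list1[1]), learn=True)
            outs.append(r.r_out)
        assert np.array_equal(outs[0], outs[1])

    def test_mossy_lesion_removes_contextual_influence(self, stimuli_set):
        """Without DG->CA3 the drug manipulation cannot reach the output."""
        cfg = tiny_network_config(vm_noise_sd=0.0)
        net = build_network(cfg, seed=31)
        net.lesion("DG->CA3")
        problem = stimuli_set.list1[0]
        net.set_context("A")
        r_saline = net.run_trial(trial_of(problem, mode="test"), learn=False)
        net.set_pfc_inactivated()
        r_musc = net.run_trial(trial_of(problem, mode="test"), learn=False)
        assert np.array_equal(r_saline.r_out, r_musc.r_out)

    def test_trained_association_recalled_from_cue_alone(self, stimuli_set):
        """End-to-end: encode one problem to criterion, recall with reward cue absent."""
        net = build_network(NetworkConfig(), seed=41)
        net.set_context("A")
        problem = stimuli_set.list1[0]
        for _ in range(16):
            net.run_trial(trial_of(problem), learn=True)
        res = net.run_trial(trial_of(problem, mode="test"), learn=False)
        assert rmse(res.r_out, problem.rewarded_odor.vector) < 0.2
        assert performance_from_rmse(rmse(res.r_out, problem.rewarded_odor.vector)) > 90


class TestConfig:
    def test_yaml_round_trip(self):
        cfg = NetworkConfig(dg_ensemble_size=128, vm_noise_sd=0.02)
        back = NetworkConfig.from_yaml(cfg.to_yaml())
        assert back == cfg

    def test_invalid_probability_rejected(self):
        from hippoctx.circuit import PathwaySpec, _sample_mask

        bad = PathwaySpec("x", "a", "b", 1.5, 1.0, 1.0, 1.0, 2)
        with pytest.raises(ValueError):
            _sample_mask(bad, 4, 4, np.random.default_rng(0))
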