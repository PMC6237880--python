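"""Shared fixtures: small networks for unit tests, full experiment runs for
the acceptance suite (session-scoped so each protocol simulates once)."""

from dataclasses import replace

import numpy as np
import pytest

from hippoctx.circuit import NetworkConfig, build_network
from hippoctx.protocols import (
    ExperimentConfig,
    run_navawongse,
    run_p1a,
    run_p1b,
    run_p2,
    run_p3,
)
from hippoctx.stimuli import make_experiment_stimuli

# fixed protocol seeds (one per experiment, chosen once)
SEEDS = {
    "p1a": 101,
    "p1a_nopre": 102,
    "nav": 103,
    "p1b": 104,
    "p2": 105,
    "p3": 106,
    "p3_nopre_k1": 107,
    "p3_nopre_k10": 108,
    "p3_nopre_k25": 109,
    "nav_lesion": 110,
}


def tiny_network_config(**kw) -> NetworkConfig:
    """A scaled-down circuit for fast unit tests (structure preserved)."""
    base = dict(dg_ensemble_size=100, ca3_size=80, ca1_size=120, vm_noise_sd=0.0)
    base.update(kw)
    return NetworkConfig(**base)


@pytest.fixture(scope="session")
def tiny_cfg() -> NetworkConfig:
    return tiny_network_config()


@pytest.fixture()
def tiny_net(tiny_cfg):
    return build_network(tiny_cfg, seed=7)


@pytest.fixture(scope="session")
def stimuli_set():
    return make_experiment_stimuli(np.random.default_rng(3))


@pytest.fixture(scope="session")
def exp_cfg() -> ExperimentConfig:
    return ExperimentConfig(n_per_group=10)


@pytest.fixture(scope="session")
def exp1a(exp_cfg):
    """Experiment 1A with lifetime pre-training, N=10 per group."""
    return run_p1a(exp_cfg, seed=SEEDS["p1a"])


@pytest.fixture(scope="session")
def exp1a_nopre(exp_cfg):
    """Experiment 1A without pre-training, N=10 per group."""
    return run_p1a(replace(exp_cfg, pretraining=False), seed=SEEDS["p1a_nopre"])


@pytest.fixture(scope="session")
def navawongse(exp_cfg):
    return run_navawongse(exp_cfg, seed=SEEDS["nav"])


@pytest.fixture(scope="session")
def navawongse_lesioned(exp_cfg):
    """Context-guided retrieval with the mossy fibers cut before any training.

    Pre-training is omitted (the lesioned circuit cannot form contextual
    memories to interfere) and training is capped: lesioned rats do not reach
    criterion, so the cap acts as a fixed session length.
    """
    from hippoctx import protocols as P

    cfg = replace(exp_cfg, pretraining=False, max_blocks=12)
    rats = P._spawn_rats(SEEDS["nav_lesion"], {"all": cfg.n_per_group}, cfg)
    import pandas as pd

    for rat in rats:
        rat.net.lesion("DG->CA3")
        rat.run_to_criterion(rat.stim.list1, phase_name="train_A", context="A")
        rat.run_to_criterion(rat.stim.list1_reversed, phase_name="train_B", context="B")
        for condition, inact in (("saline", False), ("muscimol", True)):
            for context, problems in (("A", rat.stim.list1), ("B", rat.stim.list1_reversed)):
                for block in (1, 2):
                    rat.run_block(
                        problems,
                        phase_name=f"test_{condition}",
                        block=block,
                        mode="test",
                        inactivated=inact,
                        context=context,
                        learn=False,
                    )
    trials = pd.concat([r.to_frame() for r in rats], ignore_index=True)
    test = trials[trials["mode"] == "test"]
    per_rat = test.groupby([test["phase"], test["rat"]])["perf"].mean().unstack(0)
    return P.ExperimentResult(
        "navawongse_lesioned",
        trials,
        {
            "saline_mean": float(per_rat["test_saline"].mean()),
            "muscimol_mean": float(per_rat["test_muscimol"].mean()),
            "per_rat": per_rat,
        },
    )


@pytest.fixture(scope="session")
def exp1b(exp_cfg):
    return run_p1b(exp_cfg, seed=SEEDS["p1b"])


@pytest.fixture(scope="session")
def exp2(exp_cfg):
    return run_p2(exp_cfg, seed=SEEDS["p2"])


@pytest.fixture(scope="session")
def exp3(exp_cfg):
    return run_p3(exp_cfg, seed=SEEDS["p3"])


@pytest.fixture(scope="session")
def exp3_nopre_sweep(exp_cfg):
    """Experiment 3 without pre-training at the sparse and dense ends of the
    DG sweep (the CLI ``sweep`` command covers intermediate levels)."""
    out = {}
    for level, key in ((0.01, "p3_nopre_k1"), (0.25, "p3_nopre_k25")):
        cfg = replace(exp_cfg, pretraining=False, dg_kwta=level)
        out[level] = run_p3(cfg, seed=SEEDS[key])
    return out
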