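# hippoctx

A rate-coded simulator of contextual associative memory in the rodent
entorhinal–hippocampal circuit, built to study how top-down prefrontal (PFC)
control of dentate gyrus (DG) excitability gates memory encoding and recall —
and what breaks when that control is removed (muscimol inactivation).

The model comprises superficial/deep lateral entorhinal cortex (ECin/ECout),
DG partitioned into four contextual ensembles, a fully recurrent CA3, and CA1.
Odor-discrimination memories ({X_i, Y_i} → rewarded odor) are encoded over
three theta phases per trial: a monosynaptic encoding half (ECin→CA1), a
trisynaptic recall half (ECin→DG/CA3, DG→CA3 mossy fibers, CA3→CA1) whose
ECout readout is the behavioral response, and a plus phase with the target
clamped, after which weights update by a mixture of conditional-PCA Hebbian
and contrastive (error-driven) learning:

    dw = ε [ k_hebb · y⁺(qm·x⁺(1−w) − (1−x⁺)w) + (1−k_hebb) · soft(x⁺y⁺ − x⁻y⁻) ]

Membrane dynamics are shunting (conductance-based) with k-winners-take-all
feedback inhibition per layer; a context is selected by raising the maximal
inhibitory conductance (1 → 5) of every DG ensemble except the relevant one,
and PFC inactivation simply removes that bias.  Retrieval performance per
trial is scored from the RMSE E between the recalled and target reward codes,

    P(%) = max(50, 100·(1−E)¹⁰ / (10·0.5¹⁰ + (1−E)¹⁰)),

so chance is 50% and perfect recall ≈ 99%.

The package reproduces, as simulated behavioral experiments with 10 rats per
group: context-guided retrieval of conflicting lists and its collapse under
inactivation; concurrent and one-at-a-time list acquisition with inactivation
windows; conflicting-list (proactive interference) designs with interference
index and perseverative/non-perseverative error taxonomy; the paradoxical
facilitation of a conflicting list after earlier inactivation; and the
model's predictions (no-pretraining variants, DG sparsity sweep, DG
recruitment counts, mossy-fiber lesion).  See `docs/methods.md` for the full
model description and design rationale.

## Worked example

```python
import numpy as np
from hippoctx import NetworkConfig, build_network, TrialInput
from hippoctx.stimuli import make_experiment_stimuli
from hippoctx.protocols import rmse, performance_from_rmse

stim = make_experiment_stimuli(np.random.default_rng(3))
problem = stim.list1[0]
trial = TrialInput(problem.odor_pair[0].vector, problem.odor_pair[1].vector,
                   problem.rewarded_odor.vector)

net = build_network(NetworkConfig(), seed=41).set_context("A")
for i in range(16):                      # sixteen encoding trials
    res = net.run_trial(trial, learn=True)
    if i % 5 == 0:
        e = rmse(res.r_out, problem.rewarded_odor.vector)
        print(f"trial {i:2d}: recall RMSE {e:.3f}  P {performance_from_rmse(e):5.1f}%")

probe = TrialInput(problem.odor_pair[0].vector, problem.odor_pair[1].vector,
                   problem.rewarded_odor.vector, mode="test")
e = rmse(net.run_trial(probe, learn=False).r_out, problem.rewarded_odor.vector)
print(f"cue-only test: RMSE {e:.3f}  P {performance_from_rmse(e):5.1f}%")
net.set_pfc_inactivated()
e = rmse(net.run_trial(probe, learn=False).r_out, problem.rewarded_odor.vector)
print(f"inactivated : RMSE {e:.3f}  P {performance_from_rmse(e):5.1f}%")
```

prints

```
trial  0: recall RMSE 0.525  P  50.0%
trial  5: recall RMSE 0.149  P  95.3%
trial 10: recall RMSE 0.135  P  96.0%
trial 15: recall RMSE 0.086  P  97.6%
cue-only test: RMSE 0.083  P  97.7%
inactivated : RMSE 0.103  P  97.2%
```

Recall starts at the 50% chance floor, climbs as the association is encoded,
and survives removal of the reward cue at test.  With only a single memory
stored, inactivation is harmless — the drop appears once conflicting memories
from other contexts exist (run the experiments below).

Experiments run from the shell:

```
hippoctx run p1a --seed 7 --out out/p1a          # concurrent acquisition + tests
hippoctx run navawongse --seed 7 --out out/nav   # context-guided retrieval
hippoctx sweep --param dg_kwta --values 0.01,0.10,0.25 --experiment p3 \
    --no-pretraining --seed 7 --out out/sweep
hippoctx report out/p1a
```

Each run writes `trials.csv` (one row per trial), `blocks.csv` (per-block
group mean ± SEM) and `summary.json`.

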