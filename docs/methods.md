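# Methods

`hippoctx` simulates contextual associative memory in the rodent
entorhinal–hippocampal system and the behavioral consequences of removing
top-down prefrontal (PFC) control over dentate gyrus (DG) excitability.  This
note documents the model, its parameters, the synthetic task battery, the
numerical choices, and the design decisions taken where the architecture was
genuinely open.

## The circuit

Five rate-coded layers: superficial lateral entorhinal cortex (ECin, 3 fields
of 24 cells: odor X, odor Y, reward R), deep LEC (ECout, same geometry), DG
(four contextual ensembles of 800 cells), CA3 (240 cells, fully recurrent) and
CA1 (400 cells).  Pathways follow the standard anatomy: perforant path
ECin→{DG, CA3, CA1} (25% connection probability; the projections to DG and CA3
sample the two odor-cue fields — see *Cue-defined codes* below), mossy fibers
DG→CA3 (4%, absolute synaptic scale 10, relative weight 3.5), Schaffer
collaterals CA3→CA1 (full, scale 5), recurrent CA3→CA3 (full), CA1→ECout
(full, relative weight 2), and a one-to-one ECout→ECin feedback.

### Membrane dynamics

Each cell obeys shunting dynamics on a normalized 0–1 voltage scale

    dVm/dt = tau [ gl(El − Vm) + ge·ge_bar(Ee − Vm) + gi·gi_bar(Ei − Vm) ]

with gl = 0.1, ge_bar = 1, El = 0.3, Ee = 1, Ei = 0.25, Vrest = 0.3, and
tau = 0.3 per 1-ms step.  Output activity is the saturating rectifier
y = χ/(1+χ), χ = 100·[Vm − 0.5]+.  Because the mossy-fiber scale (10) and the
contextual inhibitory conductance (gi_bar = 5 on suppressed DG cells) produce
total conductances far above the forward-Euler stability bound, each step is
integrated exactly for the step-constant conductances (exponential Euler).
The fixed points are identical to the differential equation's; the integrator
choice affects only the transient.

### Net input

A cell's excitatory drive from projection j is

    ge_i = (r_j / Σ_k r_k) · a_j · Σ_h x_h w_hi / (fan_in_i · α_src)

where α_src is the sending layer's kWTA activity fraction, so the divisor is
the *expected number of active inputs*.  This keeps ge on the same O(1) scale
for a 72-cell cortical field and a 3200-cell DG, which is what makes a single
conductance table meaningful across layers.  The relative-weight
normalization Σ_k r_k runs over the projections that are open in the current
theta phase.

### kWTA inhibition

A single inhibitory conductance per layer is set each step between the k-th
and (k+1)-th largest "threshold inhibition" values
g_theta = [ge·ge_bar(Ee−θ) + gl(El−θ)]/(θ−Ei), interpolated with q = 0.25.
Winner fractions: LEC 25%, DG 1%, CA3/CA1 2.5%.  With the contextual
gi_bar split (1 on the selected ensemble, 5 elsewhere) this ranking is
computed on the printed, gi_bar-free form.  The consequence — intended, and
and a testable prediction of the theory — is that under normal operation
the raised inhibition truncates the DG code below k (≈10 active cells per
trial, all inside the selected ensemble), while PFC inactivation (all
gi_bar = 1) lets the full k ≈ 32 win: **the number of active DG cells rises
when the top-down bias is removed**.  An alternative ranking that divides each
cell's threshold by its own gi_bar (config `kwta_rank_per_unit_gi`) hands
every slot to the facilitated ensemble and equalizes the counts; it is off by
default precisely because it abolishes that count prediction.

### Theta-phase trial structure

Each trial runs three 30-step phases.  Phase 1 (first minus half): CA3→CA1 is
gated off; CA1 auto-encodes the ECin pattern through the monosynaptic path,
decoupled from CA3 recall.  Phase 2 (second minus half): ECin→CA1 is gated
off; CA1 is driven by the pattern-completing CA3 engram and the recalled
reward pattern is read from ECout's third field at the end of the phase.
Phase 3 (plus): gating as phase 1 with ECout clamped to the full target
pattern; weights update at the end.  CA1 resets to rest at each phase start,
everything else at trial start.  ECin is clamped to the cortical input in all
phases; on test trials the R field is zeroed and only phases 1–2 run, with
learning off.

A stricter variant that silences every trisynaptic projection during phases 1
and 3 is available (`full_trisynaptic_gate`) but is off by default: with DG
and CA3 silent in the plus phase, the purely Hebbian trisynaptic pathways
would never experience a co-active pre/post pair and could not learn at all.
Keeping mossy and recurrent drive on during the plus phase is also what lets
old CA3 attractors compete with new engrams — the interference mechanism the
model exists to study.

### Learning

Weights update at the end of each encoding trial's plus phase:

    dw = ε [ k_hebb · dw_hebb + (1 − k_hebb) · dw_err ]

with k_hebb = 1 on trisynaptic pathways and 0.05 on the monosynaptic ones
(ECin→CA1, CA1→ECout, ECout→ECin), which take their minus-phase snapshot from
the first minus half.  Learning rates (free parameters of the model):
ε = 0.1 for Hebbian pathways, 0.05 for mixed ones.

The Hebbian rule is conditional-PCA with a sender-average correction,

    dw_hebb = y+ [ qm · x+ (1 − w) − (1 − x+) w ],   qm = 0.5 / α_src,

which reduces to the textbook self-bounding form y+(x+ − w) at qm = 1.  The
correction makes reliably co-active pairs saturate near 1 instead of at the
sender amplitude and prevents a synapse shared between two list problems from
being erased by cross-problem depression.  The error-driven rule is the
contrastive difference x+y+ − x−y−, soft-bounded (positive part scaled by
1 − w, negative by w) and clipped to [0, 1].

Net input reads the weights through a contrast sigmoid
w_eff = 1/(1 + (1.25(1−w)/w)^6); learning operates on the linear weights.
Initial weights are uniform on [0.25, 0.75] *on the effective scale* (the
stored linear weights are the sigmoid preimage), so an untrained synapse sits
mid-range while a learned one stands clear at ≈1.  Without this separation
the learned Schaffer drive is statistically indistinguishable from the lucky
tail of ~400 untrained competitors and recall ranking fails on many seeds.

### Cue-defined codes

The perforant-path projections to DG and CA3 sample only the two odor-cue
fields of ECin (config `pp_fields`).  Two reasons.  First, recall must be
driven by the odors: with the reward field included, the DG code computed
during encoding (reward present) and testing (reward absent) diverge, and
cue-only recall collapses on a fraction of seeds.  Second, under PFC
inactivation the reward input would act as a congruence filter, selectively
recruiting exactly those old-context ensembles whose stored reward agrees
with the current one — old memories would then only ever help, inverting the
interference phenomenology.  The monosynaptic path and the output clamp still
carry the full three-field pattern, so reward associations are learned and
recalled normally.

### Membrane noise

Independent Gaussian jitter (SD 0.01 on the 0–1 voltage scale, seeded per
network) is added each integration step.  The model's account of inactivation
requires stochastic attractor resolution — recall under conflicting engrams is
described as a random choice between contexts, and encoding interference as
CA3 "slipping" into different attractors on different trials.  A fully
deterministic settle resolves every such competition identically and
suppresses both phenomena.  Noise level is small enough that a lone,
well-supported engram is recalled reliably.

## Contextual control

`set_context(c)` raises gi_bar to 5 on the three DG ensembles outside context
c; `set_pfc_inactivated()` sets all gi_bar to 1.  Nothing else changes —
no weights, no kWTA parameters.  `lesion("DG->CA3")` removes the mossy
pathway, which disconnects the contextual machinery from CA3 entirely.

## Task battery

All inputs are synthetic.  Odors are 24-cell binary codes with exactly six
active cells, drawn uniformly.  A discrimination problem pairs two odors with
a randomly baited side, fixed across blocks; a block presents each problem of
a list once in fresh random order.  Retrieval performance per trial is

    P(%) = max(50, 100 (1−E)^10 / (10·0.5^10 + (1−E)^10))

from the RMSE E between the recalled and target reward fields; chance is 50%
(two-alternative choice) and perfect recall ≈ 99%.  The learning criterion is
a block-mean P ≥ 90% in two consecutive blocks (cap 50 blocks).  Discrete
choices (nearest odor code to the recalled pattern, ties random) feed the
error taxonomy only.

Lists per simulated rat: List 1 ({X_i, Y_i}, i = 1..8, context A); its
reversal (same pairs, opposite bait, context B); List 2 (one odor of each
List-1 pair retained with its reward status reversed, paired with a novel
odor); two pre-training lists ({X_i, Z_i} in context C, {Z_i, Y_i} in
context D, 10 blocks each) that emulate a lifetime of earlier memories
overlapping the experimental stimuli; and ten problems for one-at-a-time
acquisition.  Experiment protocols (group sizes 10, inactivation windows,
test-block schedules) follow the designs of the original rat studies; the five runners and the
prediction variants are documented in `protocols.py`.

Simulated-rat independence: each rat gets its own network seed, stimulus set
and behavioral RNG from a spawned seed sequence, so group statistics are over
genuinely independent replicates, and identical master seeds reproduce runs
bit for bit.

## What the synthetic battery does and does not capture

The generator reproduces the list structure, overlap design and schedule of
the target experiments, not the sensory richness of real odors: codes are
uncorrelated by construction, reward sides are balanced Bernoulli draws, and
"context" enters only through ensemble selection.  Passing tests therefore
demonstrate that the circuit mechanism produces the experimentally reported phenomenology
under the idealized task statistics; they do not certify quantitative rates
for real animals, odor-similarity generalization, or motivational effects.

## Known limitations

* With the printed kWTA ranking, inactivation enlarges the DG code (~10 → ~32
  cells/trial).  The extra mossy support partially offsets encoding
  interference, so simulated inactivated groups are not reliably *slower*
  during acquisition blocks 1–3 — the experimentally reported acquisition-impairment
  direction — even though retrieval impairment, its pretraining dependence and
  the recruitment prediction all reproduce.  Within a strict-k winner rule the
  count-increase prediction and the acquisition impairment pull in opposite
  directions; the package resolves the tension in favor of the count
  prediction and records the test outcomes honestly.
* For the same reason, groups trained under inactivation rebuild an
  in-context memory footprint once the bias returns (visible as a dip on the
  first post-inactivation block), which equalizes the proactive interference
  their later conflicting list faces and suppresses the reported List-2
  facilitation effect.
* Conflicting-list interference acts partly at the CA1→ECout readout, which
  is not context-gated; this flattens the same-context versus
  different-context contrast for control groups (the direction reproduces,
  and perseverative errors concentrate in the same-context control group, as reported experimentally, but the contrasts are weaker than the reported ones).
* CA3 engrams are small (k = 6); single-problem recall rests on few cells,
  which is what makes the system sensitive to engram competition — by design,
  but it also means some problems are intrinsically harder than others for a
  given connectivity draw (the blocked-acquisition difficulty split exploits
  exactly this).
* Problem sizes (layer sizes above, 10 rats/group, 30-step phases) are the
  package defaults chosen for robust statistics on a workstation; all are
  config-exposed.
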