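"""The assembled entorhinal-hippocampal circuit and its three-phase trial loop.

The network comprises superficial (ECin) and deep (ECout) lateral entorhinal
cortex, dentate gyrus (DG), CA3 and CA1.  Cortical odor codes arrive clamped
onto three 24-cell fields of ECin (the two cue odors X and Y plus the reward
field R); the hippocampus must regenerate the R field on ECout.

Two routes carry ECin to CA1: the monosynaptic perforant path ECin -> CA1, and
the trisynaptic path ECin -> DG/CA3, DG -> CA3 (mossy fibers), CA3 -> CA1
(Schaffer collaterals) with full recurrence inside CA3.  Each trial is a cycle
of three theta phases, 30 settling steps each:

1. first minus half:  CA3 -> CA1 gated off; CA1 auto-encodes the ECin pattern
   through the monosynaptic path, decoupled from CA3 recall.
2. second minus half: ECin -> CA1 gated off; CA1 is driven by the
   pattern-completing CA3 engram, and the recalled R pattern is read from
   ECout at the end of this phase.
3. plus phase: gating as phase 1 with ECout hard-clamped to the full target
   pattern; weight updates are applied at the end (encoding trials only).

CA1 potentials are reset to rest at each phase start; all other layers reset at
trial start.  Contextual control operates on DG only: the active context's
ensemble keeps its inhibitory conductance at the normal value, all other
ensembles are suppressed with a raised one.  PFC inactivation removes the bias,
leaving every DG ensemble at normal excitability.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import netcore
from .netcore import LayerParams, LayerState, activation, kwta_inhibition, step_vm
from .plasticity import (
    PhaseSnapshots,
    Projection,
    apply_update,
    init_weights,
    inverse_contrast,
)

__all__ = [
    "PathwaySpec",
    "NetworkConfig",
    "ContextState",
    "TrialInput",
    "TrialResult",
    "Network",
    "build_network",
    "set_context",
    "set_pfc_inactivated",
    "run_trial",
]

LAYERS = ("ECin", "ECout", "DG", "CA3", "CA1")

# engine-internal precision: single precision is ample for the settling
# dynamics (netcore's reference implementations stay in double precision)
DTYPE = np.float32

try:  # fused per-layer step kernel; falls back to plain numpy without numba
    from numba import njit

    @njit(cache=False, fastmath=True)
    def _step_layer(Vm, y, ge, gi_bar, noise, use_noise, rank_per_unit,
                    c_e, c_l, c_d, k, q, gl, ge_bar, El, Ee, Ei, theta, gamma, tau):
        n = Vm.shape[0]
        g_theta = (ge * c_e + c_l) / c_d
        if rank_per_unit:
            g_theta = g_theta / gi_bar
        part = np.partition(g_theta, n - k - 1)
        g_k1 = part[n - k - 1]
        g_k = part[n - k]
        for i in range(n - k + 1, n):
            if part[i] < g_k:
                g_k = part[i]
        gi = g_k1 + q * (g_k - g_k1)
        if gi < 0.0:
            gi = 0.0
        for i in range(n):
            g_exc = ge[i] * ge_bar
            g_inh = gi * gi_bar[i]
            g_tot = gl + g_exc + g_inh
            v_inf = (gl * El + g_exc * Ee + g_inh * Ei) / g_tot
            v = v_inf + (Vm[i] - v_inf) * np.exp(-tau * g_tot)
            if use_noise:
                v += noise[i]
            Vm[i] = v
            chi = gamma * (v - theta)
            y[i] = chi / (1.0 + chi) if chi > 0.0 else 0.0
        return gi

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False


@dataclass(frozen=True)
class PathwaySpec:
    """Static description of one pathway: connectivity and learning mix."""

    name: str
    src: str
    dst: str
    p: float | str | None  # probability, "one_to_one", or None for full
    k_hebb: float
    a: float
    r: float
    minus_phase: int
    gated_phases: tuple[int, ...] = ()


def default_pathways(full_trisynaptic_gate: bool = False) -> tuple[PathwaySpec, ...]:
    """The standard connectivity table.

    With ``full_trisynaptic_gate`` every trisynaptic pathway is silenced in
    phases 1 and 3; the default gates only CA3 -> CA1 there (blocking CA3-based
    recall from reaching output) so DG and CA3 remain active in the plus phase
    and their Hebbian pathways can learn.
    """
    tri = (1, 3) if full_trisynaptic_gate else ()
    return (
        PathwaySpec("ECin->DG", "ECin", "DG", 0.25, 1.0, 1.0, 1.0, 2, tri),
        PathwaySpec("ECin->CA3", "ECin", "CA3", 0.25, 1.0, 1.0, 1.0, 2, tri),
        PathwaySpec("ECin->CA1", "ECin", "CA1", 0.25, 0.05, 1.0, 1.0, 1, (2,)),
        PathwaySpec("DG->CA3", "DG", "CA3", 0.04, 1.0, 10.0, 3.5, 2, tri),
        PathwaySpec("CA3->CA3", "CA3", "CA3", None, 1.0, 1.0, 1.0, 2, tri),
        PathwaySpec("CA3->CA1", "CA3", "CA1", None, 1.0, 5.0, 1.0, 2, (1, 3)),
        PathwaySpec("CA1->ECout", "CA1", "ECout", None, 0.05, 1.0, 2.0, 1, ()),
        PathwaySpec("ECout->ECin", "ECout", "ECin", "one_to_one", 0.05, 1.0, 1.0, 1, ()),
    )


@dataclass
class NetworkConfig:
    """Sizes, sparsity levels, contextual-gain values and phase schedule."""

    field_size: int = 24
    n_fields: int = 3
    dg_ensembles: tuple[str, ...] = ("A", "B", "C", "D")
    dg_ensemble_size: int = 800
    ca3_size: int = 240
    ca1_size: int = 400
    kwta_lec: float = 0.25
    kwta_dg: float = 0.01
    kwta_ca3: float = 0.025
    kwta_ca1: float = 0.025
    gi_bar_normal: float = 1.0
    gi_bar_suppressed: float = 5.0
    phase_steps: int = 30
    tau: float = 0.3
    epsilon_hebb: float = 0.1
    epsilon_err: float = 0.05
    wt_sig_gain: float = 6.0
    wt_sig_off: float = 1.25
    hebb_savg_cor: float = 0.5  # qm = hebb_savg_cor / sender activity; 0 disables
    hebb_depress: float = 1.0  # scale on Hebbian heterosynaptic depression
    # rank kWTA thresholds by each cell's own excitability (g_theta / gi_bar)
    # instead of the printed uniform-gi_bar form; with the contextual split
    # this hands the whole DG competition budget to the facilitated ensemble
    kwta_rank_per_unit_gi: bool = False
    # per-step membrane jitter (SD on the 0-1 Vm scale): resolves competition
    # between near-equal attractors stochastically from trial to trial
    vm_noise_sd: float = 0.01
    # perforant-path projections to DG/CA3 sample only these ECin fields
    # (0 = X odor, 1 = Y odor, 2 = reward).  Excluding the reward field makes
    # hippocampal codes cue-defined, so recall is driven by the odors alone
    # and the code does not shift when the reward field is absent at test.
    pp_fields: tuple[int, ...] = (0, 1)
    full_trisynaptic_gate: bool = False

    @property
    def lec_size(self) -> int:
        return self.field_size * self.n_fields

    @property
    def dg_size(self) -> int:
        return self.dg_ensemble_size * len(self.dg_ensembles)

    def ensemble_slice(self, context: str) -> slice:
        i = self.dg_ensembles.index(context)
        return slice(i * self.dg_ensemble_size, (i + 1) * self.dg_ensemble_size)

    def layer_params(self) -> dict[str, LayerParams]:
        common = dict(tau=self.tau)
        return {
            "ECin": LayerParams(self.lec_size, self.kwta_lec, **common),
            "ECout": LayerParams(self.lec_size, self.kwta_lec, **common),
            "DG": LayerParams(self.dg_size, self.kwta_dg, **common),
            "CA3": LayerParams(self.ca3_size, self.kwta_ca3, **common),
            "CA1": LayerParams(self.ca1_size, self.kwta_ca1, **common),
        }

    def to_yaml(self) -> str:
        d = asdict(self)
        d["dg_ensembles"] = list(self.dg_ensembles)
        d["pp_fields"] = list(self.pp_fields)
        return yaml.safe_dump(d)

    @classmethod
    def from_yaml(cls, text: str) -> "NetworkConfig":
        d = yaml.safe_load(text)
        for key in ("dg_ensembles", "pp_fields"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class ContextState:
    mode: str = "normal"  # "normal" | "pfc_inactivated"
    active_context: str | None = None


@dataclass
class TrialInput:
    """One discrimination trial's cortical input.

    ``r_target`` is the rewarded odor's code; in test mode the R field
    presented to ECin is zeroed and the target is only used for scoring.
    """

    x_pattern: np.ndarray
    y_pattern: np.ndarray
    r_target: np.ndarray
    mode: str = "encode"  # "encode" | "test"

    def __post_init__(self) -> None:
        if self.mode not in ("encode", "test"):
            raise ValueError("mode must be 'encode' or 'test'")


@dataclass
class TrialResult:
    snapshots: PhaseSnapshots
    r_out: np.ndarray
    dg_active: int
    dg_active_units: np.ndarray


class Network:
    """The assembled circuit plus context state."""

    def __init__(
        self,
        cfg: NetworkConfig,
        params: dict[str, LayerParams],
        projections: dict[str, Projection],
        seed: int | None = None,
        noise_seed: int | np.random.SeedSequence | None = None,
    ) -> None:
        self.cfg = cfg
        self.params = params
        self.projections = projections
        self.context = ContextState()
        self.seed = seed
        self.states = {name: LayerState.resting(p) for name, p in params.items()}
        self.noise_rng = np.random.default_rng(noise_seed)
        self._w_norm_cache: dict[str, np.ndarray] = {}

    # -- contextual control -------------------------------------------------

    def set_context(self, context_id: str) -> "Network":
        """Facilitate one DG ensemble; suppress the rest via raised gi_bar."""
        cfg = self.cfg
        if context_id not in cfg.dg_ensembles:
            raise ValueError(f"unknown context {context_id!r}")
        gi = np.full(cfg.dg_size, cfg.gi_bar_suppressed)
        gi[cfg.ensemble_slice(context_id)] = cfg.gi_bar_normal
        self.params["DG"].gi_bar = gi
        self.context = ContextState("normal", context_id)
        return self

    def set_pfc_inactivated(self) -> "Network":
        """Remove the top-down bias: every DG cell at normal excitability."""
        self.params["DG"].gi_bar = np.full(self.cfg.dg_size, self.cfg.gi_bar_normal)
        self.context = ContextState("pfc_inactivated", None)
        return self

    def lesion(self, pathway: str) -> "Network":
        self.projections[pathway].lesioned = True
        return self

    # -- engine internals ---------------------------------------------------

    def _invalidate(self) -> None:
        self._w_norm_cache.clear()

    def _w_norm(self, proj: Projection) -> np.ndarray:
        """Weights divided by the per-receiver expected-active-input count."""
        cached = self._w_norm_cache.get(proj.name)
        if cached is None:
            cached = (proj.effective_w() / proj.recv_norm).astype(DTYPE)
            self._w_norm_cache[proj.name] = cached
        return cached

    def _refresh_w_norm(self, proj: Projection) -> None:
        """Refresh only the receiver columns touched by the last weight update."""
        cached = self._w_norm_cache.get(proj.name)
        cols = getattr(proj, "last_update_cols", None)
        if cached is None or cols is None:
            self._w_norm_cache.pop(proj.name, None)
            return
        if cols.size:
            norm = proj.recv_norm[cols] if np.ndim(proj.recv_norm) else proj.recv_norm
            cached[:, cols] = (proj.effective_w(cols) / norm).astype(DTYPE)

    def _phase_drives(self, phase: int) -> dict[str, list[tuple[str, float, np.ndarray]]]:
        """For each receiving layer: (sender, scale, normalized weights) triples."""
        incoming: dict[str, list[Projection]] = {}
        for proj in self.projections.values():
            if proj.active_in(phase):
                incoming.setdefault(proj.dst, []).append(proj)
        out: dict[str, list[tuple[str, float, np.ndarray]]] = {}
        for dst, projs in incoming.items():
            r_total = sum(p.r for p in projs)
            out[dst] = [
                (p.src, (p.r / r_total) * p.a, self._w_norm(p)) for p in projs
            ]
        return out

    def _settle_phase(self, phase: int, n_steps: int, free_layers: tuple[str, ...]) -> None:
        # Inlined, allocation-light equivalent of netcore.settle over many
        # layers at once; exploits the sparsity of sender activity (a handful
        # of active cells per layer) by multiplying only the active rows.
        drives = self._phase_drives(phase)
        states, params = self.states, self.params
        noise_sd = self.cfg.vm_noise_sd
        rank_per_unit = self.cfg.kwta_rank_per_unit_gi
        consts = {}
        for name in free_layers:
            p = params[name]
            k = p.k
            consts[name] = (
                p,
                p.ge_bar * (p.Ee - p.theta),  # ge -> g_theta slope
                p.gl_bar * (p.El - p.theta),  # g_theta offset
                p.theta - p.Ei,
                p.size - k - 1,
                p.size - k,
            )
        noise = {}
        gi_bar32 = {}
        for name in free_layers:
            gi_bar32[name] = params[name].gi_bar.astype(DTYPE)
            if noise_sd > 0.0:
                noise[name] = noise_sd * self.noise_rng.standard_normal(
                    (n_steps, params[name].size), dtype=DTYPE
                )
            else:
                noise[name] = np.zeros((1, params[name].size), dtype=DTYPE)
        use_noise = noise_sd > 0.0
        for step in range(n_steps):
            for name in free_layers:
                p, c_e, c_l, c_d, i_k1, i_k = consts[name]
                st = states[name]
                ge = np.zeros(p.size, dtype=DTYPE)
                for src, scale, w_norm in drives.get(name, ()):
                    y = states[src].y
                    idx = np.flatnonzero(y)
                    if idx.size == 0:
                        continue
                    if 3 * idx.size < y.size:
                        ge += scale * (y[idx] @ w_norm[idx])
                    else:
                        ge += scale * (y @ w_norm)
                if HAVE_NUMBA:
                    gi = _step_layer(
                        st.Vm, st.y, ge, gi_bar32[name],
                        noise[name][step if use_noise else 0], use_noise,
                        rank_per_unit, c_e, c_l, c_d, p.k, p.q,
                        p.gl_bar, p.ge_bar, p.El, p.Ee, p.Ei,
                        p.theta, p.gamma, p.tau,
                    )
                else:
                    g_theta = (ge * c_e + c_l) / c_d
                    if rank_per_unit:
                        g_theta = g_theta / p.gi_bar
                    part = np.partition(g_theta, i_k1)
                    gi = part[i_k1] + p.q * (part[i_k:].min() - part[i_k1])
                    if gi < 0.0:
                        gi = 0.0
                    g_exc = ge * p.ge_bar
                    g_inh = gi * gi_bar32[name]
                    g_tot = p.gl_bar + g_exc + g_inh
                    v_inf = (p.gl_bar * p.El + g_exc * p.Ee + g_inh * p.Ei) / g_tot
                    st.Vm = v_inf + (st.Vm - v_inf) * np.exp(-p.tau * g_tot)
                    if use_noise:
                        st.Vm = st.Vm + noise[name][step]
                    chi = p.gamma * np.maximum(st.Vm - p.theta, 0.0)
                    st.y = chi / (1.0 + chi)
                st.ge, st.gi = ge, float(gi)

    # -- the trial ----------------------------------------------------------

    def run_trial(self, trial: TrialInput, learn: bool = True) -> TrialResult:
        """Run one trial through the theta phases; see module docstring.

        Encoding trials run all three phases and (if ``learn``) update every
        adaptable pathway at the end of the plus phase.  Test trials run only
        the two minus halves with learning off.  The recalled reward pattern is
        the third ECout field at the end of the second minus half.
        """
        cfg = self.cfg
        if self.context.mode == "normal" and self.context.active_context is None:
            raise RuntimeError("context must be set before running a trial in normal mode")

        fs = cfg.field_size
        r_in = trial.r_target if trial.mode == "encode" else np.zeros(fs)
        ecin_pattern = np.concatenate([trial.x_pattern, trial.y_pattern, r_in]).astype(DTYPE)
        target_full = np.concatenate(
            [trial.x_pattern, trial.y_pattern, trial.r_target]
        ).astype(DTYPE)

        # trial start: every layer reset, ECin clamped throughout
        for name in LAYERS:
            st = self.states[name]
            st.unclamp()
            if st.Vm.dtype != DTYPE:
                st.Vm = st.Vm.astype(DTYPE)
                st.y = st.y.astype(DTYPE)
                st.ge = st.ge.astype(DTYPE)
            st.reset(self.params[name])
        self.states["ECin"].clamp(ecin_pattern)

        snaps = PhaseSnapshots()
        n = cfg.phase_steps
        free = ("DG", "CA3", "CA1", "ECout")

        # phase 1: first minus half (monosynaptic encoding, CA3 recall blocked)
        self.states["CA1"].reset(self.params["CA1"])
        self._settle_phase(1, n, free)
        snaps.y_minus1 = {name: self.states[name].y.copy() for name in LAYERS}

        # phase 2: second minus half (trisynaptic recall)
        self.states["CA1"].reset(self.params["CA1"])
        self._settle_phase(2, n, free)
        snaps.y_minus2 = {name: self.states[name].y.copy() for name in LAYERS}
        r_out = self.states["ECout"].y[2 * fs: 3 * fs].copy()
        dg_y = self.states["DG"].y
        dg_active_units = np.flatnonzero(dg_y > 0.0)

        if trial.mode == "encode":
            # phase 3: plus phase with ECout clamped to the full target
            self.states["CA1"].reset(self.params["CA1"])
            self.states["ECout"].clamp(target_full)
            self._settle_phase(3, n, ("DG", "CA3", "CA1"))
            snaps.y_plus = {name: self.states[name].y.copy() for name in LAYERS}
            self.states["ECout"].unclamp()
            if learn:
                for proj in self.projections.values():
                    if not proj.lesioned:
                        apply_update(proj, snaps)
                        self._refresh_w_norm(proj)

        return TrialResult(
            snapshots=snaps,
            r_out=r_out,
            dg_active=int(dg_active_units.size),
            dg_active_units=dg_active_units,
        )

    # -- persistence --------------------------------------------------------

    def copy(self) -> "Network":
        net = Network(self.cfg, copy.deepcopy(self.params), copy.deepcopy(self.projections), self.seed)
        net.context = copy.deepcopy(self.context)
        return net


def _sample_mask(
    spec: PathwaySpec, n_src: int, n_dst: int, rng: np.random.Generator
) -> np.ndarray:
    if spec.p is None:
        return np.ones((n_src, n_dst), dtype=np.uint8)
    if spec.p == "one_to_one":
        if n_src != n_dst:
            raise ValueError(f"one-to-one pathway {spec.name} requires equal layer sizes")
        return np.eye(n_src, dtype=np.uint8)
    if not (0.0 <= spec.p <= 1.0):
        raise ValueError(f"connection probability {spec.p} outside [0, 1]")
    return (rng.random((n_src, n_dst)) < spec.p).astype(np.uint8)


def build_network(cfg: NetworkConfig, seed: int | np.random.SeedSequence) -> Network:
    """Assemble layers and pathways; sample masks and initial weights."""
    rng = np.random.default_rng(seed)
    params = cfg.layer_params()
    sizes = {name: p.size for name, p in params.items()}
    fracs = {name: p.kwta_frac for name, p in params.items()}

    projections: dict[str, Projection] = {}
    for spec in default_pathways(cfg.full_trisynaptic_gate):
        mask = _sample_mask(spec, sizes[spec.src], sizes[spec.dst], rng)
        if spec.name in ("ECin->DG", "ECin->CA3") and len(cfg.pp_fields) < cfg.n_fields:
            keep = np.zeros(sizes["ECin"], dtype=bool)
            for f in cfg.pp_fields:
                keep[f * cfg.field_size: (f + 1) * cfg.field_size] = True
            mask[~keep, :] = 0
        # initial weights are uniform on [0.25, 0.75] on the effective
        # (contrast) scale; store the sigmoid preimage
        w = inverse_contrast(init_weights(mask, rng), cfg.wt_sig_gain, cfg.wt_sig_off)
        fan_in = np.maximum(mask.sum(axis=0), 1).astype(float)
        recv_norm = fan_in * fracs[spec.src]
        eps = cfg.epsilon_hebb if spec.k_hebb == 1.0 else cfg.epsilon_err
        projections[spec.name] = Projection(
            name=spec.name,
            src=spec.src,
            dst=spec.dst,
            w=w,
            mask=mask,
            r=spec.r,
            a=spec.a,
            k_hebb=spec.k_hebb,
            epsilon=eps,
            minus_phase=spec.minus_phase,
            gated_phases=spec.gated_phases,
            recv_norm=recv_norm,
            wt_sig_gain=cfg.wt_sig_gain,
            wt_sig_off=cfg.wt_sig_off,
            hebb_qm=(
                max(1.0, cfg.hebb_savg_cor / fracs[spec.src])
                if cfg.hebb_savg_cor > 0
                else 1.0
            ),
            hebb_depress=cfg.hebb_depress,
        )
    seed_repr = seed.entropy if isinstance(seed, np.random.SeedSequence) else seed
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    noise_seed = ss.spawn(1)[0]
    return Network(cfg, params, projections, seed=seed_repr, noise_seed=noise_seed)


def set_context(net: Network, context_id: str) -> Network:
    return net.set_context(context_id)


def set_pfc_inactivated(net: Network) -> Network:
    return net.set_pfc_inactivated()


def run_trial(net: Network, trial: TrialInput, learn: bool = True) -> TrialResult:
    return net.run_trial(trial, learn=learn)
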