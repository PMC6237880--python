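"""Rate-coded point-neuron dynamics with shunting inhibition and kWTA competition.

One layer of the entorhinal-hippocampal circuit is a population of rate-coded
point neurons.  Each cell's membrane potential obeys shunting (conductance
based) dynamics on a normalized 0-1 voltage scale,

    dVm/dt = tau * [ gl_bar (El - Vm) + ge ge_bar (Ee - Vm) + gi gi_bar (Ei - Vm) ],

integrated by forward Euler with a fixed 1-ms step.  ``ge`` is the net
excitatory synaptic drive a cell receives from projections (``net_excitation``)
and ``gi`` is a single layer-wide inhibitory drive chosen every step so that
only roughly the top-k driven cells can sit above the firing threshold
(k-winners-take-all, ``kwta_inhibition``).  Output activity is a saturating
half-wave rectifier of the potential (``activation``).

The per-unit ``gi_bar`` vector is the hook for top-down contextual control:
raising a cell's maximal inhibitory conductance (e.g. from 1 to 5) makes the
shared kWTA inhibition hit it five times harder, silencing it without touching
the competition among the remaining cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LayerParams",
    "LayerState",
    "activation",
    "step_vm",
    "vm_fixed_point",
    "net_excitation",
    "kwta_thresholds",
    "kwta_inhibition",
    "settle",
]


@dataclass
class LayerParams:
    """Conductance and competition parameters for one cell population.

    Defaults are the standard parameter set shared by every region; only
    ``kwta_frac`` (and, for DG, the per-unit ``gi_bar``) differ between layers.
    """

    size: int
    kwta_frac: float
    gl_bar: float = 0.1
    ge_bar: float = 1.0
    El: float = 0.3
    Ee: float = 1.0
    Ei: float = 0.25
    Vrest: float = 0.3
    gamma: float = 100.0
    theta: float = 0.5
    q: float = 0.25
    tau: float = 0.3
    gi_bar: np.ndarray | None = None  # per-unit; defaults to ones

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("layer size must be >= 1")
        if not (0.0 < self.kwta_frac <= 1.0):
            raise ValueError("kwta_frac must lie in (0, 1]")
        if not (0.0 < self.q < 1.0):
            raise ValueError("q must lie in (0, 1)")
        if not (self.Ei < self.theta < self.Ee):
            raise ValueError("require Ei < theta < Ee")
        if self.gi_bar is None:
            self.gi_bar = np.ones(self.size)
        else:
            self.gi_bar = np.asarray(self.gi_bar, dtype=float)
            if self.gi_bar.shape != (self.size,):
                raise ValueError("gi_bar must have one value per cell")
            if np.any(self.gi_bar <= 0):
                raise ValueError("gi_bar must be positive elementwise")

    @property
    def k(self) -> int:
        """Number of winners the kWTA rule aims to keep active."""
        return max(1, int(round(self.kwta_frac * self.size)))


@dataclass
class LayerState:
    """Evolving state of one layer: potentials, activities, drives, clamp."""

    Vm: np.ndarray
    y: np.ndarray
    ge: np.ndarray
    gi: float = 0.0
    clamp_values: np.ndarray | None = None

    @classmethod
    def resting(cls, params: LayerParams) -> "LayerState":
        n = params.size
        return cls(
            Vm=np.full(n, params.Vrest),
            y=np.zeros(n),
            ge=np.zeros(n),
        )

    @property
    def clamped(self) -> bool:
        return self.clamp_values is not None

    def clamp(self, values: np.ndarray) -> None:
        """Hard-clamp output activity to an external pattern (Vm is ignored)."""
        self.clamp_values = np.asarray(values, dtype=float)
        self.y = self.clamp_values.copy()

    def unclamp(self) -> None:
        self.clamp_values = None

    def reset(self, params: LayerParams) -> None:
        self.Vm.fill(params.Vrest)
        self.ge.fill(0.0)
        self.gi = 0.0
        if not self.clamped:
            self.y.fill(0.0)


def activation(Vm: np.ndarray, gamma: float, theta: float) -> np.ndarray:
    """Saturating rectified activation y = chi / (1 + chi), chi = gamma*[Vm - theta]+.

    Zero at and below threshold, monotone in Vm, bounded in [0, 1).
    """
    chi = gamma * np.maximum(np.asarray(Vm) - theta, 0.0)
    return chi / (1.0 + chi)


def step_vm(
    Vm: np.ndarray,
    ge: np.ndarray,
    gi: float,
    params: LayerParams,
) -> np.ndarray:
    """One 1-ms integration step of the shunting membrane equation.

    For conductances held fixed over the step the equation is linear in Vm, so
    the step is integrated exactly (exponential Euler):

        Vm' = V_inf + (Vm - V_inf) * exp(-tau * g_tot),

    with ``g_tot = gl_bar + ge*ge_bar + gi*gi_bar`` and ``V_inf`` the
    conductance-weighted equilibrium.  This agrees with forward Euler to first
    order in ``tau * g_tot`` but remains stable for the strong mossy-fiber
    drives and raised contextual inhibition, where forward Euler's step factor
    exceeds its stability bound.  ``gi`` is the shared layer inhibition; each
    cell scales it by its own ``gi_bar``.  Raises on non-finite conductances.
    """
    ge = np.asarray(ge)
    if not np.all(np.isfinite(ge)) or not np.isfinite(gi):
        raise ValueError("non-finite synaptic conductance")
    p = params
    g_exc = ge * p.ge_bar
    g_inh = gi * p.gi_bar
    g_tot = p.gl_bar + g_exc + g_inh
    v_inf = (p.gl_bar * p.El + g_exc * p.Ee + g_inh * p.Ei) / g_tot
    return v_inf + (Vm - v_inf) * np.exp(-p.tau * g_tot)


def vm_fixed_point(ge: np.ndarray, gi: float, params: LayerParams) -> np.ndarray:
    """Closed-form equilibrium of the membrane equation for constant drives."""
    p = params
    num = p.gl_bar * p.El + ge * p.ge_bar * p.Ee + gi * p.gi_bar * p.Ei
    den = p.gl_bar + ge * p.ge_bar + gi * p.gi_bar
    return num / den


def net_excitation(incoming: list) -> np.ndarray:
    """Net excitatory drive from a list of ``(sender activities, projection)``.

    Each projection contributes ``(r_j / sum_k r_k) * a_j * <x . w>_j`` where
    ``<x . w>_j`` is the summed drive through the projection's weights divided
    by the expected number of active inputs (fan-in times the sender layer's
    activity fraction), so ge stays on the 0-1 conductance scale regardless of
    fan-in and sender sparsity.  Projections must expose ``w`` (masked
    weights), ``r``, ``a`` and ``recv_norm`` (the per-unit divisor).
    """
    if not incoming:
        raise ValueError("no incoming projections")
    r_total = sum(proj.r for _, proj in incoming)
    if r_total == 0:
        raise ValueError("relative weights sum to zero")
    ge = None
    for x, proj in incoming:
        x = np.asarray(x, dtype=float)
        if x.shape[0] != proj.w.shape[0]:
            raise ValueError(
                f"sender length {x.shape[0]} != projection rows {proj.w.shape[0]}"
            )
        w = proj.effective_w() if hasattr(proj, "effective_w") else proj.w
        drive = (proj.r / r_total) * proj.a * (x @ w) / proj.recv_norm
        ge = drive if ge is None else ge + drive
    return ge


def kwta_thresholds(
    ge: np.ndarray, params: LayerParams, per_unit_gi_bar: bool = False
) -> np.ndarray:
    """Per-unit threshold inhibition: the gi that would put the cell exactly at theta.

    g_theta = [ge*ge_bar*(Ee - theta) + gl_bar*(El - theta)] / (theta - Ei).

    With ``per_unit_gi_bar`` the threshold additionally divides by each cell's
    own maximal inhibitory conductance, since a cell with a raised gi_bar
    reaches threshold at a proportionally lower shared inhibition level.  For a
    uniform gi_bar of 1 the two forms coincide.
    """
    p = params
    denom = p.theta - p.Ei
    if denom == 0:
        raise ZeroDivisionError("theta equals Ei")
    g_theta = (
        np.asarray(ge) * p.ge_bar * (p.Ee - p.theta) + p.gl_bar * (p.El - p.theta)
    ) / denom
    if per_unit_gi_bar:
        g_theta = g_theta / p.gi_bar
    return g_theta


def kwta_inhibition(
    ge: np.ndarray, params: LayerParams, per_unit_gi_bar: bool = False
) -> float:
    """Shared layer inhibition placed between the kth and (k+1)th threshold.

    gi = g_theta(k+1) + q * (g_theta(k) - g_theta(k+1)); with distinct drives
    exactly k cells have suprathreshold equilibria.  A cell whose threshold
    equals gi exactly is subthreshold (conservative tie-break).  By default the
    ranking ignores per-unit gi_bar differences (the printed form of the rule);
    with ``per_unit_gi_bar`` each cell competes at its actual excitability,
    which hands every competition slot to the facilitated ensemble.
    """
    k = params.k
    n = params.size
    if n < k + 1:
        raise ValueError(f"layer of size {n} cannot rank k+1 = {k + 1} thresholds")
    g_theta = kwta_thresholds(ge, params, per_unit_gi_bar=per_unit_gi_bar)
    # kth and (k+1)th largest via partial sort: part[n-k:] holds the k largest
    part = np.partition(g_theta, n - k - 1)
    g_k1 = part[n - k - 1]
    g_k = part[n - k:].min()
    return float(g_k1 + params.q * (g_k - g_k1))


def settle(
    state: LayerState,
    params: LayerParams,
    incoming: list,
    n_steps: int = 30,
) -> LayerState:
    """Iterate net_excitation -> kWTA -> Euler -> activation for a fixed budget.

    Sender activities in ``incoming`` are held constant; clamped layers bypass
    the dynamics entirely and output their clamp pattern.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if state.clamped:
        state.y = state.clamp_values.copy()
        return state
    for _ in range(n_steps):
        state.ge = net_excitation(incoming) if incoming else np.zeros(params.size)
        state.gi = max(0.0, kwta_inhibition(state.ge, params))
        state.Vm = step_vm(state.Vm, state.ge, state.gi, params)
        state.y = activation(state.Vm, params.gamma, params.theta)
    return state
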