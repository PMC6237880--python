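"""Synaptic pathways: weight init and mixed Hebbian / contrastive-Hebbian updates.

A :class:`Projection` is one inter-region pathway: a [0, 1]-bounded weight
matrix under a fixed binary connectivity mask, with a relative weight ``r`` and
absolute scale ``a`` that set its share of the receiver's net excitation, and a
learning mix ``k_hebb`` blending two rules applied at the end of each encoding
trial's plus phase:

* Hebbian (self-bounding):      dw = y+ * (x+ - w)
* error-driven (CHL):           dw = x+ y+ - x- y-

where +/- are activities snapshotted at the end of the plus phase and of the
pathway's designated minus half-phase.  The error-driven term is soft-bounded
(positive changes scaled by 1-w, negative by w) and the result clipped to
[0, 1] as a safety net; the Hebbian rule is self-bounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "Projection",
    "PhaseSnapshots",
    "init_weights",
    "hebbian_delta",
    "errdriven_delta",
    "apply_update",
    "save_projections",
    "load_projections",
]


def init_weights(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Initial weights: present connections i.i.d. uniform on [0.25, 0.75].

    The interval has mean 0.5 and half-range 0.25; absent connections are zero.
    """
    mask = np.asarray(mask)
    w = rng.uniform(0.25, 0.75, size=mask.shape)
    return np.where(mask > 0, w, 0.0)


def contrast(w: np.ndarray, gain: float, off: float) -> np.ndarray:
    """Sigmoidal contrast enhancement w -> 1 / (1 + (off*(1-w)/w)**gain)."""
    if gain <= 0.0:
        return w
    out = np.zeros_like(w)
    pos = w > 0.0
    full = w >= 1.0
    mid = pos & ~full
    ratio = off * (1.0 - w[mid]) / w[mid]
    out[mid] = 1.0 / (1.0 + ratio ** gain)
    out[full] = 1.0
    return out


def inverse_contrast(w_eff: np.ndarray, gain: float, off: float) -> np.ndarray:
    """Map effective (contrast-scale) weights back to linear storage weights.

    Companion of :meth:`Projection.effective_w`: initial weights are sampled
    on the effective scale, so the stored linear weights are its sigmoid
    preimage, keeping the initial drive distribution identical with and
    without contrast enhancement.
    """
    if gain <= 0.0:
        return w_eff
    out = np.zeros_like(w_eff)
    pos = w_eff > 0.0
    ratio = (1.0 / w_eff[pos] - 1.0) ** (1.0 / gain)
    out[pos] = off / (off + ratio)
    return out


@dataclass
class Projection:
    """One pathway between two layers.

    ``w[h, i]`` is the weight from sender cell h to receiver cell i.
    ``minus_phase`` names which minus half-phase (1 or 2) supplies the (x-, y-)
    snapshot for the error-driven rule.  ``gated_phases`` lists theta phases in
    which this pathway's drive is multiplicatively gated to zero.
    ``recv_norm`` is the per-receiver divisor used by the net-input rule:
    fan-in times the sender layer's expected activity fraction.
    """

    name: str
    src: str
    dst: str
    w: np.ndarray
    mask: np.ndarray
    r: float = 1.0
    a: float = 1.0
    k_hebb: float = 1.0
    epsilon: float = 0.1
    minus_phase: int = 2
    gated_phases: tuple[int, ...] = ()
    recv_norm: np.ndarray | float = 1.0
    lesioned: bool = False
    # sigmoidal contrast enhancement of the weights used for net input
    # (learning always operates on the linear weights); gain 0 disables it
    wt_sig_gain: float = 0.0
    wt_sig_off: float = 1.25
    hebb_qm: float = 1.0  # CPCA sender-average correction; 1 = plain rule
    hebb_depress: float = 1.0  # scale on the Hebbian depression term; 1 = plain rule

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.mask = np.asarray(self.mask)
        if self.w.shape != self.mask.shape:
            raise ValueError("weight and mask shapes differ")
        if not (0.0 <= self.k_hebb <= 1.0):
            raise ValueError("k_hebb must lie in [0, 1]")
        if self.minus_phase not in (1, 2):
            raise ValueError("minus_phase must be 1 or 2")

    @property
    def n_connections(self) -> int:
        return int(np.count_nonzero(self.mask))

    def effective_w(self, cols: np.ndarray | None = None) -> np.ndarray:
        """Weights as seen by the net-input rule (optionally selected columns).

        With contrast enhancement on, a learned weight above the midpoint is
        amplified toward 1 and an untrained mid-range weight compressed toward
        0, so that Hebbian learning (whose fixed point is the sender activity,
        typically 0.5-0.9) produces drives that stand clear of the initial
        random weights:  w_eff = 1 / (1 + (off * (1 - w) / w) ** gain).
        """
        w = self.w if cols is None else self.w[:, cols]
        if self.wt_sig_gain <= 0.0:
            return w.copy() if cols is not None else w
        return contrast(w, self.wt_sig_gain, self.wt_sig_off)

    def active_in(self, phase: int) -> bool:
        return (not self.lesioned) and phase not in self.gated_phases


@dataclass
class PhaseSnapshots:
    """Per-layer activity vectors captured at the end of each theta phase."""

    y_minus1: dict[str, np.ndarray] = field(default_factory=dict)
    y_minus2: dict[str, np.ndarray] = field(default_factory=dict)
    y_plus: dict[str, np.ndarray] = field(default_factory=dict)

    def minus(self, phase: int) -> dict[str, np.ndarray]:
        return self.y_minus1 if phase == 1 else self.y_minus2


def hebbian_delta(
    x_plus: np.ndarray,
    y_plus: np.ndarray,
    w: np.ndarray,
    qm: float = 1.0,
) -> np.ndarray:
    """Hebbian update dw = y+ * [qm * x+ * (1 - w) - (1 - x+) * w].

    At ``qm = 1`` this is algebraically identical to the plain self-bounding
    rule dw = y+ * (x+ - w).  ``qm > 1`` is the conditional-PCA sender-average
    correction: with sparse senders the potentiation component is boosted by
    roughly (0.5 / sender activity fraction) so that reliably co-active pairs
    saturate near 1 instead of at the sender amplitude, and occasional
    depression from conflicting patterns cannot erase a learned association.
    """
    x = x_plus[:, None]
    return y_plus[None, :] * (qm * x * (1.0 - w) - (1.0 - x) * w)


def errdriven_delta(
    x_plus: np.ndarray,
    y_plus: np.ndarray,
    x_minus: np.ndarray,
    y_minus: np.ndarray,
) -> np.ndarray:
    """Contrastive Hebbian term dw = x+ y+ - x- y- (before soft bounding)."""
    return np.outer(x_plus, y_plus) - np.outer(x_minus, y_minus)


def apply_update(proj: Projection, snaps: PhaseSnapshots) -> Projection:
    """End-of-plus-phase weight update for one pathway (in place).

    dw = eps * [k_hebb * dw_hebb + (1 - k_hebb) * soft_bound(dw_err)], with the
    error term's positive part scaled by (1 - w) and negative part by w, then
    clipped to [0, 1].  Masked-out entries are untouched.
    """
    if proj.src not in snaps.y_plus or proj.dst not in snaps.y_plus:
        raise KeyError(f"missing plus-phase snapshot for {proj.name}")
    x_plus = snaps.y_plus[proj.src]
    y_plus = snaps.y_plus[proj.dst]
    if proj.k_hebb < 1.0:
        minus = snaps.minus(proj.minus_phase)
        if proj.src not in minus or proj.dst not in minus:
            raise KeyError(f"missing minus-phase snapshot for {proj.name}")
        x_minus, y_minus = minus[proj.src], minus[proj.dst]
        active = (y_plus > 0) | (y_minus > 0)
    else:
        x_minus = y_minus = None
        active = y_plus > 0
    # both rules leave columns with silent receivers untouched, so restrict
    # the dense arithmetic to the active receiver columns
    cols = np.flatnonzero(active)
    proj.last_update_cols = cols
    if cols.size == 0:
        return proj
    w = proj.w[:, cols]
    yp = y_plus[cols]
    delta = np.zeros_like(w)
    if proj.k_hebb > 0.0:
        xp = x_plus[:, None]
        delta += proj.k_hebb * (
            yp[None, :]
            * (proj.hebb_qm * xp * (1.0 - w) - proj.hebb_depress * (1.0 - xp) * w)
        )
    if proj.k_hebb < 1.0:
        err = np.outer(x_plus, yp) - np.outer(x_minus, y_minus[cols])
        bounded = np.where(err > 0, err * (1.0 - w), err * w)
        delta += (1.0 - proj.k_hebb) * bounded
    w += proj.epsilon * delta
    np.clip(w, 0.0, 1.0, out=w)
    w[proj.mask[:, cols] == 0] = 0.0
    proj.w[:, cols] = w
    proj.last_update_cols = cols
    return proj


def save_projections(path: str, projections: dict[str, Projection], meta: dict | None = None) -> None:
    """Save weight matrices + masks to HDF5, keyed by pathway name."""
    with h5py.File(path, "w") as f:
        if meta:
            for key, val in meta.items():
                f.attrs[key] = val
        for name, proj in projections.items():
            grp = f.create_group(name)
            grp.create_dataset("w", data=proj.w)
            grp.create_dataset("mask", data=proj.mask.astype(np.uint8))
            grp.attrs.update(
                src=proj.src, dst=proj.dst, r=proj.r, a=proj.a,
                k_hebb=proj.k_hebb, epsilon=proj.epsilon,
                minus_phase=proj.minus_phase,
            )


def load_projections(path: str) -> dict[str, Projection]:
    """Inverse of :func:`save_projections` (recv_norm/gating restored by the circuit)."""
    out: dict[str, Projection] = {}
    with h5py.File(path, "r") as f:
        for name, grp in f.items():
            out[name] = Projection(
                name=name,
                src=str(grp.attrs["src"]),
                dst=str(grp.attrs["dst"]),
                w=grp["w"][()],
                mask=grp["mask"][()],
                r=float(grp.attrs["r"]),
                a=float(grp.attrs["a"]),
                k_hebb=float(grp.attrs["k_hebb"]),
                epsilon=float(grp.attrs["epsilon"]),
                minus_phase=int(grp.attrs["minus_phase"]),
            )
    return out
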