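"""Three-choice Q-learning model family for progressive-ratio lever pressing.

Mice in a progressive-ratio (PR) lever-press session distribute their behavior
over three discrete choices: pressing the reinforced *active* lever (ALP),
poking the food magazine before the ratio is complete (MNP, a "void" reward
check), and pressing the non-reinforced *inactive* lever (ILP).  This module
defines that action space and four nested Q-learning variants:

``SIMPLEQ``
    A single learning rate ``alpha``; values updated as
    ``Q[a] += alpha * (r - Q[a])`` for the chosen action ``a``.
``ASYMMETRY``
    Separate learning rates ``alpha_pos`` / ``alpha_neg`` for positive and
    negative reward prediction errors (RPEs).
``PERSEVERANCE``
    SimpleQ plus an exponentially decaying choice trace ``C[a]`` per action
    (decay rate ``tau``), entering the softmax with per-action weights
    ``phi[a]``; positive ``phi`` produces repetition, negative avoidance.
``NOLEARN``
    The perseverance model with the learning rate pinned to zero.

Action selection is softmax over logits ``beta * Q[a] + phi[a] * C[a]``
(trace term absent for SimpleQ/asymmetry).  Initial action values ``q0`` are
free parameters — operant pretraining leaves animals with pre-existing
preferences, so pinning ``Q0`` to zero is wrong for this task.

The functions here are the readable reference implementation; the optimizer
uses an equivalent compiled kernel (:mod:`prtrace._fast`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum, IntEnum

import numpy as np

__all__ = [
    "Action",
    "ModelKind",
    "ParamSet",
    "AgentState",
    "Outcome",
    "ParameterError",
    "init_state",
    "action_probabilities",
    "update",
    "effective_alpha",
    "validate_params",
]


class Action(IntEnum):
    """The three behavioral choices. A reward delivery is an outcome event,
    not an action, and is deliberately absent from this enum."""

    ALP = 0  # active (reinforced) lever press
    MNP = 1  # magazine nosepoke
    ILP = 2  # inactive lever press


ACTION_NAMES = ("ALP", "MNP", "ILP")


class ModelKind(str, Enum):
    SIMPLEQ = "simpleq"
    ASYMMETRY = "asymmetry"
    PERSEVERANCE = "perseverance"
    NOLEARN = "nolearn"

    @property
    def has_trace(self) -> bool:
        return self in (ModelKind.PERSEVERANCE, ModelKind.NOLEARN)


class ParameterError(ValueError):
    """Raised when a ParamSet is invalid for the requested model kind."""


def _triple(x, name: str) -> tuple[float, float, float]:
    arr = tuple(float(v) for v in np.atleast_1d(np.asarray(x, dtype=float)).ravel())
    if len(arr) != 3:
        raise ParameterError(f"{name} must have exactly 3 entries (ALP, MNP, ILP), got {len(arr)}")
    return arr  # type: ignore[return-value]


@dataclass(frozen=True)
class ParamSet:
    """Free parameters of one model variant, on the natural scale.

    Fields irrelevant to a given :class:`ModelKind` may be left ``None``.
    ``q0`` and ``phi`` are ordered (ALP, MNP, ILP).
    """

    beta: float = 1.0
    q0: tuple[float, float, float] = (0.0, 0.0, 0.0)
    alpha: float | None = None
    alpha_pos: float | None = None
    alpha_neg: float | None = None
    tau: float | None = None
    phi: tuple[float, float, float] | None = None

    def __post_init__(self):
        object.__setattr__(self, "q0", _triple(self.q0, "q0"))
        if self.phi is not None:
            object.__setattr__(self, "phi", _triple(self.phi, "phi"))

    # -- serialization: flat JSON mapping, absent keys = not applicable -----
    def to_dict(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for key in ("alpha", "alpha_pos", "alpha_neg", "beta", "tau"):
            val = getattr(self, key)
            if val is not None:
                out[key] = float(val)
        for i, a in enumerate(ACTION_NAMES):
            out[f"q0_{a}"] = float(self.q0[i])
        if self.phi is not None:
            for i, a in enumerate(ACTION_NAMES):
                out[f"phi_{a}"] = float(self.phi[i])
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ParamSet":
        q0 = tuple(float(d[f"q0_{a}"]) for a in ACTION_NAMES) if "q0_ALP" in d else (0.0, 0.0, 0.0)
        phi = None
        if "phi_ALP" in d:
            phi = tuple(float(d[f"phi_{a}"]) for a in ACTION_NAMES)
        return cls(
            beta=float(d.get("beta", 1.0)),
            q0=q0,  # type: ignore[arg-type]
            alpha=None if d.get("alpha") is None else float(d["alpha"]),
            alpha_pos=None if d.get("alpha_pos") is None else float(d["alpha_pos"]),
            alpha_neg=None if d.get("alpha_neg") is None else float(d["alpha_neg"]),
            tau=None if d.get("tau") is None else float(d["tau"]),
            phi=phi,  # type: ignore[arg-type]
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "ParamSet":
        return cls.from_dict(json.loads(s))


def validate_params(params: ParamSet, kind: ModelKind) -> None:
    """Check that `params` is a valid parameter set for `kind`.

    Raises :class:`ParameterError` with the offending field named.
    """
    def _need(name):
        if getattr(params, name) is None:
            raise ParameterError(f"{kind.value} model requires parameter '{name}'")

    if not np.isfinite(params.beta) or params.beta < 0:
        raise ParameterError(f"beta must be finite and >= 0, got {params.beta}")
    for i, v in enumerate(params.q0):
        if not np.isfinite(v) or not (-1.0 <= v <= 1.0):
            raise ParameterError(f"q0_{ACTION_NAMES[i]} must lie in [-1, 1], got {v}")

    if kind is ModelKind.SIMPLEQ or kind is ModelKind.PERSEVERANCE:
        _need("alpha")
        if not (0.0 <= params.alpha <= 1.0):
            raise ParameterError(f"alpha must lie in [0, 1], got {params.alpha}")
    if kind is ModelKind.ASYMMETRY:
        for name in ("alpha_pos", "alpha_neg"):
            _need(name)
            v = getattr(params, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
    if kind is ModelKind.NOLEARN and params.alpha not in (None, 0.0):
        raise ParameterError("nolearn model has alpha fixed at 0; do not set it")
    if kind.has_trace:
        _need("tau")
        if not (-1.0 <= params.tau <= 1.0):
            raise ParameterError(f"tau must lie in [-1, 1], got {params.tau}")
        _need("phi")
        for i, v in enumerate(params.phi):
            if not np.isfinite(v):
                raise ParameterError(f"phi_{ACTION_NAMES[i]} must be finite, got {v}")


@dataclass(frozen=True)
class Outcome:
    """Binary trial outcome: 1 for a food reward, 0 otherwise."""

    r: int

    def __post_init__(self):
        if self.r not in (0, 1):
            raise ValueError(f"outcome r must be 0 or 1, got {self.r}")


@dataclass
class AgentState:
    """Per-action values ``q``, choice traces ``c`` and the update counter.

    Traces start at zero and, for ``tau`` in [0, 1], remain in [0, 1].
    Models without a trace term keep ``c`` fixed at zero so that one replay
    engine serves all four variants.
    """

    q: np.ndarray
    c: np.ndarray
    step_index: int = 0

    def copy(self) -> "AgentState":
        return AgentState(self.q.copy(), self.c.copy(), self.step_index)


def init_state(params: ParamSet, kind: ModelKind = ModelKind.PERSEVERANCE) -> AgentState:
    """Initial agent state: ``q = q0`` and all choice traces zero."""
    validate_params(params, kind)
    return AgentState(q=np.asarray(params.q0, dtype=float), c=np.zeros(3), step_index=0)


def _logits(state: AgentState, params: ParamSet, kind: ModelKind) -> np.ndarray:
    z = params.beta * state.q
    if kind.has_trace:
        z = z + np.asarray(params.phi, dtype=float) * state.c
    return z


def action_probabilities(state: AgentState, params: ParamSet, kind: ModelKind) -> np.ndarray:
    """Softmax choice probabilities over (ALP, MNP, ILP).

    Computed in log space (max-subtraction) so the result is strictly
    positive and sums to one even for extreme logits.
    """
    z = _logits(state, params, kind)
    if not np.all(np.isfinite(z)):
        bad = "beta*q" if not np.all(np.isfinite(params.beta * state.q)) else "phi*c"
        raise ParameterError(f"non-finite softmax logits from the {bad} term: {z}")
    z = z - z.max()
    p = np.exp(z)
    return p / p.sum()


def effective_alpha(params: ParamSet, kind: ModelKind, rpe: float) -> float:
    """Learning rate actually applied for this update.

    Asymmetry uses ``alpha_pos`` for ``rpe >= 0`` (the tie at zero is inert:
    a zero RPE changes nothing either way) and ``alpha_neg`` otherwise.
    """
    if kind is ModelKind.NOLEARN:
        return 0.0
    if kind is ModelKind.ASYMMETRY:
        return params.alpha_pos if rpe >= 0 else params.alpha_neg
    return params.alpha


def update(
    state: AgentState,
    chosen: Action,
    outcome: Outcome,
    params: ParamSet,
    kind: ModelKind,
) -> tuple[AgentState, float]:
    """One value/trace update after taking `chosen` with result `outcome`.

    Returns the new state and the reward prediction error
    ``rpe = r - q[chosen]``.  Only the chosen action's value moves; for the
    trace models *all three* traces update,
    ``c[a] += tau * (1[a == chosen] - c[a])``, so unchosen traces decay
    toward zero.
    """
    chosen = Action(chosen)
    rpe = float(outcome.r) - float(state.q[chosen])
    new = state.copy()
    new.q[chosen] += effective_alpha(params, kind, rpe) * rpe
    if kind.has_trace:
        indicator = np.zeros(3)
        indicator[chosen] = 1.0
        new.c += params.tau * (indicator - new.c)
    new.step_index += 1
    return new, rpe
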