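"""Progressive-ratio / fixed-ratio schedule logic and the per-step task flow.

The PR schedule escalates the number of active-lever presses required per
reward as ``round(5 * exp(0.2 * R) - 5)`` where ``R`` counts the reinforcer
being worked for (rewards already earned plus one), giving the sequence
1, 2, 4, 6, 9, 12, 15, 20, 25, 32, 40, 50, 62, 77, 95, ...  The largest
ratio completed in a session is the *breakpoint*, the classical single-number
motivation index this package is built to look beyond.

``step_flow`` implements one step of the agent/task interaction shared by
replay and free-run simulation: if the current ratio is complete a reward is
delivered and credited to the magazine check (a forced MNP update with
``r = 1`` — collecting the pellet is a nosepoke, not a free choice);
otherwise the agent picks one of the three actions and its value is updated
with ``r = 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .models import (
    Action,
    AgentState,
    ModelKind,
    Outcome,
    ParamSet,
    action_probabilities,
    update,
)

__all__ = [
    "ScheduleConfig",
    "SessionConfig",
    "TaskState",
    "StepResult",
    "requirement",
    "breakpoint_of",
    "step_flow",
    "REWARD_CODE",
]

REWARD_CODE = 3  # event code for a reward delivery (0..2 are Action values)


@dataclass(frozen=True)
class ScheduleConfig:
    """Reinforcement schedule: progressive ratio (default) or fixed ratio."""

    kind: str = "PR"  # "PR" or "FR"
    fr_requirement: int = 1
    pr_coefficient: float = 5.0
    pr_rate: float = 0.2

    def __post_init__(self):
        if self.kind not in ("PR", "FR"):
            raise ValueError(f"schedule kind must be 'PR' or 'FR', got {self.kind!r}")
        if self.kind == "FR" and self.fr_requirement < 1:
            raise ValueError("fr_requirement must be a positive integer")


@dataclass(frozen=True)
class SessionConfig:
    """Session timing and termination rules.

    A session ends after ``max_duration_s`` (60 min), once ``max_rewards``
    (100) have been earned, or when no active-lever press occurs for
    ``inactivity_limit_s`` (5 min).  The inter-trial interval follows each
    reward with levers retracted; the refractory period is a post-press
    lockout.  Both affect only timestamps, never model dynamics, which are
    event-indexed.
    """

    iti_s: float = 30.0
    refractory_s: float = 0.5
    max_duration_s: float = 3600.0
    max_rewards: int = 100
    inactivity_limit_s: float = 300.0

    def __post_init__(self):
        for name in ("iti_s", "refractory_s", "max_duration_s", "inactivity_limit_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_rewards < 1:
            raise ValueError("max_rewards must be >= 1")


@dataclass
class TaskState:
    """Progress within a session: current trial, presses toward the current
    ratio, rewards earned so far, and the session clock."""

    trial_index: int = 1
    presses_this_trial: int = 0
    rewards_earned: int = 0
    elapsed_s: float = 0.0


def _round_half_away(x: float) -> int:
    # "rounded off" requirement: half-away-from-zero, e.g. 8.5 -> 9
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def requirement(reward_index: int, schedule: ScheduleConfig | None = None) -> int:
    """Lever presses required for the `reward_index`-th reinforcer (1-based).

    PR: ``round(5 * exp(0.2 * R) - 5)`` with round-half-away-from-zero,
    which reproduces the canonical 1, 2, 4, 6, 9, ... escalation (plain
    floor fails at R = 5 where 8.59 must round to 9).  FR: the fixed count.
    """
    if reward_index < 1:
        raise ValueError(f"reward_index must be >= 1, got {reward_index}")
    schedule = schedule or ScheduleConfig()
    if schedule.kind == "FR":
        return int(schedule.fr_requirement)
    return _round_half_away(
        schedule.pr_coefficient * math.exp(schedule.pr_rate * reward_index)
        - schedule.pr_coefficient
    )


def breakpoint_of(log, schedule: ScheduleConfig | None = None) -> int:
    """Breakpoint of a session: the final ratio completed.

    `log` is anything exposing integer event ``codes`` (an
    :class:`~prtrace.io.EventLog`).  Returns ``requirement(n_rewards)``, or
    0 for a session with no rewards.
    """
    codes = np.asarray(log.codes if hasattr(log, "codes") else log)
    n_rewards = int(np.sum(codes == REWARD_CODE))
    if n_rewards == 0:
        return 0
    return requirement(n_rewards, schedule)


@dataclass
class StepResult:
    event: int  # Action value or REWARD_CODE
    rpe: float
    probs: np.ndarray | None  # choice probabilities (None for reward steps)
    agent: AgentState
    task: TaskState


def step_flow(
    task: TaskState,
    agent: AgentState,
    params: ParamSet,
    kind: ModelKind,
    schedule: ScheduleConfig | None = None,
    rng: np.random.Generator | None = None,
    forced_choice: Action | None = None,
) -> StepResult:
    """Advance the agent/task loop by one event.

    If the pending ratio is complete, emit a REWARD event: the agent's MNP
    value and trace are updated with ``r = 1`` (no free choice, hence no
    likelihood term downstream), the reward counter and trial index advance
    and the press counter resets.  Otherwise a choice is made — sampled from
    the softmax policy via `rng`, or taken from `forced_choice` during
    replay — and updated with ``r = 0``; only an ALP advances the press
    counter.
    """
    schedule = schedule or ScheduleConfig()
    if task.presses_this_trial >= requirement(task.rewards_earned + 1, schedule):
        agent, rpe = update(agent, Action.MNP, Outcome(1), params, kind)
        task.rewards_earned += 1
        task.trial_index += 1
        task.presses_this_trial = 0
        return StepResult(REWARD_CODE, rpe, None, agent, task)

    probs = action_probabilities(agent, params, kind)
    if forced_choice is not None:
        chosen = Action(forced_choice)
    else:
        if rng is None:
            raise ValueError("step_flow needs an rng to sample a free choice")
        chosen = Action(rng.choice(3, p=probs))
    agent, rpe = update(agent, chosen, Outcome(0), params, kind)
    if chosen is Action.ALP:
        task.presses_this_trial += 1
    return StepResult(int(chosen), rpe, probs, agent, task)
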