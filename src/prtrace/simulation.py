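"""Generative free-run simulation, RPE trend extraction and parameter recovery.

A *free run* lets a model agent generate an entire PR session: choices are
sampled from its softmax policy, the task environment counts presses and
dispenses rewards, and timestamps are synthesized (lognormal inter-choice
intervals with median 0.9 s floored at the refractory period; the ITI after
each reward).  The run records everything needed for generative checks:
value/trace/probability trajectories and the RPE series.

Two RPE series matter scientifically.  At a reward the forced magazine
update gives ``rpe = 1 - Q[MNP]``; at a *void* magazine check it gives
``rpe = -Q[MNP]``.  Because ``Q[MNP]`` drifts down over a session under a
small positive learning rate (many unrewarded checks, few rewards), the
model predicts growing reward RPEs and shrinking magazine-dip RPEs — the
signature later sought in striatal dopamine.

`parameter_recovery` closes the loop: sample "true" parameters, free-run a
session, refit, and correlate recovered with true values per parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import FitConfig, FitResult, fit
from .io import EventLog
from .models import (
    ACTION_NAMES,
    Action,
    ModelKind,
    ParamSet,
    init_state,
    validate_params,
)
from .task import (
    REWARD_CODE,
    ScheduleConfig,
    SessionConfig,
    TaskState,
    breakpoint_of,
    requirement,
    step_flow,
)

__all__ = [
    "StopRule",
    "TimingConfig",
    "FreeRunResult",
    "TrendResult",
    "RecoveryReport",
    "free_run",
    "rpe_trends",
    "parameter_recovery",
    "default_param_sampler",
]

_HARD_STEP_CAP = 1_000_000


@dataclass(frozen=True)
class StopRule:
    """Extra stop condition: end the run after `max_choices` free choices
    (used to match a simulated session's length to an observed one).
    Session termination rules always apply as well."""

    max_choices: int | None = None


@dataclass(frozen=True)
class TimingConfig:
    """Synthetic timestamping of free-run events.

    Inter-choice intervals are lognormal with the given median, floored at
    the refractory period; ``sigma`` (log-scale SD) sets the heavy tail that
    stands in for natural pauses.
    """

    median_ici_s: float = 0.9
    sigma: float = 1.0


@dataclass
class TrendResult:
    slope: float
    intercept: float
    p_value: float
    stderr: float
    n: int


@dataclass
class FreeRunResult:
    log: EventLog
    probs: np.ndarray       # (n_events, 3); NaN rows at rewards
    q: np.ndarray           # (n_events, 3) post-update
    c: np.ndarray
    rpe: np.ndarray
    seed: int
    breakpoint: int
    counts: dict

    @property
    def reward_mask(self) -> np.ndarray:
        return self.log.codes == REWARD_CODE

    @property
    def rpe_on_reward(self) -> np.ndarray:
        """RPE at each reward delivery (equals 1 - Q[MNP] just before it)."""
        return self.rpe[self.reward_mask]

    @property
    def rpe_on_mnp(self) -> np.ndarray:
        """RPE at each void magazine check (equals -Q[MNP] just before it)."""
        return self.rpe[self.log.codes == Action.MNP]


def free_run(
    params: ParamSet,
    kind: ModelKind,
    schedule: ScheduleConfig | None = None,
    session: SessionConfig | None = None,
    stop: StopRule | None = None,
    seed: int = 0,
    timing: TimingConfig | None = None,
) -> FreeRunResult:
    """Simulate one session of the agent in the task. Deterministic per seed."""
    kind = ModelKind(kind)
    validate_params(params, kind)
    schedule = schedule or ScheduleConfig()
    session = session or SessionConfig()
    stop = stop or StopRule()
    timing = timing or TimingConfig()
    rng = np.random.default_rng(seed)
    mu = math.log(timing.median_ici_s)

    agent = init_state(params, kind)
    task = TaskState()
    t = 0.0
    last_alp_t = 0.0
    times: list[float] = []
    codes: list[int] = []
    probs: list[np.ndarray] = []
    qs: list[np.ndarray] = []
    cs: list[np.ndarray] = []
    rpes: list[float] = []
    n_choices = 0

    for step in range(_HARD_STEP_CAP):
        ratio_done = task.presses_this_trial >= requirement(task.rewards_earned + 1, schedule)
        if not ratio_done:
            # advance the clock to the next would-be choice, then test the
            # session rules against that time
            t_next = t + max(session.refractory_s, rng.lognormal(mu, timing.sigma))
            if t_next > session.max_duration_s:
                break
            if t_next - last_alp_t > session.inactivity_limit_s:
                break
            if stop.max_choices is not None and n_choices >= stop.max_choices:
                break
            t = t_next
        res = step_flow(task, agent, params, kind, schedule, rng)
        agent, task = res.agent, res.task
        if res.event == REWARD_CODE:
            times.append(t + 0.05)  # pellet drops right after the last press
            t += session.iti_s
        else:
            times.append(t)
            if res.event == Action.ALP:
                last_alp_t = t
            n_choices += 1
        codes.append(res.event)
        probs.append(res.probs if res.probs is not None else np.full(3, np.nan))
        qs.append(agent.q.copy())
        cs.append(agent.c.copy())
        rpes.append(res.rpe)
        if task.rewards_earned >= session.max_rewards:
            break
    else:
        raise RuntimeError(f"free run exceeded the hard cap of {_HARD_STEP_CAP} steps")

    log = EventLog(
        np.asarray(times),
        np.asarray(codes, dtype=np.int64),
        metadata={
            "model": kind.value,
            "params": params.to_dict(),
            "seed": int(seed),
            "schedule": schedule.kind,
        },
    )
    counts = log.counts()
    return FreeRunResult(
        log=log,
        probs=np.vstack(probs) if probs else np.empty((0, 3)),
        q=np.vstack(qs) if qs else np.empty((0, 3)),
        c=np.vstack(cs) if cs else np.empty((0, 3)),
        rpe=np.asarray(rpes),
        seed=int(seed),
        breakpoint=breakpoint_of(log, schedule),
        counts=counts,
    )


def _ols_trend(y: np.ndarray) -> TrendResult:
    """OLS of y against its 1-based ordinal with a slope t-test; a constant
    series has exactly zero slope and an uninformative p of 1."""
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 events for a trend")
    x = np.arange(1, y.size + 1, dtype=float)
    if np.ptp(y) == 0.0:
        return TrendResult(0.0, float(y[0]), 1.0, 0.0, y.size)
    res = stats.linregress(x, y)
    return TrendResult(float(res.slope), float(res.intercept),
                       float(res.pvalue), float(res.stderr), y.size)


def rpe_trends(result: FreeRunResult) -> tuple[TrendResult, TrendResult]:
    """Within-session trends: |RPE| at void magazine checks vs. event
    ordinal, and RPE at rewards vs. reward ordinal."""
    return (
        _ols_trend(np.abs(result.rpe_on_mnp)),
        _ols_trend(result.rpe_on_reward),
    )


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------

def default_param_sampler(rng: np.random.Generator,
                          kind: ModelKind = ModelKind.PERSEVERANCE) -> ParamSet:
    """Draw "true" parameters over the regime fitted mouse behavior occupies:
    small learning rates, sharp softmax, positive initial values, strong
    avoidance of consecutive magazine checks."""
    from scipy.special import expit, logit

    kind = ModelKind(kind)
    alpha = float(expit(rng.uniform(logit(1e-4), logit(0.1))))
    beta = float(rng.uniform(5.0, 30.0))
    q0 = tuple(rng.uniform(0.0, 1.0, size=3))
    common = dict(beta=beta, q0=q0)
    if kind is ModelKind.SIMPLEQ:
        return ParamSet(alpha=alpha, **common)
    if kind is ModelKind.ASYMMETRY:
        alpha2 = float(expit(rng.uniform(logit(1e-4), logit(0.1))))
        return ParamSet(alpha_pos=alpha, alpha_neg=alpha2, **common)
    tau = float(rng.uniform(0.3, 0.95))
    phi = (float(rng.uniform(-3.0, 3.0)),
           float(rng.uniform(-25.0, -5.0)),
           float(rng.uniform(-3.0, 5.0)))
    if kind is ModelKind.NOLEARN:
        return ParamSet(tau=tau, phi=phi, **common)
    return ParamSet(alpha=alpha, tau=tau, phi=phi, **common)


@dataclass
class RecoveryReport:
    kind: ModelKind
    param_names: list
    true: np.ndarray       # (n_ok, n_params)
    recovered: np.ndarray  # (n_ok, n_params)
    pearson: dict          # name -> r (NaN for zero-variance parameters)
    cross_correlation: np.ndarray  # (n_params, n_params) of recovered values
    n_sims: int
    n_failed: int
    seed: int
    zero_variance: list

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, name in enumerate(self.param_names):
            rows.append({"parameter": name, "pearson_r": self.pearson[name],
                         "true_mean": self.true[:, j].mean(),
                         "recovered_mean": self.recovered[:, j].mean()})
        return pd.DataFrame(rows).set_index("parameter")


def _param_vector(p: ParamSet, names) -> np.ndarray:
    d = p.to_dict()
    return np.array([d[n] for n in names], dtype=float)


def parameter_recovery(
    kind: ModelKind = ModelKind.PERSEVERANCE,
    n_sims: int = 50,
    true_param_sampler: Callable[[np.random.Generator], ParamSet] | None = None,
    fit_config: FitConfig | None = None,
    seed: int = 0,
    schedule: ScheduleConfig | None = None,
    session: SessionConfig | None = None,
    stop: StopRule | None = None,
    timing: TimingConfig | None = None,
) -> RecoveryReport:
    """Simulate-and-refit assessment of parameter identifiability.

    For each of `n_sims` simulations: sample true parameters, free-run one
    session, fit `kind` back to the generated choices, and record the
    true/recovered pair.  Reports the Pearson correlation per parameter and
    the cross-correlation matrix of recovered values (off-diagonal structure
    there would indicate non-identifiable parameter combinations).
    Individual fit failures are counted and skipped, not fatal; so are
    sessions in which the sampled agent never earned a reward — such
    non-engaged runs end by the inactivity rule, are not PR sessions in any
    meaningful sense, and their fits are ill-posed.
    """
    if n_sims < 2:
        raise ValueError("n_sims must be >= 2")
    kind = ModelKind(kind)
    sampler = true_param_sampler or (lambda rng: default_param_sampler(rng, kind))
    fit_config = fit_config or FitConfig()
    master = np.random.default_rng(seed)
    sim_seeds = master.integers(0, 2**31 - 1, size=n_sims)

    names = sorted(sampler(np.random.default_rng(0)).to_dict())
    trues, recs = [], []
    n_failed = 0
    for s in range(n_sims):
        rng = np.random.default_rng(sim_seeds[s])
        true_p = sampler(rng)
        run = free_run(true_p, kind, schedule=schedule, session=session,
                       stop=stop, seed=int(sim_seeds[s]), timing=timing)
        if run.log.n_rewards == 0:
            n_failed += 1
            continue
        try:
            fr = fit(run.log, kind,
                     FitConfig(n_starts=fit_config.n_starts,
                               seed=int(sim_seeds[s] % (2**31 - 1)),
                               maxiter=fit_config.maxiter,
                               paper_param_counts=fit_config.paper_param_counts))
        except Exception:
            n_failed += 1
            continue
        trues.append(_param_vector(true_p, names))
        recs.append(_param_vector(fr.params, names))

    true_m = np.vstack(trues)
    rec_m = np.vstack(recs)
    pearson = {}
    zero_var = []
    for j, name in enumerate(names):
        if np.ptp(true_m[:, j]) == 0.0 or np.ptp(rec_m[:, j]) == 0.0:
            pearson[name] = float("nan")
            zero_var.append(name)
        else:
            pearson[name] = float(stats.pearsonr(true_m[:, j], rec_m[:, j])[0])
    with np.errstate(invalid="ignore"):
        cross = np.corrcoef(rec_m, rowvar=False)
    return RecoveryReport(
        kind=kind, param_names=names, true=true_m, recovered=rec_m,
        pearson=pearson, cross_correlation=cross, n_sims=n_sims,
        n_failed=n_failed, seed=int(seed), zero_variance=zero_var,
    )
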