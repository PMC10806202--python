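"""Maximum-likelihood fitting of the choice models and AIC model comparison.

A session log is replayed through a model: every free choice (ALP, MNP, ILP)
contributes ``log P(chosen)`` under the current softmax policy and is then
updated with ``r = 0``; every REWARD event applies the forced magazine-check
update with ``r = 1`` and contributes no likelihood term.  Free parameters
are maximized by multi-start bounded L-BFGS-B on transformed scales
(learning rates via logit, ``beta`` via softplus, ``q0`` and ``tau`` box-
constrained to [-1, 1], ``phi`` unconstrained) and reported back on the
natural scale.  Models are compared by ``AIC = -2 log L + 2 N_param``.

Parameter accounting: literal enumeration of free parameters gives
5 (SimpleQ), 6 (asymmetry), 9 (perseverance) and 8 (NoLearn).  A commonly
used alternative accounting charges the trace models 8 and 7 (counting the
trace block one short); ``FitConfig(paper_param_counts=True)`` switches the
AIC penalty to that convention.  The likelihood is unaffected either way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from ._fast import KIND_CODE, loglik_core, replay_core
from .models import ACTION_NAMES, ModelKind, ParamSet, validate_params

__all__ = [
    "N_FREE_PARAMS",
    "PAPER_PARAM_COUNTS",
    "ReplayResult",
    "FitConfig",
    "FitResult",
    "ModelComparison",
    "aic",
    "n_free_params",
    "replay_loglik",
    "fit",
    "compare_models",
]

#: literal count of free parameters per model variant
N_FREE_PARAMS = {
    ModelKind.SIMPLEQ: 5,        # alpha, beta, q0 x3
    ModelKind.ASYMMETRY: 6,      # alpha+-, beta, q0 x3
    ModelKind.PERSEVERANCE: 9,   # alpha, beta, q0 x3, tau, phi x3
    ModelKind.NOLEARN: 8,        # beta, q0 x3, tau, phi x3
}

#: alternative accounting charging the trace models one parameter less
PAPER_PARAM_COUNTS = {
    ModelKind.SIMPLEQ: 5,
    ModelKind.ASYMMETRY: 6,
    ModelKind.PERSEVERANCE: 8,
    ModelKind.NOLEARN: 7,
}

CANONICAL_ORDER = [
    ModelKind.SIMPLEQ,
    ModelKind.ASYMMETRY,
    ModelKind.PERSEVERANCE,
    ModelKind.NOLEARN,
]


def n_free_params(kind: ModelKind, paper_param_counts: bool = False) -> int:
    return (PAPER_PARAM_COUNTS if paper_param_counts else N_FREE_PARAMS)[ModelKind(kind)]


def aic(loglik: float, n_free: int) -> float:
    """Akaike information criterion, ``-2 log L + 2 k``."""
    if n_free < 1:
        raise ValueError("n_free must be >= 1")
    return -2.0 * float(loglik) + 2.0 * int(n_free)


def _core_args(params: ParamSet, kind: ModelKind):
    """Flatten a ParamSet into the scalar tuple the compiled kernels take."""
    tau = params.tau if params.tau is not None else 0.0
    phi = params.phi if params.phi is not None else (0.0, 0.0, 0.0)
    return (
        KIND_CODE[ModelKind(kind).value],
        params.alpha if params.alpha is not None else 0.0,
        params.alpha_pos if params.alpha_pos is not None else 0.0,
        params.alpha_neg if params.alpha_neg is not None else 0.0,
        float(params.beta),
        params.q0[0], params.q0[1], params.q0[2],
        float(tau), phi[0], phi[1], phi[2],
    )


@dataclass
class ReplayResult:
    """Per-event record of replaying a log through a model."""

    loglik: float
    n_choice_events: int
    codes: np.ndarray
    p_chosen: np.ndarray  # NaN at reward events
    rpe: np.ndarray
    q: np.ndarray  # (n_events, 3) post-update action values
    c: np.ndarray  # (n_events, 3) post-update choice traces

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"code": self.codes, "p_chosen": self.p_chosen, "rpe": self.rpe})
        for i, a in enumerate(ACTION_NAMES):
            df[f"q_{a}"] = self.q[:, i]
            df[f"c_{a}"] = self.c[:, i]
        return df


def replay_loglik(log, params: ParamSet, kind: ModelKind) -> ReplayResult:
    """Replay `log` under `params`, returning likelihood and trajectories."""
    kind = ModelKind(kind)
    validate_params(params, kind)
    codes = np.ascontiguousarray(np.asarray(log.codes if hasattr(log, "codes") else log, dtype=np.int64))
    if codes.size == 0 or int(np.sum(codes != 3)) == 0:
        raise ValueError("event log contains no free-choice events")
    n = codes.size
    p_chosen = np.empty(n)
    rpe = np.empty(n)
    q = np.empty((n, 3))
    c = np.empty((n, 3))
    ll, n_choice = replay_core(codes, *_core_args(params, kind), p_chosen, rpe, q, c)
    return ReplayResult(float(ll), int(n_choice), codes, p_chosen, rpe, q, c)


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitConfig:
    n_starts: int = 10
    seed: int = 0
    maxiter: int = 500
    paper_param_counts: bool = False


def _softplus(x: float) -> float:
    return float(np.logaddexp(0.0, x))


def _inv_softplus(b: float) -> float:
    if b <= 0:
        raise ValueError("softplus output must be positive")
    return float(b + np.log1p(-np.exp(-b))) if b < 30 else float(b)


# optimizer-space layout per kind: (field, transform) with transform one of
# "logit" (learning rates), "softplus" (beta), "box" (q0/tau), "free" (phi)
_LAYOUTS = {
    ModelKind.SIMPLEQ: [("alpha", "logit"), ("beta", "softplus"),
                        ("q0_0", "box"), ("q0_1", "box"), ("q0_2", "box")],
    ModelKind.ASYMMETRY: [("alpha_pos", "logit"), ("alpha_neg", "logit"), ("beta", "softplus"),
                          ("q0_0", "box"), ("q0_1", "box"), ("q0_2", "box")],
    ModelKind.PERSEVERANCE: [("alpha", "logit"), ("beta", "softplus"),
                             ("q0_0", "box"), ("q0_1", "box"), ("q0_2", "box"),
                             ("tau", "box"),
                             ("phi_0", "free"), ("phi_1", "free"), ("phi_2", "free")],
    ModelKind.NOLEARN: [("beta", "softplus"),
                        ("q0_0", "box"), ("q0_1", "box"), ("q0_2", "box"),
                        ("tau", "box"),
                        ("phi_0", "free"), ("phi_1", "free"), ("phi_2", "free")],
}

# Search bounds on the optimizer scale.  phi and beta get finite boxes: once
# |phi * c| or beta * |dQ| passes ~20 the softmax saturates and the likelihood
# is flat, so under separation (e.g. zero observed immediate magazine
# re-checks) the unconstrained MLE diverges; the box is the regularization.
_PHI_BOX = 30.0
_BETA_CAP = 100.0
_BOUNDS = {
    "logit": (None, None),
    "softplus": (None, _BETA_CAP),  # softplus(x) <= x + log 2, cap ~ 100
    "box": (-1.0, 1.0),
    "free": (-_PHI_BOX, _PHI_BOX),
}


def _x_to_params(x: np.ndarray, kind: ModelKind) -> ParamSet:
    vals: dict[str, float] = {}
    for (name, tf), xi in zip(_LAYOUTS[kind], x):
        if tf == "logit":
            vals[name] = float(special.expit(xi))
        elif tf == "softplus":
            vals[name] = _softplus(xi)
        else:
            vals[name] = float(xi)
    q0 = (vals["q0_0"], vals["q0_1"], vals["q0_2"])
    phi = (vals["phi_0"], vals["phi_1"], vals["phi_2"]) if "phi_0" in vals else None
    return ParamSet(
        beta=vals["beta"],
        q0=q0,
        alpha=vals.get("alpha"),
        alpha_pos=vals.get("alpha_pos"),
        alpha_neg=vals.get("alpha_neg"),
        tau=vals.get("tau"),
        phi=phi,
    )


def _params_to_x(params: ParamSet, kind: ModelKind) -> np.ndarray:
    flat = {
        "alpha": params.alpha, "alpha_pos": params.alpha_pos, "alpha_neg": params.alpha_neg,
        "beta": params.beta, "tau": params.tau,
        "q0_0": params.q0[0], "q0_1": params.q0[1], "q0_2": params.q0[2],
    }
    if params.phi is not None:
        flat.update({"phi_0": params.phi[0], "phi_1": params.phi[1], "phi_2": params.phi[2]})
    x = []
    for name, tf in _LAYOUTS[kind]:
        v = flat[name]
        if tf == "logit":
            v = float(special.logit(np.clip(v, 1e-12, 1 - 1e-12)))
        elif tf == "softplus":
            v = _inv_softplus(max(v, 1e-8))
        x.append(float(v))
    return np.array(x)


def _draw_start(rng: np.random.Generator, kind: ModelKind) -> np.ndarray:
    """Seeded random start on the optimizer scale, drawn over the natural
    ranges the fitted mouse regime occupies."""
    x = []
    for name, tf in _LAYOUTS[kind]:
        if tf == "logit":  # learning rates: logit-uniform over (1e-4, 0.5)
            x.append(rng.uniform(special.logit(1e-4), special.logit(0.5)))
        elif tf == "softplus":  # beta uniform over (1, 30)
            x.append(_inv_softplus(rng.uniform(1.0, 30.0)))
        elif name == "tau":
            x.append(rng.uniform(0.05, 0.95))
        elif name.startswith("q0"):
            x.append(rng.uniform(-1.0, 1.0))
        else:  # phi: cover strong avoidance through mild repetition
            x.append(rng.uniform(-25.0, 5.0))
    return np.array(x)


def _heuristic_start(codes: np.ndarray, kind: ModelKind) -> ParamSet:
    """Data-driven first start: q0 from observed choice frequencies (which
    the early-session softmax must reproduce), mid-range everything else."""
    choice = codes[codes != 3]
    freq = np.bincount(choice, minlength=3) + 1.0
    freq = freq / freq.sum()
    q0 = tuple(np.clip(freq / freq.max(), 0.0, 1.0))
    if kind is ModelKind.SIMPLEQ:
        return ParamSet(alpha=0.005, beta=10.0, q0=q0)
    if kind is ModelKind.ASYMMETRY:
        return ParamSet(alpha_pos=0.005, alpha_neg=0.005, beta=10.0, q0=q0)
    if kind is ModelKind.NOLEARN:
        return ParamSet(beta=10.0, q0=q0, tau=0.7, phi=(0.0, 0.0, 0.0))
    return ParamSet(alpha=0.005, beta=10.0, q0=q0, tau=0.7, phi=(0.0, 0.0, 0.0))


@dataclass
class FitResult:
    kind: ModelKind
    params: ParamSet
    loglik: float
    n_free_params: int
    aic: float
    n_choice_events: int
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind.value,
            "params": self.params.to_dict(),
            "loglik": self.loglik,
            "n_free_params": self.n_free_params,
            "aic": self.aic,
            "n_choice_events": self.n_choice_events,
            "diagnostics": self.diagnostics,
        }


def fit(log, kind: ModelKind, config: FitConfig | None = None,
        x0: ParamSet | None = None) -> FitResult:
    """Fit `kind`'s free parameters to `log` by multi-start bounded MLE.

    Deterministic given ``config.seed``; the best of all starts is reported.
    The first start is a data-driven heuristic (or `x0` when given); the
    rest are seeded random draws over the plausible natural ranges.
    """
    kind = ModelKind(kind)
    config = config or FitConfig()
    codes = np.ascontiguousarray(np.asarray(log.codes if hasattr(log, "codes") else log, dtype=np.int64))
    choice_codes = codes[codes != 3]
    if choice_codes.size == 0:
        raise ValueError("event log contains no free-choice events")
    if np.unique(choice_codes).size == 1:
        warnings.warn("degenerate log: a single action type only; fit may be ill-posed",
                      stacklevel=2)

    kind_code = KIND_CODE[kind.value]
    layout = _LAYOUTS[kind]

    # hot path: transform optimizer coordinates straight into kernel scalars
    def neg_ll(x):
        vals = np.empty(11)  # alpha, apos, aneg, beta, q0 x3, tau, phi x3
        vals[:] = 0.0
        for (name, tf), xi in zip(layout, x):
            if tf == "logit":
                v = special.expit(xi)
            elif tf == "softplus":
                v = np.logaddexp(0.0, xi)
            else:
                v = xi
            if name == "alpha":
                vals[0] = v
            elif name == "alpha_pos":
                vals[1] = v
            elif name == "alpha_neg":
                vals[2] = v
            elif name == "beta":
                vals[3] = v
            elif name == "q0_0":
                vals[4] = v
            elif name == "q0_1":
                vals[5] = v
            elif name == "q0_2":
                vals[6] = v
            elif name == "tau":
                vals[7] = v
            elif name == "phi_0":
                vals[8] = v
            elif name == "phi_1":
                vals[9] = v
            else:
                vals[10] = v
        ll, _ = loglik_core(codes, kind_code, vals[0], vals[1], vals[2], vals[3],
                            vals[4], vals[5], vals[6], vals[7], vals[8], vals[9], vals[10])
        return -ll if np.isfinite(ll) else 1e12

    bounds = [_BOUNDS[tf] for _, tf in layout]
    rng = np.random.default_rng(config.seed)
    best = None
    start_neglls = []
    converged = []
    for s in range(config.n_starts):
        if s == 0:
            xs = _params_to_x(x0 if x0 is not None else _heuristic_start(codes, kind), kind)
        else:
            xs = _draw_start(rng, kind)
        res = optimize.minimize(neg_ll, xs, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": config.maxiter})
        start_neglls.append(float(res.fun))
        converged.append(bool(res.success))
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"all {config.n_starts} starts failed: {start_neglls}")
    if not any(converged):
        warnings.warn("no optimizer start reported formal convergence; best value used",
                      stacklevel=2)

    params = _x_to_params(best.x, kind)
    ll = -float(best.fun)
    k = n_free_params(kind, config.paper_param_counts)
    _, n_choice = loglik_core(codes, *_core_args(params, kind))
    return FitResult(
        kind=kind,
        params=params,
        loglik=ll,
        n_free_params=k,
        aic=aic(ll, k),
        n_choice_events=int(n_choice),
        diagnostics={
            "n_starts": config.n_starts,
            "seed": config.seed,
            "start_neglls": start_neglls,
            "converged": converged,
            "best_start": int(np.argmin(start_neglls)),
        },
    )


@dataclass
class ModelComparison:
    results: dict  # ModelKind -> FitResult (or Exception for failed fits)
    winner: ModelKind
    table: pd.DataFrame

    def __getitem__(self, kind) -> FitResult:
        return self.results[ModelKind(kind)]


def compare_models(log, kinds=None, config: FitConfig | None = None) -> ModelComparison:
    """Fit each model in `kinds` and rank by AIC.

    The winner has the lowest AIC; ties resolve to the first model in
    canonical order (SimpleQ, asymmetry, perseverance, NoLearn) and are
    visible in the table.  A failed fit is recorded as its exception; the
    other models are still reported.
    """
    kinds = [ModelKind(k) for k in (kinds or CANONICAL_ORDER)]
    if len(kinds) < 2:
        raise ValueError("compare_models needs at least 2 model kinds")
    config = config or FitConfig()
    results: dict[ModelKind, object] = {}
    rows = []
    for kind in kinds:
        try:
            fr = fit(log, kind, config)
        except Exception as exc:  # propagate per-model, keep the rest
            results[kind] = exc
            rows.append({"model": kind.value, "loglik": np.nan, "n_free_params": np.nan,
                         "aic": np.nan, "error": str(exc)})
            continue
        results[kind] = fr
        rows.append({"model": kind.value, "loglik": fr.loglik,
                     "n_free_params": fr.n_free_params, "aic": fr.aic, "error": ""})
    table = pd.DataFrame(rows)
    if table["aic"].notna().sum() == 0:
        raise RuntimeError("every model fit failed")
    best_aic = table["aic"].min()
    table["delta_aic"] = table["aic"] - best_aic
    # tie-break: first row (in the order given, canonical by default) at the minimum
    winner_row = int(np.flatnonzero(table["aic"].to_numpy() == best_aic)[0])
    winner = kinds[winner_row]
    table["winner"] = False
    table.loc[winner_row, "winner"] = True
    return ModelComparison(results=results, winner=winner, table=table)
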