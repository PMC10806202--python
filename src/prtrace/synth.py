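"""Synthetic fixture generators: behavioral sessions and matched photometry.

`make_session` wraps a model free run to produce a timestamped event log
with its full generative ground truth, emulating the empirical session
structure: exponential PR escalation, ~0.9-s inter-press intervals, a 30-s
ITI after each reward, 60-min / 100-reward / 5-min-inactivity termination,
and the characteristic choice-frequency ordering ALP > MNP > ILP.

`make_photometry` synthesizes a two-channel 20-Hz trace locked to a session
log: shared multiplicative bleaching on both channels, white baseline
noise, a large positive transient at each reward and a small negative
transient at each void magazine check.  Transient amplitudes are specified
in z units (multiples of the post-filter baseline SD) so that the analysis
chain's z-scored output can be compared with the injected truth; per-event
linear trends (surge growth, dip attenuation) emulate the within-session
dynamics the perseverance model predicts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace  # noqa: F401

import numpy as np

from .io import EventLog
from .models import ModelKind, ParamSet
from .photometry import PhotometryTrace
from .simulation import FreeRunResult, StopRule, TimingConfig, free_run
from .task import REWARD_CODE, ScheduleConfig, SessionConfig

__all__ = [
    "REFERENCE_PERSEVERANCE_PARAMS",
    "SyntheticSessionSpec",
    "SyntheticPhotometrySpec",
    "SyntheticSession",
    "make_session",
    "make_photometry",
]

#: a perseverance-model parameter regime typical of fitted mouse behavior:
#: tiny learning rate, sharp softmax, high initial values for the rewarded
#: lever and the magazine, strong avoidance of consecutive magazine checks
REFERENCE_PERSEVERANCE_PARAMS = ParamSet(
    alpha=6.8e-4,
    beta=14.8,
    q0=(0.82, 0.73, 0.23),
    tau=0.69,
    phi=(-0.1, -16.6, 3.0),
)


@dataclass(frozen=True)
class SyntheticSessionSpec:
    kind: ModelKind = ModelKind.PERSEVERANCE
    params: ParamSet = REFERENCE_PERSEVERANCE_PARAMS
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    session: SessionConfig = field(default_factory=SessionConfig)
    timing: TimingConfig = field(default_factory=TimingConfig)
    stop: StopRule = field(default_factory=StopRule)
    seed: int = 0


@dataclass
class SyntheticSession:
    """A generated event log together with its generative ground truth."""

    log: EventLog
    run: FreeRunResult
    spec: SyntheticSessionSpec

    @property
    def params(self) -> ParamSet:
        return self.spec.params


def make_session(spec: SyntheticSessionSpec | None = None, **overrides) -> SyntheticSession:
    """Generate one synthetic PR (or FR) session. Deterministic per seed."""
    spec = replace(spec or SyntheticSessionSpec(), **overrides)
    run = free_run(
        spec.params,
        spec.kind,
        schedule=spec.schedule,
        session=spec.session,
        stop=spec.stop,
        seed=spec.seed,
        timing=spec.timing,
    )
    return SyntheticSession(log=run.log, run=run, spec=spec)


@dataclass(frozen=True)
class SyntheticPhotometrySpec:
    """Generator settings for a session-locked two-channel trace.

    Amplitudes are in z units.  ``noise_sd`` is the fractional baseline
    noise of the reconstructed ratio (split evenly between the channels);
    the generator scales transient kernels by ``signal_scale`` fractional
    units per z unit, which defaults to ``noise_sd`` so that the analysis
    chain's z-scores recover the injected amplitudes.  Set ``signal_scale``
    explicitly when generating noiseless traces (where z-scoring is
    degenerate and recovery is checked on the filtered ratio instead).
    """

    frame_rate_hz: float = 20.0
    noise_sd: float = 0.005
    signal_scale: float | None = None
    base_465: float = 2.0
    base_405: float = 1.0
    bleach_tau465_s: float = 1200.0
    bleach_tau405_s: float = 1200.0
    surge_peak_z: float = 5.2
    surge_growth_per_reward: float = 5.2e-2
    dip_trough_z: float = -0.57
    dip_attenuation_per_event: float = 5.4e-3
    surge_peak_time_s: float = 1.0
    surge_shape: float = 3.0
    dip_trough_time_s: float = 1.5
    dip_shape: float = 8.0
    kernel_support_s: float = 3.0
    pre_mnp_ramp_z: float = 0.0  # optional reward-expectation bump before MNP
    max_duration_s: float = 7200.0
    seed: int = 0


def _gamma_kernel(t: np.ndarray, peak_time: float, shape: float, support: float) -> np.ndarray:
    """Unit-peak gamma-shaped transient confined to (0, support] s."""
    k = np.zeros_like(t)
    ok = (t > 0) & (t <= support)
    tt = t[ok] / peak_time
    k[ok] = tt**shape * np.exp(shape * (1.0 - tt))
    return k


def make_photometry(
    spec: SyntheticPhotometrySpec,
    log: EventLog,
) -> tuple[PhotometryTrace, dict]:
    """Synthesize a trace locked to `log`; returns (trace, ground_truth).

    Ground truth records per-event injected z amplitudes (surge amplitudes
    grow linearly per reward; dip amplitudes attenuate linearly toward, and
    clamped at, zero) plus the scales needed to verify recovery.
    """
    if len(log) == 0:
        raise ValueError("empty event log")
    fs = spec.frame_rate_hz
    iti = 30.0
    t_end = float(log.time_s[-1]) + iti + 5.0
    if t_end > spec.max_duration_s:
        raise ValueError(f"session span {t_end:.0f}s exceeds the generator cap "
                         f"{spec.max_duration_s:.0f}s")
    n = int(round(t_end * fs)) + 1
    time = np.arange(n) / fs
    rng = np.random.default_rng(spec.seed)

    reward_times = log.time_s[log.codes == REWARD_CODE]
    mnp_times = log.time_s[log.codes == 1]

    surge_amps = spec.surge_peak_z + spec.surge_growth_per_reward * np.arange(reward_times.size)
    dip_amps = np.minimum(
        0.0, spec.dip_trough_z + spec.dip_attenuation_per_event * np.arange(mnp_times.size)
    )

    sig_z = np.zeros(n)
    for amp, te in zip(surge_amps, reward_times):
        sig_z += amp * _gamma_kernel(time - te, spec.surge_peak_time_s,
                                     spec.surge_shape, spec.kernel_support_s)
    for amp, te in zip(dip_amps, mnp_times):
        sig_z += amp * _gamma_kernel(time - te, spec.dip_trough_time_s,
                                     spec.dip_shape, spec.kernel_support_s)
    if spec.pre_mnp_ramp_z:
        for te in mnp_times:
            sig_z += spec.pre_mnp_ramp_z * _gamma_kernel(te - time, 0.5, 2.0, 1.5)

    scale = spec.signal_scale if spec.signal_scale is not None else spec.noise_sd
    ch_sd = spec.noise_sd / math.sqrt(2.0)  # split so the ratio noise SD is noise_sd
    frac465 = scale * sig_z + rng.normal(0.0, ch_sd, n) if ch_sd > 0 else scale * sig_z
    frac405 = rng.normal(0.0, ch_sd, n) if ch_sd > 0 else np.zeros(n)

    f465 = spec.base_465 * np.exp(-time / spec.bleach_tau465_s) * (1.0 + frac465)
    f405 = spec.base_405 * np.exp(-time / spec.bleach_tau405_s) * (1.0 + frac405)
    trace = PhotometryTrace(time_s=time, f465=f465, f405=f405)

    truth = {
        "reward_times": reward_times.tolist(),
        "mnp_times": mnp_times.tolist(),
        "surge_amps_z": surge_amps.tolist(),
        "dip_amps_z": dip_amps.tolist(),
        "surge_growth_per_reward": spec.surge_growth_per_reward,
        "dip_attenuation_per_event": spec.dip_attenuation_per_event,
        "signal_scale": scale,
        "noise_sd": spec.noise_sd,
        "ratio_baseline": spec.base_465 / spec.base_405,
        "seed": spec.seed,
    }
    return trace, truth
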