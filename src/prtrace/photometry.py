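"""Fiber-photometry dopamine signal processing.

The chain mirrors standard ratiometric GRAB-sensor practice: the 465 nm
(dopamine-sensitive) channel is divided by the 405 nm reference to cancel
shared multiplicative artifacts (bleaching, fiber bending), the ratio is
high-pass filtered at ~0.0167 Hz (1-minute wavelength) to strip residual
slow drift, and the session is z-scored against a pooled baseline taken
from the last 20 s of every inter-trial interval — the early ITI is
contaminated by reward-consumption dopamine, the late ITI is quiet.

Peri-event analysis bins the z-scored signal into 100 ms blocks around each
event and extracts one amplitude per event over the (0, 3] s post-event
window: the minimum for magazine-nosepoke dips, the maximum for reward
surges.  `amplitude_trend` then regresses amplitudes on event ordinal to
quantify within-session attenuation or growth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats

from .simulation import TrendResult

__all__ = [
    "PhotometryTrace",
    "PeriEventMatrix",
    "PhotometryError",
    "read_photometry",
    "write_photometry",
    "ratiometric",
    "highpass",
    "zscore_by_iti_baseline",
    "iti_windows_from_rewards",
    "peri_event",
    "amplitude_trend",
]

FRAME_RATE_HZ = 20.0
JITTER_TOL = 0.05  # accept +-5% deviation from nominal frame spacing


class PhotometryError(ValueError):
    pass


@dataclass
class PhotometryTrace:
    """Two-channel photometry time series at a nominally uniform frame rate."""

    time_s: np.ndarray
    f465: np.ndarray
    f405: np.ndarray

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.f465 = np.asarray(self.f465, dtype=float)
        self.f405 = np.asarray(self.f405, dtype=float)
        if not (self.time_s.size == self.f465.size == self.f405.size):
            raise PhotometryError("time_s, f465, f405 must be equal length")

    @property
    def fs(self) -> float:
        dt = np.diff(self.time_s)
        med = np.median(dt)
        if med <= 0:
            raise PhotometryError("non-increasing time axis")
        if np.any(np.abs(dt - med) > JITTER_TOL * med):
            raise PhotometryError("sampling jitter exceeds the 5% tolerance")
        return 1.0 / med

    @property
    def ratio(self) -> np.ndarray:
        return ratiometric(self.f465, self.f405)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time_s, "f465": self.f465, "f405": self.f405})


def read_photometry(path: str | Path) -> PhotometryTrace:
    df = pd.read_csv(path)
    missing = {"time_s", "f465", "f405"} - set(df.columns)
    if missing:
        raise PhotometryError(f"{path}: missing column(s) {sorted(missing)}")
    return PhotometryTrace(df["time_s"].to_numpy(), df["f465"].to_numpy(), df["f405"].to_numpy())


def write_photometry(trace: PhotometryTrace, path: str | Path) -> None:
    trace.to_frame().to_csv(path, index=False, float_format="%.6f")


def ratiometric(f465: np.ndarray, f405: np.ndarray) -> np.ndarray:
    """Elementwise 465/405 ratio; frames with a non-positive reference are
    NaN (invalid) and excluded downstream.  A multiplicative artifact shared
    by both channels cancels exactly — the point of the reference channel."""
    f465 = np.asarray(f465, dtype=float)
    f405 = np.asarray(f405, dtype=float)
    if f465.shape != f405.shape:
        raise PhotometryError("channel lengths differ")
    out = np.full(f465.shape, np.nan)
    ok = f405 > 0
    out[ok] = f465[ok] / f405[ok]
    return out


def _interp_nan(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    bad = ~np.isfinite(x)
    if not bad.any():
        return x, bad
    if bad.all():
        raise PhotometryError("no valid frames")
    idx = np.arange(x.size)
    filled = x.copy()
    filled[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    return filled, bad


def highpass(x: np.ndarray, fs: float = FRAME_RATE_HZ, method: str = "moving_average",
             cutoff_hz: float = 1.0 / 60.0) -> np.ndarray:
    """Remove components slower than ~1 minute.

    ``moving_average`` (default) subtracts a 60-s centered moving average —
    a direct reading of the 1-minute-wavelength cutoff: constants and linear
    drift vanish, transients of a few seconds pass essentially untouched.
    ``butterworth`` applies a 2nd-order zero-phase Butterworth high-pass at
    `cutoff_hz` instead.  Invalid (NaN) frames are interpolated for the
    filter and restored to NaN afterwards.
    """
    x = np.asarray(x, dtype=float)
    win = int(round(fs / cutoff_hz))
    if x.size <= win:
        raise PhotometryError(
            f"series of {x.size} samples is shorter than the {win}-sample filter window"
        )
    filled, bad = _interp_nan(x)
    if method == "moving_average":
        baseline = ndimage.uniform_filter1d(filled, size=win | 1, mode="nearest")
        out = filled - baseline
    elif method == "butterworth":
        sos = signal.butter(2, cutoff_hz, btype="highpass", fs=fs, output="sos")
        out = signal.sosfiltfilt(sos, filled)
    else:
        raise ValueError(f"unknown high-pass method {method!r}")
    out[bad] = np.nan
    return out


def iti_windows_from_rewards(reward_times_s, iti_s: float = 30.0) -> list[tuple[float, float]]:
    """ITI windows (levers retracted) following each reward delivery."""
    return [(float(t), float(t) + iti_s) for t in np.asarray(reward_times_s, dtype=float)]


def zscore_by_iti_baseline(
    x: np.ndarray,
    time_s: np.ndarray,
    iti_windows,
    baseline_s: float = 20.0,
) -> np.ndarray:
    """z-score the whole session against pooled late-ITI baseline samples.

    Samples from the last `baseline_s` of every ITI window are pooled into
    one mean/SD applied session-wide, so the transformation is invariant to
    affine rescaling of the input and the pooled baseline itself maps to
    mean 0, SD 1 by construction.
    """
    x = np.asarray(x, dtype=float)
    time_s = np.asarray(time_s, dtype=float)
    mask = np.zeros(x.size, dtype=bool)
    for start, end in iti_windows:
        if end - start < baseline_s:
            warnings.warn(f"ITI window ({start:.1f}, {end:.1f}) shorter than the "
                          f"{baseline_s:.0f}-s baseline; using its full span", stacklevel=2)
            lo = start
        else:
            lo = end - baseline_s
        mask |= (time_s >= lo) & (time_s < end)
    mask &= np.isfinite(x)
    if not mask.any():
        raise PhotometryError("no baseline samples fall inside the recording")
    base = x[mask]
    mu = base.mean()
    sd = base.std()
    if sd <= 1e-12 * (1.0 + abs(mu)):
        raise PhotometryError("zero pooled baseline variance; z-scores undefined")
    return (x - mu) / sd


@dataclass
class PeriEventMatrix:
    """Event-aligned, 100-ms-binned signal with per-event amplitudes.

    ``matrix`` is (n_events, n_bins), NaN where the recording did not cover
    the bin.  ``amplitudes`` holds the signed extremum over (0, 3] s after
    each event (min for MNP dips, max for reward surges); events with less
    than 3 s of post-event recording are excluded (NaN) with a warning and
    marked in ``truncated``.
    """

    event_type: str
    event_times: np.ndarray
    bin_centers: np.ndarray
    matrix: np.ndarray
    amplitudes: np.ndarray
    truncated: np.ndarray
    pre_s: float
    post_s: float
    bin_s: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=[f"{t:+.2f}s" for t in self.bin_centers])
        df.insert(0, "event_time_s", self.event_times)
        df.insert(1, "amplitude", self.amplitudes)
        return df


def peri_event(
    z: np.ndarray,
    time_s: np.ndarray,
    event_times_s,
    event_type: str = "MNP",
    pre_s: float = 2.0,
    post_s: float = 5.0,
    bin_s: float = 0.1,
    amp_window_s: tuple[float, float] = (0.0, 3.0),
) -> PeriEventMatrix:
    """Extract event-aligned binned signal and per-event amplitudes.

    `event_type` decides the amplitude convention: ``"MNP"`` takes the
    minimum (a dip, reported signed and typically negative), ``"REWARD"``
    the maximum (a surge).  Bins are `bin_s` wide, aligned so that bin edges
    fall on multiples of `bin_s` relative to the event; samples are assigned
    to bins by their timestamps (nearest-frame within jitter tolerance).
    """
    z = np.asarray(z, dtype=float)
    time_s = np.asarray(time_s, dtype=float)
    event_times = np.asarray(event_times_s, dtype=float)
    if event_times.size == 0:
        raise PhotometryError("no events supplied")
    if event_type not in ("MNP", "REWARD"):
        raise ValueError("event_type must be 'MNP' or 'REWARD'")
    take_min = event_type == "MNP"

    n_bins = int(round((pre_s + post_s) / bin_s))
    edges = -pre_s + bin_s * np.arange(n_bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2.0

    t0, t1 = time_s[0], time_s[-1]
    inside = (event_times >= t0) & (event_times <= t1)
    if not inside.any():
        raise PhotometryError("no events fall within the recording span")
    if not inside.all():
        warnings.warn(f"{int((~inside).sum())} event(s) outside the recording dropped",
                      stacklevel=2)
    event_times = event_times[inside]

    matrix = np.full((event_times.size, n_bins), np.nan)
    truncated = np.zeros(event_times.size, dtype=bool)
    for i, te in enumerate(event_times):
        rel = time_s - te
        bins = np.floor((rel + pre_s) / bin_s).astype(int)
        ok = (bins >= 0) & (bins < n_bins) & np.isfinite(z)
        if ok.any():
            sums = np.bincount(bins[ok], weights=z[ok], minlength=n_bins)
            cnts = np.bincount(bins[ok], minlength=n_bins)
            with np.errstate(invalid="ignore"):
                matrix[i] = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
        truncated[i] = (te + amp_window_s[1] > t1) or (te - pre_s < t0)

    amp_bins = (centers > amp_window_s[0]) & (centers <= amp_window_s[1])
    amplitudes = np.full(event_times.size, np.nan)
    for i in range(event_times.size):
        if event_times[i] + amp_window_s[1] > t1:
            continue
        seg = matrix[i, amp_bins]
        seg = seg[np.isfinite(seg)]
        if seg.size:
            amplitudes[i] = seg.min() if take_min else seg.max()
    n_excl = int(np.sum(~np.isfinite(amplitudes)))
    if n_excl:
        warnings.warn(f"{n_excl} event(s) lacked full {amp_window_s[1]:.0f}-s post-event "
                      "coverage and were excluded from amplitude extraction", stacklevel=2)
    return PeriEventMatrix(
        event_type=event_type, event_times=event_times, bin_centers=centers,
        matrix=matrix, amplitudes=amplitudes, truncated=truncated,
        pre_s=pre_s, post_s=post_s, bin_s=bin_s,
    )


def amplitude_trend(amplitudes, ordinals=None) -> TrendResult:
    """OLS of amplitude against event ordinal with a two-sided slope t-test.

    For attenuating dips (negative amplitudes shrinking toward zero) the
    slope comes out positive — the sign convention follows the signed
    amplitudes, not their magnitudes.
    """
    amps = np.asarray(amplitudes, dtype=float)
    if ordinals is None:
        ordinals = np.arange(1, amps.size + 1, dtype=float)
    else:
        ordinals = np.asarray(ordinals, dtype=float)
    ok = np.isfinite(amps) & np.isfinite(ordinals)
    amps, ordinals = amps[ok], ordinals[ok]
    if amps.size < 3:
        raise PhotometryError("need at least 3 events for an amplitude trend")
    if np.ptp(amps) == 0.0:
        return TrendResult(0.0, float(amps[0]), 1.0, 0.0, amps.size)
    res = stats.linregress(ordinals, amps)
    return TrendResult(float(res.slope), float(res.intercept),
                       float(res.pvalue), float(res.stderr), amps.size)
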