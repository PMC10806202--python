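"""Event-log container, CSV round-tripping and cross-condition comparison.

The on-disk format is a two-column CSV with header ``time_s,event`` where
``event`` is one of ``ALP``, ``MNP``, ``ILP``, ``REWARD``; session metadata
(subject, session id, schedule, condition label, generator provenance)
travels in an optional JSON sidecar next to the CSV.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .models import ACTION_NAMES, ModelKind
from .task import REWARD_CODE, ScheduleConfig, requirement

__all__ = [
    "EVENT_LABELS",
    "EventLog",
    "EventLogError",
    "read_events",
    "write_events",
    "condition_compare",
]

EVENT_LABELS = ACTION_NAMES + ("REWARD",)
_LABEL_TO_CODE = {lab: i for i, lab in enumerate(EVENT_LABELS)}


class EventLogError(ValueError):
    pass


@dataclass
class EventLog:
    """Ordered, timestamped session events.

    ``codes`` holds integer events (0 ALP, 1 MNP, 2 ILP, 3 REWARD) aligned
    with ``time_s`` (seconds from session start, non-decreasing).
    """

    time_s: np.ndarray
    codes: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.time_s.shape != self.codes.shape:
            raise EventLogError("time_s and codes must have equal length")

    def __len__(self) -> int:
        return self.codes.size

    @property
    def events(self) -> list[str]:
        return [EVENT_LABELS[c] for c in self.codes]

    @property
    def n_rewards(self) -> int:
        return int(np.sum(self.codes == REWARD_CODE))

    @property
    def n_choices(self) -> int:
        return int(np.sum(self.codes != REWARD_CODE))

    def counts(self) -> dict[str, int]:
        return {lab: int(np.sum(self.codes == c)) for lab, c in _LABEL_TO_CODE.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time_s, "event": self.events})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, metadata: dict | None = None) -> "EventLog":
        bad = ~df["event"].isin(EVENT_LABELS)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise EventLogError(
                f"unknown event label {df['event'].iloc[i]!r} at data row {i + 1} "
                f"(allowed: {', '.join(EVENT_LABELS)})"
            )
        codes = df["event"].map(_LABEL_TO_CODE).to_numpy(dtype=np.int64)
        return cls(df["time_s"].to_numpy(dtype=float), codes, metadata or {})

    def validate(self, schedule: ScheduleConfig | None = None, strict: bool = False) -> None:
        """Check event-log invariants.

        Always enforced: closed vocabulary (by construction) and
        non-decreasing times.  If a schedule is given, also check that the
        number of ALPs between consecutive rewards equals the ratio
        requirement; real logs can be imperfect, so a mismatch is a warning
        unless ``strict``.
        """
        dt = np.diff(self.time_s)
        if np.any(dt < 0):
            i = int(np.flatnonzero(dt < 0)[0])
            raise EventLogError(
                f"times must be non-decreasing: row {i + 2} goes backwards "
                f"({self.time_s[i]:.4f} -> {self.time_s[i + 1]:.4f})"
            )
        if schedule is not None:
            alp = 0
            n_rew = 0
            for code in self.codes:
                if code == REWARD_CODE:
                    need = requirement(n_rew + 1, schedule)
                    if alp != need:
                        msg = (
                            f"reward {n_rew + 1} completed after {alp} active presses; "
                            f"schedule requires {need}"
                        )
                        if strict:
                            raise EventLogError(msg)
                        warnings.warn(msg, stacklevel=2)
                    n_rew += 1
                    alp = 0
                elif code == 0:
                    alp += 1


def read_events(path: str | Path, schedule: ScheduleConfig | None = None) -> EventLog:
    """Read a ``time_s,event`` CSV (+ optional ``<stem>.meta.json`` sidecar)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"event": str})
    missing = {"time_s", "event"} - set(df.columns)
    if missing:
        raise EventLogError(f"{path}: missing column(s) {sorted(missing)}")
    meta = {}
    sidecar = path.with_suffix(".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    log = EventLog.from_frame(df, meta)
    log.validate(schedule)
    return log


def write_events(log: EventLog, path: str | Path) -> None:
    """Write the CSV (deterministic %.4f timestamps) and metadata sidecar.

    Validation runs first so a bad log never partially writes output.
    """
    log.validate()
    path = Path(path)
    lines = ["time_s,event"]
    lines += [f"{t:.4f},{lab}" for t, lab in zip(log.time_s, log.events)]
    path.write_text("\n".join(lines) + "\n")
    if log.metadata:
        path.with_suffix(".meta.json").write_text(json.dumps(log.metadata, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# Cross-condition parameter comparison (e.g. saline vs. drug sessions)
# ---------------------------------------------------------------------------

def _param_table(fits) -> pd.DataFrame:
    rows = [f.params.to_dict() if hasattr(f, "params") else dict(f) for f in fits]
    return pd.DataFrame(rows)


def condition_compare(fits_a, fits_b, paired: bool = False) -> pd.DataFrame:
    """Per-parameter comparison of two cohorts of fit results.

    Returns a DataFrame indexed by parameter with per-condition mean and
    SEM, the two-sided t statistic (paired or unpaired) and raw p-value.
    This is the operation by which a drug effect expressed purely through
    initial action values (``q0`` shifts without learning-parameter shifts)
    becomes visible.  p-values are reported uncorrected; callers wanting a
    Holm correction across the parameters can apply it to the output.
    """
    if len(fits_a) < 2 or len(fits_b) < 2:
        raise ValueError("need at least 2 fits per condition")
    if paired and len(fits_a) != len(fits_b):
        raise ValueError("paired comparison requires equal-length, matched cohorts")
    ta, tb = _param_table(fits_a), _param_table(fits_b)
    params = [c for c in ta.columns if c in tb.columns]
    rows = []
    for name in params:
        a = ta[name].to_numpy(dtype=float)
        b = tb[name].to_numpy(dtype=float)
        if paired:
            d = b - a
            if np.allclose(d, 0.0):
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_rel(a, b)
        elif np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
            # both cohorts constant (e.g. a parameter pinned by its bound):
            # identical -> no difference; else infinitely separated
            t, p = (0.0, 1.0) if a[0] == b[0] else (np.inf * np.sign(a[0] - b[0]), 0.0)
        else:
            with np.errstate(all="ignore"):
                t, p = stats.ttest_ind(a, b)
        rows.append(
            {
                "parameter": name,
                "mean_a": a.mean(),
                "sem_a": stats.sem(a),
                "mean_b": b.mean(),
                "sem_b": stats.sem(b),
                "diff": b.mean() - a.mean(),
                "t": float(t),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
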