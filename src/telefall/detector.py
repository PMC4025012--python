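"""Three-phase threshold fall detector and cancellable-alarm handling.

The detector scans the SVM feature series and classifies candidate impacts
into two alarm severities across three phases:

* **Phase 1 (critical)** — the peak ``SVM_xyz`` exceeds the maximum value
  any daily activity can produce (``th_high_xyz``, 6 G).
* **Phase 3 (critical)** — the horizontal magnitude ``SVM_xz`` exceeds
  ``th_xz`` (2 G) at some sample K, the body then comes to rest (static for
  ``rest_window_s``) within ``search_window_s`` after K at sample L, and
  the reference velocity integrated over [K, L] exceeds ``th_v`` (1.7 m/s).
* **Phase 2 (normal)** — the peak ``SVM_xyz`` exceeds ``th_low_xyz``
  (3.5 G), the ceiling of normal-speed daily activities.  Normal alarms are
  cancellable by pressing and holding the emergency button; critical alarms
  never are.

Phase precedence within a candidate window is critical-by-peak, then
critical-by-velocity, then normal, so a slow slump that a single peak
threshold would miss can still escalate to a critical alarm, and a hard
impact is never downgraded by its sub-6 G leading edge.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import yaml

from .accel import AccelTrace, EmptyTraceError, G_MPS2, compute_features, reference_velocity

CRITICAL = "critical"
NORMAL = "normal"

RAISED = "raised"
CANCELED = "canceled"
CONFIRMED = "confirmed"


class ConfigError(ValueError):
    """Detector configuration violates its invariants."""


@dataclass(frozen=True)
class DetectorConfig:
    """Thresholds and windows of the three-phase detector.

    The four physical thresholds carry the values calibrated for waist-worn
    sensors: ``th_high_xyz`` / ``th_low_xyz`` bound the peak SVM of fast and
    normal daily activities, ``th_xz`` is the horizontal-impact trigger and
    ``th_v`` the reference-velocity criterion.  The remaining fields are
    implementation parameters: what counts as "static", how long a phase-3
    search may look for the rest onset, duplicate-alarm suppression and the
    cancel-button protocol.
    """

    th_high_xyz: float = 6.0  # G
    th_low_xyz: float = 3.5  # G
    th_xz: float = 2.0  # G
    th_v: float = 1.7  # m/s
    rest_window_s: float = 0.3
    search_window_s: float = 2.0
    rest_epsilon_g: float = 0.2
    refractory_s: float = 2.0
    cancel_hold_s: float = 2.0
    cancel_timeout_s: float = 30.0
    g_mps2: float = G_MPS2

    def __post_init__(self) -> None:
        if not (0 < self.th_low_xyz < self.th_high_xyz):
            raise ConfigError("require 0 < th_low_xyz < th_high_xyz")
        if self.th_xz <= 0 or self.th_v <= 0:
            raise ConfigError("thresholds must be positive")
        if not (0 < self.rest_window_s < self.search_window_s):
            raise ConfigError("require 0 < rest_window_s < search_window_s")
        if self.rest_epsilon_g <= 0 or self.refractory_s <= 0:
            raise ConfigError("rest_epsilon_g and refractory_s must be positive")
        if self.cancel_hold_s < 0 or self.cancel_timeout_s < 0:
            raise ConfigError("cancellation durations must be non-negative")


@dataclass(frozen=True)
class FallEvent:
    """A detected fall alarm.

    ``severity`` is ``"critical"`` for phases 1 and 3 and ``"normal"`` for
    phase 2.  ``k_index``/``l_index`` and ``v_max`` are populated for
    phase-3 events only (the horizontal trigger K and rest onset L of the
    velocity integral).  ``status`` starts at ``"raised"`` and becomes
    ``"confirmed"`` or (normal events only) ``"canceled"`` once button
    presses are applied.
    """

    severity: str
    phase: int
    trigger_index: int
    trigger_time_s: float
    peak_svm_xyz: float
    k_index: Optional[int] = None
    l_index: Optional[int] = None
    v_max: Optional[float] = None
    status: str = RAISED

    def __post_init__(self) -> None:
        if self.phase in (1, 3):
            if self.severity != CRITICAL:
                raise ValueError("phase 1/3 events must be critical")
        elif self.phase == 2:
            if self.severity != NORMAL:
                raise ValueError("phase 2 events must be normal")
        else:
            raise ValueError(f"invalid phase {self.phase}")
        if self.phase == 3:
            if self.k_index is None or self.l_index is None or self.v_max is None:
                raise ValueError("phase 3 events require k_index, l_index, v_max")
            if not self.k_index < self.l_index:
                raise ValueError("phase 3 requires k_index < l_index")
        if self.status == CANCELED and self.severity != NORMAL:
            raise ValueError("only normal events can be canceled")


def detect(trace: AccelTrace, config: DetectorConfig = DetectorConfig()) -> list[FallEvent]:
    """Run the three-phase detector over a trace.

    Scans for candidate samples where any trigger condition holds
    (``svm_xyz > th_low_xyz`` or ``svm_xz > th_xz``), evaluates the phases
    in precedence order over a ``search_window_s`` evaluation window, and
    emits at most one event per ``refractory_s``.  Events are ordered by
    trigger index.  A trace shorter than the search window is processed
    with the window truncated at end of trace.
    """
    feats = compute_features(trace)
    s = feats.svm_xyz
    h = feats.svm_xz
    n = len(trace)
    fs = trace.sample_rate_hz

    win = max(1, int(round(config.search_window_s * fs)))
    rest_len = max(1, int(round(config.rest_window_s * fs)))
    refr = max(1, int(round(config.refractory_s * fs)))

    # rest_start[i] is True when samples i .. i+rest_len-1 are all static.
    static = np.abs(s - 1.0) <= config.rest_epsilon_g
    if n >= rest_len:
        runs = np.convolve(static.astype(int), np.ones(rest_len, dtype=int), mode="valid")
        rest_start = runs == rest_len  # length n - rest_len + 1
    else:
        rest_start = np.zeros(0, dtype=bool)

    trigger_idx = np.flatnonzero((s > config.th_low_xyz) | (h > config.th_xz))

    events: list[FallEvent] = []
    cursor = 0
    ptr = 0
    while ptr < trigger_idx.size:
        ptr = int(np.searchsorted(trigger_idx, cursor))
        if ptr >= trigger_idx.size:
            break
        i0 = int(trigger_idx[ptr])
        end = min(i0 + win, n)
        window_s = s[i0:end]
        peak = float(window_s.max())

        emitted: Optional[FallEvent] = None

        # Phase 1: critical by high peak.
        over_high = np.flatnonzero(window_s > config.th_high_xyz)
        if over_high.size:
            trig = i0 + int(over_high[0])
            emitted = FallEvent(
                severity=CRITICAL,
                phase=1,
                trigger_index=trig,
                trigger_time_s=trace.time_at(trig),
                peak_svm_xyz=peak,
            )

        # Phase 3: critical by reference velocity.
        if emitted is None:
            over_xz = np.flatnonzero(h[i0:end] > config.th_xz)
            if over_xz.size:
                k = i0 + int(over_xz[0])
                # Rest onset L strictly after K, starting within the search
                # window; the full rest run must fit inside the trace.
                lo = k + 1
                hi = min(k + win, rest_start.size - 1)
                if lo <= hi:
                    hits = np.flatnonzero(rest_start[lo : hi + 1])
                    if hits.size:
                        l = lo + int(hits[0])
                        v = reference_velocity(trace, k, l, config.g_mps2)
                        if v > config.th_v:
                            emitted = FallEvent(
                                severity=CRITICAL,
                                phase=3,
                                trigger_index=k,
                                trigger_time_s=trace.time_at(k),
                                peak_svm_xyz=peak,
                                k_index=k,
                                l_index=l,
                                v_max=v,
                            )

        # Phase 2: normal by low peak.
        if emitted is None:
            over_low = np.flatnonzero(window_s > config.th_low_xyz)
            if over_low.size:
                trig = i0 + int(over_low[0])
                emitted = FallEvent(
                    severity=NORMAL,
                    phase=2,
                    trigger_index=trig,
                    trigger_time_s=trace.time_at(trig),
                    peak_svm_xyz=peak,
                )

        if emitted is not None:
            events.append(emitted)
            cursor = emitted.trigger_index + refr
        else:
            cursor = i0 + 1
    return events


def apply_cancellation(
    events: Sequence[FallEvent],
    button_presses: Iterable[Tuple[float, float]],
    config: DetectorConfig = DetectorConfig(),
) -> list[FallEvent]:
    """Resolve alarm statuses against emergency-button presses.

    A press is a ``(press_time_s, hold_duration_s)`` pair.  A normal event
    is canceled iff some press starts within ``cancel_timeout_s`` after its
    trigger time and is held for at least ``cancel_hold_s``; every other
    event — including every critical event, which can never be canceled —
    is confirmed.
    """
    presses = sorted(button_presses)
    for _, hold in presses:
        if hold < 0:
            raise ValueError("button hold duration must be non-negative")
    out: list[FallEvent] = []
    for ev in events:
        status = CONFIRMED
        if ev.severity == NORMAL:
            for press_t, hold in presses:
                in_window = ev.trigger_time_s <= press_t <= ev.trigger_time_s + config.cancel_timeout_s
                if in_window and hold >= config.cancel_hold_s:
                    status = CANCELED
                    break
        out.append(dataclasses.replace(ev, status=status))
    return out


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def event_to_record(event: FallEvent) -> dict:
    """JSON-lines record for one event."""
    return {
        "t": event.trigger_time_s,
        "severity": event.severity,
        "phase": event.phase,
        "peak_svm_xyz": event.peak_svm_xyz,
        "v_max": event.v_max,
        "status": event.status,
    }


def write_events_jsonl(events: Sequence[FallEvent], path) -> None:
    with open(path, "w") as fh:
        for ev in events:
            fh.write(json.dumps(event_to_record(ev)) + "\n")


def load_detector_config(path, **overrides) -> DetectorConfig:
    """Load a DetectorConfig from a YAML or JSON file; kwargs override."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    known = {f.name for f in dataclasses.fields(DetectorConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return DetectorConfig(**data)
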