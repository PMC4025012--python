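"""Synthetic accelerometer traces and RSSI collection rounds.

No public dataset accompanies waist-worn fall studies at this scale, so the
package ships generators for both inputs the system needs:

* **Accelerometer traces.**  A fall follows the classic three-stage
  signature — an optional sub-1 G free-fall dip, an impact spike, then a
  post-impact rest near 1 G — layered after a pre-fall activity segment.
  Daily activities (ADLs) are oscillatory or bump-like signatures whose
  peak SVM stays below the normal-activity ceiling (3.5 G) at normal speed
  and may exceed it for violent variants (fast jumps, fast stairs), which
  by design can raise false alarms just as acute activities do in
  practice.  The impact spike is a half-sine (optionally with a plateau at
  the peak), split across axes by a per-direction horizontal fraction so
  that lateral falls load the x axis and front/posterior falls the z axis;
  Gaussian jitter (default 0.05 G per axis) roughens every segment.  Every
  trace carries ground-truth labels so detector evaluation is
  self-contained.

* **RSSI rounds.**  Given a node layout, one collection round broadcasts
  from each RF generator in turn; every observer (the wearable plus each
  reference node) reports one integer RSSI per generator, drawn from the
  log-distance path-loss model with seeded Gaussian shadowing and the
  calibrated dBm-to-RSSI map.  The default layout reconstructs the
  reference deployment: an 11 x 5.75 m room with 18 reference nodes on a
  2 m grid and 5 generators placed symmetrically (center + quadrant
  centers), gateway at the room center.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .accel import AccelTrace, G_MPS2
from .locator import LayoutError, NodeLayout, NodePosition, RssiRound
from .rssi import (
    PathLossParams,
    RssiClassTable,
    calibrate_rssi_map,
    dbm_to_rssi,
    default_class_table,
    path_loss_power,
)


class ScenarioError(ValueError):
    """A scenario combination outside the supported taxonomy."""


class GeometryError(ValueError):
    """The wearable position is outside the room."""


FALL = "fall"
ADL = "adl"

FALL_DIRECTIONS = ("front", "posterior", "left-lateral", "right-lateral")

#: The 28 valid (pre-activity, fall-direction) pairs.  Walk-backward falls
#: cannot go forward; the lie-then-turn fall rolls off the bed on the worn
#: (left) side.
VALID_FALL_PAIRS: Dict[str, Tuple[str, ...]] = {
    "stand": FALL_DIRECTIONS,
    "sit-to-stand": FALL_DIRECTIONS,
    "stand-to-sit": FALL_DIRECTIONS,
    "walk": FALL_DIRECTIONS,
    "stoop": FALL_DIRECTIONS,
    "jump": FALL_DIRECTIONS,
    "walk-backward": ("posterior", "left-lateral", "right-lateral"),
    "lie-then-turn": ("left-lateral",),
}

ADL_ACTIVITIES = ("stand-up", "sit-down", "lie-on-bed", "walk", "jump", "stairs", "run")
ADL_SPEEDS = ("normal", "fast")

#: Direction -> (axis, sign) for the dominant horizontal impact component.
_DIRECTION_AXIS = {
    "front": ("az", 1.0),
    "posterior": ("az", -1.0),
    "right-lateral": ("ax", 1.0),
    "left-lateral": ("ax", -1.0),
}

#: Default fraction of the impact SVM carried by the horizontal plane.
_DEFAULT_HORIZONTAL_FRACTION = {
    "front": 0.65,
    "posterior": 0.65,
    "right-lateral": 0.7,
    "left-lateral": 0.7,
}


@dataclass(frozen=True)
class FallScenario:
    """Parameters of one simulated fall.

    The physical fields describe the three-stage signature (impact peak in
    G, free-fall dip depth below 1 G and its duration, post-impact rest
    duration); the remaining knobs expose the trace morphology: pre-fall
    activity duration, impact pulse width, an optional plateau at the peak
    (sustained deceleration, as in a slump against furniture), the
    horizontal fraction of the impact (per-direction default when None)
    and the jitter level.
    """

    pre_activity: str = "stand"
    direction: str = "front"
    impact_peak: float = 5.0  # G
    free_fall_depth: float = 0.6  # G below 1 G
    free_fall_duration: float = 0.25  # s
    rest_duration: float = 1.0  # s
    seed: int = 0
    pre_duration: float = 1.0  # s
    impact_duration: float = 0.12  # s
    sustain_duration: float = 0.0  # s, plateau at the peak
    horizontal_fraction: Optional[float] = None
    jitter_g: float = 0.05

    def __post_init__(self) -> None:
        if self.pre_activity not in VALID_FALL_PAIRS:
            raise ScenarioError(f"unknown pre-fall activity {self.pre_activity!r}")
        if self.direction not in VALID_FALL_PAIRS[self.pre_activity]:
            raise ScenarioError(
                f"direction {self.direction!r} not valid after {self.pre_activity!r}"
            )
        if not self.impact_peak > 1:
            raise ScenarioError("impact_peak must exceed 1 G")
        if self.rest_duration < 0.3:
            raise ScenarioError("ground-truth falls need rest_duration >= 0.3 s")
        if not (0 <= self.free_fall_depth <= 1):
            raise ScenarioError("free_fall_depth must lie in [0, 1] G")
        if self.horizontal_fraction is not None and not (0 <= self.horizontal_fraction < 1):
            raise ScenarioError("horizontal_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class AdlScenario:
    """Parameters of one simulated daily activity."""

    activity: str = "walk"
    speed: str = "normal"
    duration: float = 5.0  # s
    seed: int = 0
    jitter_g: float = 0.05

    def __post_init__(self) -> None:
        if self.activity not in ADL_ACTIVITIES:
            raise ScenarioError(f"unknown activity {self.activity!r}")
        if self.speed not in ADL_SPEEDS:
            raise ScenarioError(f"unknown speed {self.speed!r}")
        if self.activity == "run" and self.speed != "normal":
            raise ScenarioError("run is only simulated at normal speed")
        if self.duration <= 0:
            raise ScenarioError("duration must be positive")


# ---------------------------------------------------------------------------
# SVM profile construction
# ---------------------------------------------------------------------------


def _pre_activity_profile(activity: str, n: int, fs: float) -> np.ndarray:
    """Designed SVM profile (in G) of the pre-fall activity segment."""
    if n == 0:
        return np.ones(0)
    t = np.arange(n) / fs
    if activity in ("stand", "lie-then-turn"):
        return np.ones(n)
    if activity in ("walk", "walk-backward"):
        amp = 0.4 if activity == "walk" else 0.35
        return 1.0 + 0.5 * amp * (1 - np.cos(2 * math.pi * 2.0 * t))
    if activity in ("sit-to-stand", "stand-to-sit", "stoop"):
        peak = {"sit-to-stand": 0.5, "stand-to-sit": 0.4, "stoop": -0.3}[activity]
        return 1.0 + peak * np.sin(math.pi * np.clip(t / max(float(t[-1]), 1e-9), 0, 1))
    if activity == "jump":
        return 1.0 + 1.5 * np.maximum(0.0, np.sin(2 * math.pi * 1.5 * t)) ** 2
    raise ScenarioError(f"unknown pre-fall activity {activity!r}")


def _impact_profile(scn: FallScenario, fs: float) -> np.ndarray:
    """Designed SVM of dip + impact: half-sine spike with optional plateau."""
    base = 1.0 - scn.free_fall_depth
    dip_n = int(round(scn.free_fall_duration * fs)) if scn.free_fall_depth > 0 else 0
    ramp_n = max(2, int(round(scn.impact_duration * fs / 2)))
    sus_n = int(round(scn.sustain_duration * fs))

    parts = []
    if dip_n:
        parts.append(np.linspace(1.0, base, dip_n, endpoint=False))
    up = base + (scn.impact_peak - base) * np.sin(
        0.5 * math.pi * np.arange(ramp_n) / ramp_n
    )
    parts.append(up)
    if sus_n:
        parts.append(np.full(sus_n, scn.impact_peak))
    down = 1.0 + (scn.impact_peak - 1.0) * np.sin(
        0.5 * math.pi * (1.0 - np.arange(1, ramp_n + 1) / ramp_n)
    )
    parts.append(down)
    return np.concatenate(parts)


def _assemble_trace(
    svm: np.ndarray,
    frac: np.ndarray,
    axis: str,
    sign: float,
    jitter_g: float,
    rng: np.random.Generator,
    sample_rate_hz: float,
) -> AccelTrace:
    """Distribute a designed SVM profile across axes and add jitter.

    The dominant horizontal axis carries ``sign * frac * svm``; the
    vertical axis carries the remainder so the designed SVM is exact
    before jitter.
    """
    horiz = sign * frac * svm
    vert = svm * np.sqrt(1.0 - frac**2)
    axes = {"ax": np.zeros_like(svm), "ay": vert, "az": np.zeros_like(svm)}
    axes[axis] = axes[axis] + horiz
    if jitter_g > 0:
        for k in axes:
            axes[k] = axes[k] + rng.normal(0.0, jitter_g, size=svm.shape)
    return AccelTrace(ax=axes["ax"], ay=axes["ay"], az=axes["az"], sample_rate_hz=sample_rate_hz)


def generate_fall_trace(
    scenario: FallScenario,
    sample_rate_hz: float = 200.0,
) -> Tuple[AccelTrace, dict]:
    """Synthesize one fall trace with ground-truth labels.

    Returns ``(trace, labels)`` where labels carry the true class
    (``"fall"``), the fall interval in seconds, and the severity class the
    designed morphology implies under the default thresholds (computed
    from the noise-free profile, independently of the detector):
    ``"critical"`` when the peak exceeds 6 G or when the designed
    horizontal trigger plus velocity integral satisfy the phase-3
    criterion, ``"normal"`` above 3.5 G, else ``None``.
    """
    fs = sample_rate_hz
    rng = np.random.default_rng(scenario.seed)

    pre_n = int(round(scenario.pre_duration * fs))
    pre = _pre_activity_profile(scenario.pre_activity, pre_n, fs)
    impact = _impact_profile(scenario, fs)
    rest_n = int(round(scenario.rest_duration * fs))
    rest = np.ones(rest_n)

    svm = np.concatenate([pre, impact, rest])
    frac_default = _DEFAULT_HORIZONTAL_FRACTION[scenario.direction]
    f_impact = scenario.horizontal_fraction if scenario.horizontal_fraction is not None else frac_default
    frac = np.concatenate(
        [np.full(pre.size, 0.2), np.full(impact.size, f_impact), np.full(rest_n, 0.0)]
    )
    axis, sign = _DIRECTION_AXIS[scenario.direction]
    trace = _assemble_trace(svm, frac, axis, sign, scenario.jitter_g, rng, fs)

    labels = {
        "label": FALL,
        "fall_start_s": pre.size / fs,
        "fall_end_s": (pre.size + impact.size) / fs,
        "expected_severity": _designed_severity(svm, frac, pre.size, pre.size + impact.size, fs),
    }
    return trace, labels


def _designed_severity(
    svm: np.ndarray,
    frac: np.ndarray,
    impact_start: int,
    rest_start: int,
    fs: float,
    th_high: float = 6.0,
    th_low: float = 3.5,
    th_xz: float = 2.0,
    th_v: float = 1.7,
) -> Optional[str]:
    """Severity implied by the noise-free designed profile (label oracle)."""
    peak = float(svm[impact_start:].max()) if impact_start < svm.size else 0.0
    if peak > th_high:
        return "critical"
    horiz = frac * svm
    over = np.flatnonzero(horiz[impact_start:] > th_xz)
    if over.size:
        k = impact_start + int(over[0])
        l = max(rest_start, k + 1)
        if l < svm.size:
            v = float(np.trapezoid((svm[k : l + 1] - 1.0) * G_MPS2, dx=1.0 / fs))
            if v > th_v:
                return "critical"
    if peak > th_low:
        return "normal"
    return None


#: (peak excess in G at normal speed, at fast speed, oscillation Hz or None)
_ADL_PARAMS = {
    "stand-up": (0.8, 1.8, None),
    "sit-down": (0.6, 2.0, None),
    "lie-on-bed": (0.5, 2.9, None),
    "walk": (0.4, 0.9, 2.0),
    "jump": (2.2, 5.6, 1.2),
    "stairs": (1.2, 3.2, 1.6),
    "run": (1.6, 1.6, 2.8),
}


def generate_adl_trace(
    scenario: AdlScenario,
    sample_rate_hz: float = 200.0,
) -> Tuple[AccelTrace, dict]:
    """Synthesize one daily-activity trace with its ground-truth label.

    Normal-speed house activities stay below the 3.5 G normal-fall
    threshold; fast variants of the violent activities (jump, stairs,
    lie-on-bed) may exceed it — or, for fast jumps, the 6 G critical
    threshold — producing the designed false alarms acute activities cause.
    """
    fs = sample_rate_hz
    rng = np.random.default_rng(scenario.seed)
    n = max(2, int(round(scenario.duration * fs)))
    t = np.arange(n) / fs
    amp_normal, amp_fast, freq = _ADL_PARAMS[scenario.activity]
    amp = amp_normal if scenario.speed == "normal" else amp_fast

    if freq is not None:
        f = freq * (1.4 if scenario.speed == "fast" else 1.0)
        svm = 1.0 + amp * np.maximum(0.0, np.sin(2 * math.pi * f * t)) ** 2
    else:
        # single smooth bump with a small leading dip (posture transition)
        phase = np.clip(t / scenario.duration, 0, 1)
        svm = 1.0 + amp * np.sin(math.pi * phase) ** 2 - 0.2 * np.sin(2 * math.pi * phase)

    frac = np.full(n, 0.3)
    trace = _assemble_trace(svm, frac, "az", 1.0, scenario.jitter_g, rng, fs)
    labels = {"label": ADL, "activity": scenario.activity, "speed": scenario.speed}
    return trace, labels


# ---------------------------------------------------------------------------
# Layout and RSSI round simulation
# ---------------------------------------------------------------------------


def grid_layout(
    room_length: float = 11.0,
    room_width: float = 5.75,
    node_spacing: float = 2.0,
    n_generators: int = 5,
) -> NodeLayout:
    """Regular-grid deployment reconstruction.

    Reference nodes sit on a centered grid at ``node_spacing`` intervals
    (the default reproduces 18 nodes in an 11 x 5.75 m room); generators
    are placed symmetrically — quadrant centers in pairs, plus the room
    center when the count is odd — and the gateway at the room center.
    """
    if room_length <= 0 or room_width <= 0 or node_spacing <= 0:
        raise LayoutError("room dimensions and spacing must be positive")
    if node_spacing > room_length or node_spacing > room_width:
        raise LayoutError("node spacing exceeds the room dimensions")

    nx = int(math.floor(room_length / node_spacing + 1e-9)) + 1
    ny = int(math.floor(room_width / node_spacing + 1e-9)) + 1
    mx = (room_length - (nx - 1) * node_spacing) / 2
    my = (room_width - (ny - 1) * node_spacing) / 2
    refs = []
    k = 0
    for iy in range(ny):
        for ix in range(nx):
            k += 1
            refs.append(
                NodePosition(f"ref{k:02d}", mx + ix * node_spacing, my + iy * node_spacing)
            )

    lx, wy = room_length, room_width
    center = (lx / 2, wy / 2)
    pair_positions = [
        (lx / 4, wy / 4),
        (3 * lx / 4, 3 * wy / 4),
        (3 * lx / 4, wy / 4),
        (lx / 4, 3 * wy / 4),
        (lx / 2, wy / 4),
        (lx / 2, 3 * wy / 4),
        (lx / 4, wy / 2),
        (3 * lx / 4, wy / 2),
    ]
    positions = ([center] if n_generators % 2 else []) + pair_positions
    if n_generators < 1 or n_generators > len(positions):
        raise LayoutError(f"n_generators must lie in 1..{len(positions)}")
    gens = [
        NodePosition(f"gen{i + 1}", x, y) for i, (x, y) in enumerate(positions[:n_generators])
    ]
    return NodeLayout(
        room_length=room_length,
        room_width=room_width,
        reference_nodes=tuple(refs),
        rf_generators=tuple(gens),
        gateway=center,
    )


#: Minimum geometric distance fed to the path-loss law, meters; prevents a
#: singular power for an observer co-located with a generator.
MIN_RADIO_DISTANCE_M = 1e-3


def simulate_round(
    layout: NodeLayout,
    wearable_position: Tuple[float, float],
    pl: PathLossParams = PathLossParams(),
    table: Optional[RssiClassTable] = None,
    seed: int = 0,
    averaging: int = 1,
    drop_probability: float = 0.0,
) -> RssiRound:
    """Simulate one RSSI collection round.

    Each generator broadcasts in turn; the wearable and every reference
    node observe one RSSI value per generator: the log-distance power at
    their geometric distance, plus seeded Gaussian shadowing of
    ``pl.sigma_db``, passed through the calibrated linear dBm-to-RSSI map.
    ``averaging`` > 1 averages that many integer readings per entry.
    ``drop_probability`` > 0 marks entries as missing (an extension, off
    by default); missing entries are masked out of distance computations.
    """
    x, y = wearable_position
    if not layout.contains(x, y):
        raise GeometryError(f"wearable position ({x}, {y}) outside room")
    if averaging < 1:
        raise ValueError("averaging count must be >= 1")
    if not (0 <= drop_probability < 1):
        raise ValueError("drop_probability must lie in [0, 1)")
    table = table or default_class_table()
    slope, intercept = calibrate_rssi_map(pl)
    rng = np.random.default_rng(seed)

    observers = np.vstack([[x, y], layout.reference_coords()])
    gens = np.array([[g.x, g.y] for g in layout.rf_generators])
    n_obs, n_gen = observers.shape[0], gens.shape[0]

    values = np.zeros((n_obs, n_gen), dtype=int)
    for j in range(n_gen):  # generators broadcast in turn
        d = np.hypot(observers[:, 0] - gens[j, 0], observers[:, 1] - gens[j, 1])
        d = np.maximum(d, MIN_RADIO_DISTANCE_M)
        for i in range(n_obs):
            readings = []
            for _ in range(averaging):
                noise = rng.normal(0.0, pl.sigma_db) if pl.sigma_db > 0 else 0.0
                power = path_loss_power(float(d[i]), pl, noise)
                readings.append(dbm_to_rssi(power, slope, intercept))
            values[i, j] = int(round(float(np.mean(readings))))

    kwargs = {}
    if drop_probability > 0:
        observed = rng.random((n_obs, n_gen)) >= drop_probability
        kwargs = {
            "wearable_mask": observed[0],
            "reference_mask": observed[1:],
        }
    return RssiRound(
        wearable=values[0],
        references=values[1:],
        reference_ids=tuple(n.id for n in layout.reference_nodes),
        generator_ids=tuple(g.id for g in layout.rf_generators),
        **kwargs,
    )
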