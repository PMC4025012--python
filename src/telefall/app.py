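"""End-to-end orchestration and detector evaluation.

The system couples the two engines: the wearable continuously runs the
fall detector, and every confirmed (non-canceled) alarm triggers one RSSI
collection round and a position estimate, so caregivers receive both the
alarm and the faller's indoor location.  This module also provides the
confusion-matrix evaluation used to score the detector (falls are the
positive class).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence, Tuple

import numpy as np

from .accel import AccelTrace
from .detector import (
    CANCELED,
    DetectorConfig,
    FallEvent,
    apply_cancellation,
    detect,
    event_to_record,
)
from .locator import (
    NodeLayout,
    PositionEstimate,
    RssiRound,
    estimate_position,
    estimate_to_dict,
    weight_round,
)
from .rssi import PathLossParams, RssiClassTable, default_class_table
from .simulator import simulate_round

logger = logging.getLogger("telefall")

FALL_LABEL = "fall"
ADL_LABEL = "adl"


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts with falls as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn < 1:
            raise ValueError("confusion counts must describe at least one case")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _ratio(num: int, den: int) -> float:
    """A metric ratio; undefined denominators yield NaN, never 0."""
    return num / den if den > 0 else math.nan


def metrics_from_counts(counts: ConfusionCounts) -> dict:
    return {
        "sensitivity": _ratio(counts.tp, counts.tp + counts.fn),
        "specificity": _ratio(counts.tn, counts.tn + counts.fp),
        "accuracy": _ratio(counts.tp + counts.tn, counts.total),
        "precision": _ratio(counts.tp, counts.tp + counts.fp),
    }


def evaluate_detector(
    pairs: Iterable[Tuple[str, str]],
) -> Tuple[ConfusionCounts, dict]:
    """Score (ground-truth, predicted) label pairs.

    Labels are ``"fall"`` or ``"adl"``.  Returns the confusion counts and
    the four standard metrics; ratios with a zero denominator are NaN.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no label pairs to evaluate")
    tp = fp = tn = fn = 0
    for truth, pred in pairs:
        if truth not in (FALL_LABEL, ADL_LABEL) or pred not in (FALL_LABEL, ADL_LABEL):
            raise ValueError(f"labels must be '{FALL_LABEL}' or '{ADL_LABEL}', got ({truth!r}, {pred!r})")
        if truth == FALL_LABEL:
            tp += pred == FALL_LABEL
            fn += pred == ADL_LABEL
        else:
            fp += pred == FALL_LABEL
            tn += pred == ADL_LABEL
    counts = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
    return counts, metrics_from_counts(counts)


def derive_seed(seed: int, index: int) -> int:
    """Deterministic per-event sub-seed below 2^31."""
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))


def run_pipeline(
    trace: AccelTrace,
    layout: NodeLayout,
    wearable_position: Tuple[float, float],
    detector_config: DetectorConfig = DetectorConfig(),
    pl_params: PathLossParams = PathLossParams(sigma_db=2.0),
    class_table: Optional[RssiClassTable] = None,
    p: int = 4,
    use_weighting: bool = True,
    button_presses: Sequence[Tuple[float, float]] = (),
    seed: int = 0,
    round_provider: Optional[Callable[[FallEvent], RssiRound]] = None,
) -> list[Tuple[FallEvent, Optional[PositionEstimate]]]:
    """Detect falls and localize the wearer for each confirmed alarm.

    Runs the detector, resolves alarm statuses against the button presses,
    and for every confirmed event performs one RSSI collection round
    (simulated at ``wearable_position``, or supplied by
    ``round_provider``) followed by a position estimate.  Canceled normal
    events yield no position.  Fully deterministic given the seed.
    """
    table = class_table or default_class_table()
    events = detect(trace, detector_config)
    resolved = apply_cancellation(events, button_presses, detector_config)
    logger.info("detector: %d event(s), seed=%d", len(resolved), seed)

    results: list[Tuple[FallEvent, Optional[PositionEstimate]]] = []
    for idx, ev in enumerate(resolved):
        if ev.status == CANCELED:
            logger.info("event %d canceled; no positioning round", idx)
            results.append((ev, None))
            continue
        if round_provider is not None:
            rnd = round_provider(ev)
        else:
            rnd = simulate_round(
                layout, wearable_position, pl_params, table, seed=derive_seed(seed, idx)
            )
        if use_weighting and not rnd.is_weighted:
            rnd = weight_round(rnd, table)
        est = estimate_position(rnd, layout, p=p, use_weighting=use_weighting)
        logger.info(
            "event %d (%s, phase %d) localized at (%.2f, %.2f)",
            idx, ev.severity, ev.phase, est.x, est.y,
        )
        results.append((ev, est))
    return results


def pipeline_to_json(
    results: Sequence[Tuple[FallEvent, Optional[PositionEstimate]]],
    p: Optional[int] = None,
) -> str:
    """Deterministic JSON rendering of pipeline output."""
    payload = [
        {
            "event": event_to_record(ev),
            "position": estimate_to_dict(est, p) if est is not None else None,
        }
        for ev, est in results
    ]
    return json.dumps(payload, indent=2, sort_keys=True)
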