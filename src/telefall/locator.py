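"""Weighted-RSSI k-nearest-neighbor indoor positioning.

One collection round gives every observer (the wearable plus M fixed
reference nodes at known coordinates) an RSSI vector over the N fixed RF
generators.  The wearable's position is estimated LANDMARC-style:

1. Euclidean distance in RSSI space between the wearable's vector W and
   each reference node's vector R_i, ``e_i = ||W - R_i||`` — computed on
   weighted RSSI values (the per-class affine transform) when enabled;
2. the p reference nodes with the smallest distances are selected
   (default p = 4, the value that minimizes the error distance);
3. the estimate is the convex combination of their coordinates under
   normalized inverse-square weights ``w_k = (1/e_k^2) / sum(1/e_i^2)``,
   so the nearest node in RSSI space carries the largest weight.

Performance is scored by the error distance — the planar Euclidean
distance between estimated and true positions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .rssi import InvalidRssiError, RssiClassTable, weight_rssi


class DimensionError(ValueError):
    """RSSI vector/matrix dimensions do not match."""


class LayoutError(ValueError):
    """A node layout violates its invariants."""


class LocatorConfigError(ValueError):
    """Invalid positioning configuration (e.g. p exceeds node count)."""


WEARABLE_ID = "wearable"


@dataclass(frozen=True)
class NodePosition:
    id: str
    x: float
    y: float

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass(frozen=True)
class NodeLayout:
    """Planar deployment: room bounds and node coordinates in meters.

    Coordinates use a room-corner origin with x along the length axis.
    """

    room_length: float
    room_width: float
    reference_nodes: Tuple[NodePosition, ...]
    rf_generators: Tuple[NodePosition, ...]
    gateway: Tuple[float, float]

    def __post_init__(self) -> None:
        if self.room_length <= 0 or self.room_width <= 0:
            raise LayoutError("room dimensions must be positive")
        if len(self.reference_nodes) < 1 or len(self.rf_generators) < 1:
            raise LayoutError("need at least one reference node and one generator")
        ids = [n.id for n in self.reference_nodes] + [n.id for n in self.rf_generators]
        if len(set(ids)) != len(ids):
            raise LayoutError("node ids must be unique")
        for node in (*self.reference_nodes, *self.rf_generators):
            if not (0 <= node.x <= self.room_length and 0 <= node.y <= self.room_width):
                raise LayoutError(f"node {node.id} at ({node.x}, {node.y}) outside room")
        gx, gy = self.gateway
        if not (0 <= gx <= self.room_length and 0 <= gy <= self.room_width):
            raise LayoutError("gateway outside room")

    @property
    def m(self) -> int:
        """Number of reference nodes."""
        return len(self.reference_nodes)

    @property
    def n(self) -> int:
        """Number of RF generators."""
        return len(self.rf_generators)

    def reference_coords(self) -> np.ndarray:
        return np.array([[p.x, p.y] for p in self.reference_nodes])

    def contains(self, x: float, y: float) -> bool:
        return 0 <= x <= self.room_length and 0 <= y <= self.room_width


@dataclass(frozen=True)
class RssiRound:
    """One collection round of RSSI observations.

    ``wearable`` is the wearable sensor's length-N RSSI vector over the
    generators; ``references`` is the M x N matrix with row i the i-th
    reference node's vector.  Raw entries are integers on 0-255; the
    ``weighted_*`` fields hold the transformed real-valued copies once
    :func:`weight_round` has been applied.
    """

    wearable: np.ndarray
    references: np.ndarray
    reference_ids: Tuple[str, ...]
    generator_ids: Tuple[str, ...]
    weighted_wearable: Optional[np.ndarray] = None
    weighted_references: Optional[np.ndarray] = None
    # Optional observation masks (True = observed); entries masked False in
    # either the wearable's or a reference's vector are excluded pairwise
    # from that node's distance.  Only populated by the packet-drop
    # extension of the simulator; None means fully observed.
    wearable_mask: Optional[np.ndarray] = None
    reference_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        w = np.asarray(self.wearable)
        r = np.asarray(self.references)
        object.__setattr__(self, "wearable", w)
        object.__setattr__(self, "references", r)
        if w.ndim != 1 or r.ndim != 2:
            raise DimensionError("wearable must be a vector, references a matrix")
        if r.shape != (len(self.reference_ids), len(self.generator_ids)):
            raise DimensionError("references shape must be (len(reference_ids), len(generator_ids))")
        if w.shape[0] != len(self.generator_ids):
            raise DimensionError("wearable length must equal the number of generators")
        for arr in (w, r):
            if not np.issubdtype(arr.dtype, np.integer):
                raise InvalidRssiError("raw RSSI entries must be integers")
            if arr.size and (arr.min() < 0 or arr.max() > 255):
                raise InvalidRssiError("raw RSSI entries must lie in 0-255")
        if (self.wearable_mask is None) != (self.reference_mask is None):
            raise DimensionError("masks must be supplied together or not at all")
        if self.wearable_mask is not None:
            wm = np.asarray(self.wearable_mask, dtype=bool)
            rm = np.asarray(self.reference_mask, dtype=bool)
            if wm.shape != w.shape or rm.shape != r.shape:
                raise DimensionError("mask shapes must match the RSSI arrays")
            object.__setattr__(self, "wearable_mask", wm)
            object.__setattr__(self, "reference_mask", rm)

    @property
    def is_weighted(self) -> bool:
        return self.weighted_wearable is not None


@dataclass(frozen=True)
class PositionEstimate:
    """Estimated planar position with its supporting neighbors.

    ``neighbors`` holds the p selected reference nodes as
    ``(id, rssi_space_distance, weight)`` triples ordered by increasing
    distance; ``distances`` is the full length-M distance vector in
    layout order.
    """

    x: float
    y: float
    neighbors: Tuple[Tuple[str, float, float], ...]
    distances: np.ndarray

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y])


def rssi_distance(w: np.ndarray, r_i: np.ndarray) -> float:
    """Euclidean distance between two RSSI vectors (raw or weighted)."""
    w = np.asarray(w, dtype=float)
    r_i = np.asarray(r_i, dtype=float)
    if w.shape != r_i.shape or w.ndim != 1 or w.size < 1:
        raise DimensionError(f"RSSI vectors must share a length >= 1, got {w.shape} vs {r_i.shape}")
    return float(np.linalg.norm(w - r_i))


def weight_round(rnd: RssiRound, table: RssiClassTable) -> RssiRound:
    """Fill a round's weighted copies by applying the class transform.

    Raw entries are untouched.  Applying the transform to an
    already-weighted round is a contract violation (weighted values are
    reals outside the integer RSSI domain).
    """
    if rnd.is_weighted:
        raise InvalidRssiError("round is already weighted; transform is not idempotent")
    lut = np.array([weight_rssi(v, table) for v in range(256)])
    return dataclasses.replace(
        rnd,
        weighted_wearable=lut[rnd.wearable],
        weighted_references=lut[rnd.references],
    )


def _knn_weights(distances: np.ndarray) -> np.ndarray:
    """Normalized inverse-square weights; zero distances absorb all mass."""
    zero = distances == 0
    if zero.any():
        w = np.zeros_like(distances, dtype=float)
        w[zero] = 1.0 / zero.sum()
        return w
    inv = 1.0 / distances**2
    return inv / inv.sum()


def estimate_position(
    rnd: RssiRound,
    layout: NodeLayout,
    p: int = 4,
    use_weighting: bool = True,
) -> PositionEstimate:
    """Weighted p-nearest-neighbor position estimate for one round.

    Distances are computed against every reference node on weighted RSSI
    (requiring :func:`weight_round` to have run) or on raw values; the p
    smallest select the neighbors, ties at the p-th distance broken by
    ascending reference-node id.
    """
    if not (1 <= p <= layout.m):
        raise LocatorConfigError(f"p must satisfy 1 <= p <= {layout.m}, got {p}")
    if tuple(n.id for n in layout.reference_nodes) != rnd.reference_ids:
        raise DimensionError("round reference ids do not match layout")
    if rnd.wearable.size < 1:
        raise DimensionError("empty round")
    if use_weighting:
        if not rnd.is_weighted:
            raise LocatorConfigError("use_weighting requires a weighted round (run weight_round)")
        w_vec = rnd.weighted_wearable
        r_mat = rnd.weighted_references
    else:
        w_vec = rnd.wearable.astype(float)
        r_mat = rnd.references.astype(float)

    if rnd.wearable_mask is not None:
        distances = np.empty(layout.m)
        for i in range(layout.m):
            shared = rnd.wearable_mask & rnd.reference_mask[i]
            if not shared.any():
                distances[i] = np.inf  # no common observation; never nearest
            else:
                distances[i] = rssi_distance(w_vec[shared], r_mat[i][shared])
    else:
        distances = np.array([rssi_distance(w_vec, r_mat[i]) for i in range(layout.m)])
    order = sorted(range(layout.m), key=lambda i: (distances[i], rnd.reference_ids[i]))
    chosen = order[:p]
    d_sel = distances[chosen]
    weights = _knn_weights(d_sel)
    coords = layout.reference_coords()[chosen]
    xy = weights @ coords
    neighbors = tuple(
        (rnd.reference_ids[i], float(distances[i]), float(w))
        for i, w in zip(chosen, weights)
    )
    return PositionEstimate(x=float(xy[0]), y=float(xy[1]), neighbors=neighbors, distances=distances)


def error_distance(estimate: Sequence[float], truth: Sequence[float]) -> float:
    """Planar Euclidean distance in meters between estimate and truth."""
    ex, ey = float(estimate[0]), float(estimate[1])
    tx, ty = float(truth[0]), float(truth[1])
    if not all(np.isfinite([ex, ey, tx, ty])):
        raise ValueError("coordinates must be finite")
    return float(np.hypot(ex - tx, ey - ty))


# ---------------------------------------------------------------------------
# Serialization: layout (JSON/YAML), round (CSV), estimate (JSON)
# ---------------------------------------------------------------------------


def layout_to_dict(layout: NodeLayout) -> dict:
    return {
        "room": {"length": layout.room_length, "width": layout.room_width},
        "reference_nodes": [{"id": p.id, "x": p.x, "y": p.y} for p in layout.reference_nodes],
        "rf_generators": [{"id": p.id, "x": p.x, "y": p.y} for p in layout.rf_generators],
        "gateway": {"x": layout.gateway[0], "y": layout.gateway[1]},
    }


def layout_from_dict(data: dict) -> NodeLayout:
    return NodeLayout(
        room_length=float(data["room"]["length"]),
        room_width=float(data["room"]["width"]),
        reference_nodes=tuple(
            NodePosition(str(n["id"]), float(n["x"]), float(n["y"]))
            for n in data["reference_nodes"]
        ),
        rf_generators=tuple(
            NodePosition(str(n["id"]), float(n["x"]), float(n["y"]))
            for n in data["rf_generators"]
        ),
        gateway=(float(data["gateway"]["x"]), float(data["gateway"]["y"])),
    )


def write_layout(layout: NodeLayout, path) -> None:
    path = str(path)
    data = layout_to_dict(layout)
    with open(path, "w") as fh:
        if path.endswith((".yaml", ".yml")):
            yaml.safe_dump(data, fh)
        else:
            json.dump(data, fh, indent=2)


def read_layout(path) -> NodeLayout:
    with open(str(path)) as fh:
        if str(path).endswith((".yaml", ".yml")):
            data = yaml.safe_load(fh)
        else:
            data = json.load(fh)
    return layout_from_dict(data)


def write_round_csv(rnd: RssiRound, path) -> None:
    """Write `observer_id,generator_id,rssi` rows (raw values only)."""
    rows = []
    for j, gid in enumerate(rnd.generator_ids):
        rows.append({"observer_id": WEARABLE_ID, "generator_id": gid, "rssi": int(rnd.wearable[j])})
    for i, rid in enumerate(rnd.reference_ids):
        for j, gid in enumerate(rnd.generator_ids):
            rows.append({"observer_id": rid, "generator_id": gid, "rssi": int(rnd.references[i, j])})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_round_csv(path) -> RssiRound:
    df = pd.read_csv(path, dtype={"observer_id": str, "generator_id": str, "rssi": int})
    required = {"observer_id", "generator_id", "rssi"}
    if not required.issubset(df.columns):
        raise ValueError(f"round CSV must have columns {sorted(required)}")
    generator_ids = tuple(dict.fromkeys(df["generator_id"]))
    observers = tuple(dict.fromkeys(df["observer_id"]))
    if WEARABLE_ID not in observers:
        raise ValueError(f"round CSV must contain observer '{WEARABLE_ID}'")
    reference_ids = tuple(o for o in observers if o != WEARABLE_ID)
    pivot = df.pivot_table(index="observer_id", columns="generator_id", values="rssi", aggfunc="first")
    wearable = pivot.loc[WEARABLE_ID, list(generator_ids)].to_numpy(dtype=int)
    references = pivot.loc[list(reference_ids), list(generator_ids)].to_numpy(dtype=int)
    return RssiRound(
        wearable=wearable,
        references=references,
        reference_ids=reference_ids,
        generator_ids=generator_ids,
    )


def estimate_to_dict(est: PositionEstimate, p: Optional[int] = None) -> dict:
    return {
        "x": est.x,
        "y": est.y,
        "p": p if p is not None else len(est.neighbors),
        "neighbors": [
            {"id": nid, "distance": d, "weight": w} for nid, d, w in est.neighbors
        ],
    }


def write_estimate_json(est: PositionEstimate, path) -> None:
    with open(path, "w") as fh:
        json.dump(estimate_to_dict(est), fh, indent=2)
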