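"""Radio signal model: log-distance path loss and the weighted-RSSI transform.

Received power at distance ``d`` follows the log-distance path-loss law

    P(d) = PL(d0) - 10 * n * log10(d / d0) + X_sigma

with path-loss exponent ``n`` (2 in free space), reference power ``PL(d0)``
at a close-in distance ``d0`` (1 m indoors) and zero-mean Gaussian
shadowing ``X_sigma`` in dB.  The radio chip maps dBm linearly onto an
integer RSSI scale 0–255.

Because the measured RSSI-vs-distance relationship is not log-linear, the
RSSI axis is split into four distance classes (at 25 degC: Class I 144–255,
within 0.5 m; Class II 112–143, 0.5–2 m; Class III 61–111, 2–7 m;
Class IV 0–60, beyond 7 m) and each class carries an affine transform

    rss' = A + ratio * (rss - B)

— the *weighted RSSI* — that compresses within-class variation while
keeping the overall map strictly increasing.  Localization distances are
computed on weighted values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np


class GeometryError(ValueError):
    """A distance or coordinate is geometrically invalid."""


class CalibrationError(ValueError):
    """The dBm-to-RSSI linear map cannot be constructed."""


class InvalidRssiError(ValueError):
    """An RSSI value lies outside the integer range 0–255."""


@dataclass(frozen=True)
class PathLossParams:
    """Log-distance path-loss parameters.

    ``pl_d0_dbm`` is the received power at the reference distance ``d0_m``;
    the default -40 dBm at 1 m is typical of 2.4 GHz low-power radios.
    ``sigma_db`` is the shadowing standard deviation (0 for deterministic
    use).
    """

    pl_d0_dbm: float = -40.0
    n: float = 2.0
    d0_m: float = 1.0
    sigma_db: float = 0.0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("path-loss exponent n must be positive")
        if self.d0_m <= 0:
            raise ValueError("reference distance d0 must be positive")
        if self.sigma_db < 0:
            raise ValueError("shadowing sigma must be non-negative")


@dataclass(frozen=True)
class RssiClass:
    """One RSSI class: its integer range and affine transform parameters."""

    name: str
    rssi_lo: int
    rssi_hi: int
    a: float
    ratio: float
    b: float


@dataclass(frozen=True)
class RssiClassTable:
    """Partition of the 0–255 RSSI range into classes with transforms.

    The default table carries the 25 degC calibration.  The printed class
    ranges meet at 60; that boundary value is assigned to Class IV (both
    parameterizations give the identical weighted value 60.0 there, so the
    choice only fixes the partition).
    """

    classes: Tuple[RssiClass, ...]

    def __post_init__(self) -> None:
        covered = np.zeros(256, dtype=int)
        for c in self.classes:
            if not (0 <= c.rssi_lo <= c.rssi_hi <= 255):
                raise ValueError(f"class {c.name} range out of 0-255")
            if c.ratio <= 0:
                raise ValueError(f"class {c.name} ratio must be positive")
            covered[c.rssi_lo : c.rssi_hi + 1] += 1
        if not np.all(covered == 1):
            raise ValueError("class ranges must partition 0-255 exactly")
        w = np.array([weight_rssi(r, self) for r in range(256)])
        if not np.all(np.diff(w) > 0):
            raise ValueError("weighted transform must be strictly increasing on 0-255")

    def class_for(self, rss: int) -> RssiClass:
        rss = _check_rssi(rss)
        for c in self.classes:
            if c.rssi_lo <= rss <= c.rssi_hi:
                return c
        raise InvalidRssiError(f"RSSI {rss} not covered by any class")


def default_class_table() -> RssiClassTable:
    """The 25 degC class table (ranges and A/ratio/B per class)."""
    return RssiClassTable(
        classes=(
            RssiClass("I", 144, 255, a=176.0, ratio=0.05, b=144.0),
            RssiClass("II", 112, 143, a=112.0, ratio=0.3, b=112.0),
            RssiClass("III", 61, 111, a=60.0, ratio=0.6, b=60.0),
            RssiClass("IV", 0, 60, a=0.0, ratio=1.0, b=0.0),
        )
    )


def _check_rssi(rss) -> int:
    as_int = int(rss)
    if as_int != rss or not (0 <= as_int <= 255):
        raise InvalidRssiError(f"RSSI must be an integer in 0-255, got {rss!r}")
    return as_int


def path_loss_power(
    distance_m: float,
    params: PathLossParams,
    noise_db: Optional[float] = None,
) -> float:
    """Received power in dBm at a given distance under the path-loss law.

    Strictly decreasing in distance when ``noise_db`` is zero or None.
    """
    if not distance_m > 0:
        raise GeometryError(f"distance must be positive, got {distance_m}")
    power = params.pl_d0_dbm - 10.0 * params.n * np.log10(distance_m / params.d0_m)
    if noise_db is not None:
        power += noise_db
    return float(power)


#: Distance anchors tying the calibrated RSSI map to the class semantics:
#: within 0.5 m reads Class I's lower edge, 7 m reads the Class III/IV edge.
CAL_NEAR_M, CAL_NEAR_RSSI = 0.5, 144
CAL_FAR_M, CAL_FAR_RSSI = 7.0, 60


def calibrate_rssi_map(params: PathLossParams) -> Tuple[float, float]:
    """Fit the linear dBm-to-RSSI map from the class distance anchors.

    Returns ``(slope, intercept)`` such that the noise-free power at 0.5 m
    maps to RSSI 144 and at 7 m to RSSI 60, so simulated RSSI classes keep
    their distance meaning regardless of the absolute power level.
    """
    p_near = path_loss_power(CAL_NEAR_M, params)
    p_far = path_loss_power(CAL_FAR_M, params)
    if p_near == p_far:
        raise CalibrationError("degenerate anchors: equal powers at 0.5 m and 7 m")
    slope = (CAL_NEAR_RSSI - CAL_FAR_RSSI) / (p_near - p_far)
    intercept = CAL_NEAR_RSSI - slope * p_near
    return slope, intercept


def dbm_to_rssi(power_dbm: float, slope: float, intercept: float) -> int:
    """Map received power linearly onto the integer RSSI scale 0–255.

    The slope must be positive so that stronger signals yield larger RSSI;
    results are rounded and clamped to [0, 255].
    """
    if slope <= 0:
        raise CalibrationError("RSSI map slope must be positive")
    if not np.isfinite(power_dbm):
        raise ValueError("power must be finite")
    return int(np.clip(np.round(slope * power_dbm + intercept), 0, 255))


def classify_rssi(rss: int, table: Optional[RssiClassTable] = None) -> str:
    """Name of the class whose range contains ``rss``."""
    table = table or default_class_table()
    return table.class_for(rss).name


def weight_rssi(rss: int, table: Optional[RssiClassTable] = None) -> float:
    """Weighted RSSI ``A + ratio * (rss - B)`` using rss's class parameters."""
    table = table or default_class_table()
    rss = _check_rssi(rss)
    for c in table.classes:
        if c.rssi_lo <= rss <= c.rssi_hi:
            return float(c.a + c.ratio * (rss - c.b))
    raise InvalidRssiError(f"RSSI {rss} not covered by any class")


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def table_to_json(table: RssiClassTable, path) -> None:
    data = {
        "classes": [
            {
                "name": c.name,
                "rssi_lo": c.rssi_lo,
                "rssi_hi": c.rssi_hi,
                "A": c.a,
                "ratio": c.ratio,
                "B": c.b,
            }
            for c in table.classes
        ]
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2)


def table_from_json(path) -> RssiClassTable:
    with open(path) as fh:
        data = json.load(fh)
    return RssiClassTable(
        classes=tuple(
            RssiClass(
                name=c["name"],
                rssi_lo=int(c["rssi_lo"]),
                rssi_hi=int(c["rssi_hi"]),
                a=float(c["A"]),
                ratio=float(c["ratio"]),
                b=float(c["B"]),
            )
            for c in data["classes"]
        )
    )
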