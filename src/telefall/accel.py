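"""Tri-axial accelerometer traces and impact features.

A waist-worn tri-axial accelerometer reports acceleration in units of G
(1 G = standard gravity) on three body axes: x sagittal, y vertical,
z frontal.  Fall detection works on two derived series:

* the sum vector magnitude ``SVM_xyz = sqrt(ax^2 + ay^2 + az^2)``, the
  rotation-invariant impact feature, and
* the horizontal-plane magnitude ``SVM_xz = sqrt(ax^2 + az^2)``, which
  captures the body tilting forward, backward or laterally.

A third feature, the reference velocity, integrates the gravity-subtracted
``SVM_xyz`` between an impact trigger and the onset of post-fall rest; it
separates genuinely violent falls from slower slumps.  SVM values are
computed on raw samples — no low-pass filter is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Standard gravity, m/s^2 per G, used to convert the velocity integral.
G_MPS2 = 9.80665


class InvalidSampleError(ValueError):
    """An acceleration sample is non-finite (NaN or infinite)."""


class InvalidWindowError(ValueError):
    """An integration window [k, l] is empty, reversed or out of bounds."""


class EmptyTraceError(ValueError):
    """A trace with zero samples was supplied where data is required."""


class NonUniformSamplingError(ValueError):
    """Timestamps in an input file are not uniformly spaced."""


@dataclass(frozen=True)
class AccelTrace:
    """Uniformly sampled tri-axial acceleration series in G.

    Parameters
    ----------
    ax, ay, az : array-like
        Equal-length acceleration series in G for the sagittal (x),
        vertical (y) and frontal (z) axes.
    sample_rate_hz : float, default 200
        Sampling rate; samples are spaced ``1/sample_rate_hz`` seconds.
    t0 : float, default 0
        Time of the first sample, seconds.
    """

    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    sample_rate_hz: float = 200.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("ax", "ay", "az"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
        if not (self.ax.ndim == self.ay.ndim == self.az.ndim == 1):
            raise ValueError("axis series must be one-dimensional")
        if not (len(self.ax) == len(self.ay) == len(self.az)):
            raise ValueError("axis series must have identical length")
        if len(self.ax) < 1:
            raise EmptyTraceError("trace must contain at least one sample")
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be positive")
        for name in ("ax", "ay", "az"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise InvalidSampleError(f"non-finite sample in {name}")

    def __len__(self) -> int:
        return len(self.ax)

    @property
    def dt(self) -> float:
        """Sample spacing in seconds."""
        return 1.0 / self.sample_rate_hz

    @property
    def times(self) -> np.ndarray:
        """Sample timestamps in seconds."""
        return self.t0 + np.arange(len(self)) / self.sample_rate_hz

    def time_at(self, index: int) -> float:
        return self.t0 + index / self.sample_rate_hz


@dataclass(frozen=True)
class FeatureSeries:
    """Per-sample impact features aligned 1:1 with a parent trace."""

    svm_xyz: np.ndarray
    svm_xz: np.ndarray

    def __post_init__(self) -> None:
        if len(self.svm_xyz) != len(self.svm_xz):
            raise ValueError("feature series must have identical length")

    def __len__(self) -> int:
        return len(self.svm_xyz)


def svm_xyz(ax, ay, az):
    """Sum vector magnitude ``sqrt(ax^2 + ay^2 + az^2)`` in G.

    Accepts scalars or equal-shape arrays; raises
    :class:`InvalidSampleError` on non-finite input.
    """
    ax, ay, az = (np.asarray(v, dtype=float) for v in (ax, ay, az))
    if not (np.all(np.isfinite(ax)) and np.all(np.isfinite(ay)) and np.all(np.isfinite(az))):
        raise InvalidSampleError("non-finite acceleration sample")
    out = np.sqrt(ax * ax + ay * ay + az * az)
    return float(out) if out.ndim == 0 else out


def svm_xz(ax, az):
    """Horizontal-plane magnitude ``sqrt(ax^2 + az^2)`` in G."""
    ax, az = (np.asarray(v, dtype=float) for v in (ax, az))
    if not (np.all(np.isfinite(ax)) and np.all(np.isfinite(az))):
        raise InvalidSampleError("non-finite acceleration sample")
    out = np.sqrt(ax * ax + az * az)
    return float(out) if out.ndim == 0 else out


def compute_features(trace: AccelTrace) -> FeatureSeries:
    """Vectorized per-sample ``SVM_xyz`` and ``SVM_xz`` for a whole trace."""
    if len(trace) == 0:  # unreachable through AccelTrace, kept as a guard
        raise EmptyTraceError("cannot compute features of an empty trace")
    return FeatureSeries(
        svm_xyz=svm_xyz(trace.ax, trace.ay, trace.az),
        svm_xz=svm_xz(trace.ax, trace.az),
    )


def reference_velocity(
    trace: AccelTrace,
    k_index: int,
    l_index: int,
    g_mps2: float = G_MPS2,
) -> float:
    """Signed velocity integral of the gravity-subtracted SVM, in m/s.

    Integrates ``(SVM_xyz(t) - 1 G) * g_mps2`` over samples
    ``[k_index, l_index]`` with the trapezoidal rule at the native sample
    spacing.  The integrand is deliberately not clamped at zero: free-fall
    segments below 1 G legitimately reduce the velocity estimate, so the
    result may be negative for sub-1 G windows.

    Parameters
    ----------
    k_index, l_index : int
        Inclusive sample bounds, ``0 <= k_index < l_index < len(trace)``.
    g_mps2 : float
        Conversion from G to m/s^2 (default standard gravity).
    """
    if not (0 <= k_index < l_index < len(trace)):
        raise InvalidWindowError(
            f"window [{k_index}, {l_index}] invalid for trace of length {len(trace)}"
        )
    seg = svm_xyz(
        trace.ax[k_index : l_index + 1],
        trace.ay[k_index : l_index + 1],
        trace.az[k_index : l_index + 1],
    )
    integrand = (seg - 1.0) * g_mps2
    return float(np.trapezoid(integrand, dx=trace.dt))


# ---------------------------------------------------------------------------
# CSV dialect: header `t,ax,ay,az`, t in seconds, axes in G.
# ---------------------------------------------------------------------------

#: Tolerance for timestamp-uniformity validation, seconds.
UNIFORMITY_TOL_S = 1e-6


def read_accel_csv(path) -> AccelTrace:
    """Read a `t,ax,ay,az` CSV, validating uniform sampling.

    Timestamps must be strictly monotone with a constant spacing to within
    1e-6 s; the sample rate is inferred from the mean spacing.
    """
    df = pd.read_csv(path)
    required = ["t", "ax", "ay", "az"]
    if list(df.columns[:4]) != required:
        raise ValueError(f"accelerometer CSV must have columns {required}")
    if len(df) < 1:
        raise EmptyTraceError(f"no samples in {path}")
    t = df["t"].to_numpy(dtype=float)
    if len(t) > 1:
        dts = np.diff(t)
        if np.any(dts <= 0):
            raise NonUniformSamplingError("timestamps must be strictly increasing")
        if np.max(np.abs(dts - dts.mean())) > UNIFORMITY_TOL_S:
            raise NonUniformSamplingError(
                "timestamps are not uniformly spaced (tolerance 1e-6 s); "
                "resampling of irregular input is not supported"
            )
        rate = 1.0 / float(dts.mean())
    else:
        rate = 200.0
    return AccelTrace(
        ax=df["ax"].to_numpy(dtype=float),
        ay=df["ay"].to_numpy(dtype=float),
        az=df["az"].to_numpy(dtype=float),
        sample_rate_hz=rate,
        t0=float(t[0]),
    )


def write_accel_csv(trace: AccelTrace, path) -> None:
    """Write a trace in the `t,ax,ay,az` CSV dialect."""
    pd.DataFrame(
        {"t": trace.times, "ax": trace.ax, "ay": trace.ay, "az": trace.az}
    ).to_csv(path, index=False)
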