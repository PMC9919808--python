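"""Per-sample feature engineering for tri-axial acceleration streams.

Nine features feed the classifiers, all computable on-line from the current
and the immediately preceding sample:

==========  ===========================================================
column      meaning
==========  ===========================================================
Xacc        X-axis acceleration, g
Yacc        Y-axis acceleration, g
Zacc        Z-axis acceleration, g
dXacc       |Xacc_i - Xacc_{i-1}|
dYacc       |Yacc_i - Yacc_{i-1}|
dZacc       |Zacc_i - Zacc_{i-1}|
dAccNorm    Euclidean norm sqrt(dXacc^2 + dYacc^2 + dZacc^2)
dRoll       absolute change of the roll tilt angle, degrees (wrap-aware)
dPitch      absolute change of the pitch tilt angle, degrees
==========  ===========================================================

Roll and pitch use the standard accelerometer-tilt convention,
``roll = atan2(Y, Z)`` and ``pitch = atan2(-X, sqrt(Y^2 + Z^2))``; only
their sample-to-sample changes enter the feature set, so the absolute
convention is immaterial as long as it is fixed.  The first sample of a
stream has no predecessor; all six delta features are defined as 0 there,
which keeps one feature row per input sample in real-time use.

No scaling or normalisation is applied: the tree ensembles the system
defaults to are scale-invariant, and every algorithm in the comparison
harness sees identical inputs.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import DegenerateOrientationError, InvalidInputError

__all__ = [
    "FEATURE_COLUMNS",
    "AccelSample",
    "Orientation",
    "compute_orientation",
    "featurize_stream",
    "feature_table",
]

#: Canonical feature order; every model consumes columns in this order.
FEATURE_COLUMNS: tuple[str, ...] = (
    "Xacc",
    "Yacc",
    "Zacc",
    "dXacc",
    "dYacc",
    "dZacc",
    "dAccNorm",
    "dRoll",
    "dPitch",
)


class AccelSample(NamedTuple):
    """One time-stamped tri-axial acceleration reading, in g."""

    t: float
    x: float
    y: float
    z: float


class Orientation(NamedTuple):
    """Tilt angles in degrees: roll in (-180, 180], pitch in [-90, 90]."""

    roll_deg: float
    pitch_deg: float


def compute_orientation(x: float, y: float, z: float) -> Orientation:
    """Tilt angles of the gravity vector for a single reading.

    Raises :class:`DegenerateOrientationError` for the zero vector, where
    tilt is undefined.
    """
    if x == 0.0 and y == 0.0 and z == 0.0:
        raise DegenerateOrientationError("orientation undefined for zero acceleration vector")
    roll = math.degrees(math.atan2(y, z))
    pitch = math.degrees(math.atan2(-x, math.hypot(y, z)))
    return Orientation(roll, pitch)


def _angles(xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    roll = np.degrees(np.arctan2(xyz[:, 1], xyz[:, 2]))
    pitch = np.degrees(np.arctan2(-xyz[:, 0], np.hypot(xyz[:, 1], xyz[:, 2])))
    return roll, pitch


def _wrapped_abs_diff_deg(angles: np.ndarray) -> np.ndarray:
    """|a_i - a_{i-1}| on the circle: 179 deg then -179 deg gives 2, not 358."""
    d = np.diff(angles)
    return np.abs((d + 180.0) % 360.0 - 180.0)


def _as_txyz(stream) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Accept a LabeledStream or a DataFrame with t,x,y,z[,label] columns."""
    if hasattr(stream, "xyz"):
        labels = np.asarray(stream.labels) if stream.labels is not None else None
        return np.asarray(stream.t, dtype=float), np.asarray(stream.xyz, dtype=float), labels
    df = stream
    missing = {"t", "x", "y", "z"} - set(df.columns)
    if missing:
        raise InvalidInputError(f"stream table missing columns: {sorted(missing)}")
    labels = df["label"].to_numpy() if "label" in df.columns else None
    return (
        df["t"].to_numpy(dtype=float),
        df[["x", "y", "z"]].to_numpy(dtype=float),
        labels,
    )


def featurize_stream(stream) -> pd.DataFrame:
    """Compute the 9-column feature table for an ordered stream.

    Accepts a :class:`~harcascade.simulate.LabeledStream` or a DataFrame
    with columns ``t, x, y, z``.  Output has one row per sample, columns
    in :data:`FEATURE_COLUMNS` order.  Timestamps must be strictly
    increasing; they enter only through sample order, so shifting them all
    by a constant leaves the features unchanged.
    """
    t, xyz, _ = _as_txyz(stream)
    if len(t) == 0:
        raise InvalidInputError("cannot featurize an empty stream")
    if not np.all(np.isfinite(xyz)):
        raise InvalidInputError("non-finite acceleration values")
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise InvalidInputError("timestamps must be strictly increasing")

    d = np.abs(np.diff(xyz, axis=0))
    d = np.vstack([np.zeros((1, 3)), d])
    dnorm = np.linalg.norm(d, axis=1)
    roll, pitch = _angles(xyz)
    droll = np.concatenate([[0.0], _wrapped_abs_diff_deg(roll)])
    dpitch = np.concatenate([[0.0], np.abs(np.diff(pitch))])

    return pd.DataFrame(
        {
            "Xacc": xyz[:, 0],
            "Yacc": xyz[:, 1],
            "Zacc": xyz[:, 2],
            "dXacc": d[:, 0],
            "dYacc": d[:, 1],
            "dZacc": d[:, 2],
            "dAccNorm": dnorm,
            "dRoll": droll,
            "dPitch": dpitch,
        }
    )


def feature_table(stream) -> pd.DataFrame:
    """Feature table with the per-sample ``label`` column attached."""
    _, _, labels = _as_txyz(stream)
    if labels is None:
        raise InvalidInputError("stream carries no labels")
    out = featurize_stream(stream)
    out["label"] = labels
    return out
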