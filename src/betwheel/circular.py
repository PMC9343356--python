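"""Circular geometry and statistics on the 360-degree shape wheel.

The response space is a circle of 360 shapes, one per integer degree.
All public functions take and return **degrees**.  Positions live in
[0, 360); signed errors live in (-180, 180] with positive = clockwise.
Continuous (non-integer) positions are allowed throughout: the wheel is
rendered at integer bins but mouse-placed bets are continuous.

The antipodal tie (a displacement of exactly 180 degrees) is resolved to
+180 by convention, so ``signed_delta`` is a total function and
antisymmetric everywhere except at that single tie.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "UndefinedCircularMeanError",
    "wrap",
    "signed_delta",
    "abs_error",
    "circ_mean",
    "cumulative_means",
    "rotate_profile",
]

N_BINS = 360

#: resultant lengths below this fraction of total weight are treated as zero
RESULTANT_TOL = 1e-9


class UndefinedCircularMeanError(ValueError):
    """The vector resultant of the given angles is (numerically) zero."""


def wrap(angle):
    """Reduce an angle (scalar or array) to the wheel, i.e. into [0, 360).

    360 maps to 0 exactly.
    """
    return np.mod(angle, 360.0)


def signed_delta(a, b):
    """Shortest signed angular displacement from ``b`` to ``a`` in degrees.

    Returns a value in (-180, 180]; positive means ``a`` lies clockwise of
    ``b``.  Vectorized over array inputs.

    ``signed_delta(a, b) == -signed_delta(b, a)`` except at the antipodal
    tie, where both return +180.
    """
    d = np.mod(np.asarray(a, dtype=float) - np.asarray(b, dtype=float), 360.0)
    out = np.where(d > 180.0, d - 360.0, d)
    return out if out.ndim else float(out)


def abs_error(a, b):
    """Absolute circular distance |signed_delta(a, b)| in [0, 180]."""
    return np.abs(signed_delta(a, b))


def circ_mean(values, weights=None):
    """Direction of the (weighted) vector resultant of angles in degrees.

    For tightly clustered angles this reduces to the arithmetic mean.
    Raises :class:`UndefinedCircularMeanError` when the resultant length
    is below tolerance (e.g. two opposite, equally weighted angles).
    """
    values = np.atleast_1d(np.asarray(values, dtype=float))
    if values.size == 0:
        raise ValueError("circ_mean requires at least one value")
    if weights is None:
        weights = np.ones_like(values)
    else:
        weights = np.atleast_1d(np.asarray(weights, dtype=float))
        if weights.shape != values.shape:
            raise ValueError("weights must match values in length")
        if np.any(weights < 0):
            raise ValueError("weights must be nonnegative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("weights must not all be zero")
    rad = np.deg2rad(values)
    c = float(np.sum(weights * np.cos(rad)))
    s = float(np.sum(weights * np.sin(rad)))
    if np.hypot(c, s) / total < RESULTANT_TOL:
        raise UndefinedCircularMeanError(
            "circular mean undefined: resultant length ~ 0"
        )
    return float(wrap(np.rad2deg(np.arctan2(s, c))))


def cumulative_means(bets):
    """Running circular means of an ordered bet sequence.

    Element ``k`` (0-based) is the unweighted circular mean of bets
    ``0..k``; element 0 equals the first bet.  Propagates
    :class:`UndefinedCircularMeanError` if any prefix has a degenerate
    resultant.
    """
    bets = np.atleast_1d(np.asarray(bets, dtype=float))
    rad = np.deg2rad(bets)
    c = np.cumsum(np.cos(rad))
    s = np.cumsum(np.sin(rad))
    n = np.arange(1, bets.size + 1)
    if np.any(np.hypot(c, s) / n < RESULTANT_TOL):
        raise UndefinedCircularMeanError(
            "cumulative circular mean undefined for some prefix"
        )
    return wrap(np.rad2deg(np.arctan2(s, c)))


def rotate_profile(heights, shift):
    """Rotate a 360-bin profile so that bin ``i`` of the output equals bin
    ``(i + shift) mod 360`` of the input.

    Rotating by the (rounded) target position therefore brings the target
    to bin 0.  Mass is conserved exactly; ``shift`` is rounded to the
    nearest integer bin.
    """
    heights = np.asarray(heights, dtype=float)
    if heights.shape[-1] != N_BINS:
        raise ValueError(f"profile must have exactly {N_BINS} bins")
    return np.roll(heights, -int(round(shift)), axis=-1)


def nearest_bin(position):
    """Index of the integer wheel bin nearest a continuous position."""
    return int(np.round(wrap(position))) % N_BINS


def bin_signed_coords():
    """Signed-error coordinate of each wheel bin, in (-180, 180].

    Bin ``i`` maps to ``i`` for ``i <= 180`` and ``i - 360`` otherwise —
    the coordinate used once a profile has been rotated target-to-zero.
    """
    i = np.arange(N_BINS, dtype=float)
    return np.where(i > 180, i - 360.0, i)
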