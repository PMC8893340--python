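"""Circular geometry primitives for angular estimates.

All public functions work in degrees and accept scalars or numpy arrays.
Angles are normalised to the half-open interval [0, 360); arc distances
live in [0, 180].  The revision and influence statistics of the
advice-taking task are both computed by :func:`shift_fraction`: the
fraction of the gap between two initial estimates that a revised
estimate closes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "normalize",
    "arc_distance",
    "signed_arc",
    "move_toward",
    "shift_fraction",
    "ArcConstraintError",
]


class ArcConstraintError(ValueError):
    """A revised estimate lies off the shorter arc between the two initial estimates."""


def _as_finite(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} must be finite, got {x!r}")
    return a


def _maybe_scalar(a: np.ndarray):
    return a.item() if a.ndim == 0 else a


def normalize(angle):
    """Map an angle (degrees) to [0, 360).  Idempotent; ``a`` and ``a + 360k`` coincide."""
    return _maybe_scalar(_as_finite(angle, "angle") % 360.0)


def arc_distance(x, y):
    """Shortest angular distance between two angles, in [0, 180] degrees.

    Symmetric, zero iff the angles are equal modulo 360, and a metric on
    the circle.
    """
    xv = _as_finite(x, "x")
    yv = _as_finite(y, "y")
    d = np.abs(xv - yv) % 360.0
    return _maybe_scalar(np.minimum(d, 360.0 - d))


def signed_arc(origin, target):
    """Signed shortest rotation from *origin* to *target* in (-180, 180].

    Positive values are counter-clockwise.  The antipodal tie (exactly
    180 degrees apart) resolves to +180, i.e. counter-clockwise.
    """
    o = _as_finite(origin, "origin")
    t = _as_finite(target, "target")
    d = (t - o) % 360.0
    return _maybe_scalar(np.where(d <= 180.0, d, d - 360.0))


def move_toward(origin, target, w):
    """Angle a fraction ``w`` along the shorter arc from *origin* to *target*.

    ``w = 0`` returns *origin*, ``w = 1`` returns *target* (mod 360), and
    ``arc_distance(result, origin) == w * arc_distance(origin, target)``.
    Antipodal pairs move counter-clockwise (see :func:`signed_arc`).

    Raises
    ------
    ValueError
        If any ``w`` lies outside [0, 1].
    """
    wv = _as_finite(w, "w")
    if np.any(wv < 0.0) or np.any(wv > 1.0):
        raise ValueError(f"w must lie in [0, 1], got {w!r}")
    o = _as_finite(origin, "origin")
    return _maybe_scalar((o + wv * signed_arc(o, target)) % 360.0)


def shift_fraction(init, final, other_init, *, tol=1e-9):
    """Fraction of the initial disagreement closed by a revision, in [0, 1].

    ``arc_distance(init, final) / arc_distance(init, other_init)``: 0 means
    the revised estimate *final* kept the initial estimate, 1 means full
    adoption of the other party's initial estimate.  Computes both the
    participant's *revision* and the partner's *influence* statistic,
    depending on whose estimates are passed.

    Trials with zero initial disagreement have no defined statistic and
    yield ``nan`` (callers drop those trials).  A *final* estimate off the
    shorter arc between ``init`` and ``other_init`` violates the task rule
    and raises :class:`ArcConstraintError`.
    """
    a = np.atleast_1d(np.asarray(arc_distance(init, other_init), dtype=float))
    b = np.atleast_1d(np.asarray(arc_distance(init, final), dtype=float))
    c = np.atleast_1d(np.asarray(arc_distance(final, other_init), dtype=float))
    a, b, c = np.broadcast_arrays(a, b, c)
    # on the shorter arc the two part-distances sum to the whole
    atol = tol + 1e-9 * np.maximum(a, 1.0)
    off = (b + c > a + atol) & (a > 0)
    if np.any(off):
        raise ArcConstraintError(
            f"{int(off.sum())} revised estimate(s) lie off the shorter arc "
            "between the initial estimates"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(a > 0, b / np.where(a > 0, a, 1.0), np.nan)
    out = np.clip(out, 0.0, 1.0)  # nan passes through
    shape = np.broadcast_shapes(np.shape(init), np.shape(final), np.shape(other_init))
    return _maybe_scalar(np.asarray(out).reshape(shape))
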