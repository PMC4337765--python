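"""Kinematic series and pairwise relative geometry from recorded tracks.

Everything here is computed exactly as an observer of real tracks would
compute it: from the recorded positions alone, by finite differences.
Speed and heading at time t are taken from the step arriving at t
(backward difference); the responses — tangential acceleration and turning
rate — attributed to time t are the changes occurring between t and t+1
(forward difference), so that a response always follows the configuration
it is binned against.

Angles are mathematical convention internally (radians, counter-clockwise
positive, 0 along +x).  The pairwise geometry is reported right-positive
(positive = neighbour or bearing to the focal's right), the convention in
which force maps are usually drawn; the conversion is a single negation
done in this layer only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KinematicSeries",
    "PairGeometry",
    "kinematic_series",
    "pair_geometry",
    "wrap_angle",
    "regression_to_mean_slopes",
]


def wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap angles to the interval (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    return -((-a + np.pi) % (2 * np.pi) - np.pi)


@dataclass(frozen=True)
class KinematicSeries:
    """Per-individual derived series, all length N with NaN where undefined.

    speed (a.u./s) and heading (rad) are defined for t >= 1; tangential
    acceleration (a.u./s^2) and turning rate (rad/s) for 1 <= t <= N-2.
    ``heading_defined`` flags steps whose displacement was non-zero; across
    zero-length steps the previous heading is carried forward.
    """

    speed: np.ndarray
    heading: np.ndarray
    accel: np.ndarray
    turn_rate: np.ndarray
    heading_defined: np.ndarray
    dt: float


def kinematic_series(xy: np.ndarray, dt: float) -> KinematicSeries:
    """Compute speed, heading, tangential acceleration and turning rate.

    Parameters
    ----------
    xy : array_like, shape (N, 2)
        Recorded positions, N >= 3.
    dt : float
        Duration of one time step in seconds.
    """
    xy = np.asarray(xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2 or xy.shape[0] < 3:
        raise ValueError(f"need a (N>=3, 2) position array, got shape {xy.shape}")
    if not dt > 0:
        raise ValueError(f"dt must be positive, got {dt!r}")
    n = xy.shape[0]
    disp = np.diff(xy, axis=0)  # step t-1 -> t lands at index t-1
    step_len = np.hypot(disp[:, 0], disp[:, 1])

    speed = np.full(n, np.nan)
    speed[1:] = step_len / dt

    heading = np.full(n, np.nan)
    heading_defined = np.zeros(n, dtype=bool)
    raw = np.arctan2(disp[:, 1], disp[:, 0])
    moved = step_len > 0
    heading[1:] = raw
    heading_defined[1:] = moved
    # zero-length step: heading undefined, carry the previous value forward
    if not moved.all():
        for t in range(1, n):
            if not heading_defined[t]:
                heading[t] = heading[t - 1]  # NaN at t=1 stays NaN

    accel = np.full(n, np.nan)
    accel[1:-1] = (speed[2:] - speed[1:-1]) / dt

    turn_rate = np.full(n, np.nan)
    turn_rate[1:-1] = wrap_angle(heading[2:] - heading[1:-1]) / dt

    return KinematicSeries(
        speed=speed,
        heading=heading,
        accel=accel,
        turn_rate=turn_rate,
        heading_defined=heading_defined,
        dt=dt,
    )


@dataclass(frozen=True)
class PairGeometry:
    """Relative state of a neighbour in the focal frame, right-positive.

    ``theta`` is the direction of the neighbour (0 = dead ahead, positive =
    to the focal's right); ``phi`` the relative bearing (0 = parallel
    headings, positive = neighbour oriented to the right); ``d_fb`` and
    ``d_lat`` the signed front-back and lateral components of the distance
    (positive = ahead / to the right).  ``valid`` flags steps where both
    headings are defined and the positions are distinct.
    """

    distance: np.ndarray
    theta: np.ndarray
    phi: np.ndarray
    d_fb: np.ndarray
    d_lat: np.ndarray
    valid: np.ndarray


def pair_geometry(
    focal_xy: np.ndarray,
    focal_heading: np.ndarray,
    neighbour_xy: np.ndarray,
    neighbour_heading: np.ndarray,
) -> PairGeometry:
    """Relative position and orientation of a neighbour in the focal frame.

    All inputs share the same time index.  Headings are mathematical
    convention; the returned angles are right-positive, i.e.
    ``theta = wrap(psi_focal - atan2(dy, dx))`` and
    ``phi = wrap(psi_focal - psi_neighbour)``.
    """
    focal_xy = np.asarray(focal_xy, dtype=float)
    neighbour_xy = np.asarray(neighbour_xy, dtype=float)
    focal_heading = np.asarray(focal_heading, dtype=float)
    neighbour_heading = np.asarray(neighbour_heading, dtype=float)
    if focal_xy.shape != neighbour_xy.shape:
        raise ValueError("focal and neighbour position series must have the same shape")

    delta = neighbour_xy - focal_xy
    d = np.hypot(delta[:, 0], delta[:, 1])
    bearing = np.arctan2(delta[:, 1], delta[:, 0])
    theta = wrap_angle(focal_heading - bearing)
    phi = wrap_angle(focal_heading - neighbour_heading)
    d_fb = d * np.cos(theta)
    d_lat = d * np.sin(theta)
    valid = (d > 0) & np.isfinite(focal_heading) & np.isfinite(neighbour_heading)
    return PairGeometry(distance=d, theta=theta, phi=phi, d_fb=d_fb, d_lat=d_lat, valid=valid)


def regression_to_mean_slopes(trackset) -> tuple[float, float]:
    """Regression slope of the next-step change of the recorded relative
    position on its current deviation from the target, per component.

    With weakly correlated noise the recorded relative position of a pair
    reverts on average towards its fixed target, so both slopes are
    negative — the regression-to-the-mean signature that masquerades as an
    attraction/repulsion response.

    Parameters
    ----------
    trackset : TrackSet
        A flight (or the pair of individuals 0 and 1 of one).

    Returns
    -------
    (slope_x, slope_y) : tuple of float
    """
    rel_rec = trackset.recorded[1] - trackset.recorded[0]
    rel_ideal = trackset.ideal[1] - trackset.ideal[0]
    dev = rel_rec - rel_ideal
    change = dev[1:] - dev[:-1]
    slopes = []
    for c in range(2):
        x = dev[:-1, c]
        slopes.append(float(np.polyfit(x, change[:, c], 1)[0]))
    return slopes[0], slopes[1]
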