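"""Run-and-tumble swimming kinematics.

During a run a cell translates in a straight line at constant speed c:

    dx/dt = c * sin(theta),    dy/dt = c * cos(theta)

with the heading ``theta`` measured clockwise from the +y axis (the
convention forced by the sin/cos assignment).  A tumble first rotates the
heading by a random angle -- a random sign times a uniform draw on
[turn_min, turn_max] degrees, matching the measured mean turn of ~58
degrees -- and then translates for the full timestep along the new heading,
since tumbles are much shorter than the timestep but the cell keeps moving.

Domain coordinates are interpreted as millimetres, so the default swim
speed of 29 um/s is 0.029 domain units per second on the default
[-2, 2] x [-2, 2] domain.  Two boundary rules are supported: ``solid``
clamps each coordinate back to the wall (a cell that would end the step at
(2.05, 1) is returned to (2, 1)) and ``periodic`` wraps coordinates by the
domain width.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

__all__ = ["KinematicsError", "KinematicSpec", "run_step", "tumble_reorient",
           "turn_angle_from_uniforms", "tumble_step", "apply_boundary"]

UM_PER_DOMAIN_UNIT = 1000.0  # domain units are mm

_TWO_PI = 2.0 * np.pi


class KinematicsError(ValueError):
    """Invalid kinematic specification or input."""


@dataclass(frozen=True)
class KinematicSpec:
    """Swimming constants, turn-angle range, boundary rule and domain."""

    speed_um_per_s: float = 29.0
    turn_min_deg: float = 18.0
    turn_max_deg: float = 98.0
    boundary: str = "solid"
    domain: Tuple[Tuple[float, float], Tuple[float, float]] = ((-2.0, 2.0),
                                                               (-2.0, 2.0))

    def __post_init__(self) -> None:
        if self.speed_um_per_s <= 0:
            raise KinematicsError("speed must be positive")
        if not (0 <= self.turn_min_deg <= self.turn_max_deg):
            raise KinematicsError("require 0 <= turn_min <= turn_max")
        if self.boundary not in ("solid", "periodic"):
            raise KinematicsError(f"unknown boundary mode {self.boundary!r}")
        (x0, x1), (y0, y1) = self.domain
        if not (x1 > x0 and y1 > y0):
            raise KinematicsError("domain must be non-degenerate")

    @property
    def speed(self) -> float:
        """Swim speed in domain units (mm) per second."""
        return self.speed_um_per_s / UM_PER_DOMAIN_UNIT


def run_step(position, theta, spec: KinematicSpec, dt: float):
    """Straight-line translation over ``dt`` seconds; heading unchanged."""
    if dt <= 0:
        raise KinematicsError("dt must be positive")
    x, y = position
    c = spec.speed
    return (x + c * np.sin(theta) * dt, y + c * np.cos(theta) * dt)


def turn_angle_from_uniforms(u_sign, u_angle, spec: KinematicSpec):
    """Signed turning angle (radians) from two uniform [0,1) draws.

    Sign is +1 for ``u_sign < 0.5`` and -1 otherwise; magnitude is uniform
    on [turn_min, turn_max] degrees.
    """
    sign = np.where(np.asarray(u_sign) < 0.5, 1.0, -1.0)
    mag_deg = spec.turn_min_deg + (spec.turn_max_deg - spec.turn_min_deg) * \
        np.asarray(u_angle)
    return sign * np.deg2rad(mag_deg)


def tumble_reorient(theta, rng: np.random.Generator, spec: KinematicSpec):
    """New heading after a tumble, wrapped to [0, 2*pi).

    Consumes two draws from the cell's stream: sign, then magnitude.
    """
    u_sign = rng.random()
    u_angle = rng.random()
    return np.mod(theta + turn_angle_from_uniforms(u_sign, u_angle, spec),
                  _TWO_PI)


def tumble_step(position, theta, spec: KinematicSpec, dt: float,
                rng: np.random.Generator):
    """Tumble: reorient first, then translate the full ``dt`` along the new
    heading."""
    theta_new = tumble_reorient(theta, rng, spec)
    return run_step(position, theta_new, spec, dt), theta_new


def apply_boundary(position, spec: KinematicSpec):
    """Return the position corrected by the domain's boundary rule.

    ``solid``: each coordinate independently clamped to its interval (the
    cell is returned to the wall it swam into).  ``periodic``: each
    coordinate wrapped by the domain width (exit on one side, re-enter on
    the opposite side).  In-domain positions are unchanged.
    """
    x, y = position
    (x0, x1), (y0, y1) = spec.domain
    if spec.boundary == "solid":
        return (np.clip(x, x0, x1), np.clip(y, y0, y1))
    if spec.boundary == "periodic":
        wx, wy = x1 - x0, y1 - y0
        # wrap only out-of-domain coordinates so interior points are exact;
        # the upper edge is identified with the lower one
        xa, ya = np.asarray(x), np.asarray(y)
        wrapped_x = np.where((xa < x0) | (xa >= x1),
                             x0 + np.mod(xa - x0, wx), xa)
        wrapped_y = np.where((ya < y0) | (ya >= y1),
                             y0 + np.mod(ya - y0, wy), ya)
        if wrapped_x.shape:
            return (wrapped_x, wrapped_y)
        return (float(wrapped_x), float(wrapped_y))
    raise KinematicsError(f"unknown boundary mode {spec.boundary!r}")
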