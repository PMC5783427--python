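"""Coordinate conventions and stimulus frames in a circular arena.

Everything downstream (simulation, segmentation, inference) shares the
conventions defined here:

* lengths in mm, times in s, angles in rad;
* angles wrapped to the half-open interval ``(-pi, pi]``;
* the arena is a circle of radius ``R`` centred on the origin;
* positions refer to the fish centre of mass.

Two stimulus frames drive the behavioural model.  The *wall frame*
``(r_w, theta_w)`` gives the distance from the fish to the wall and the
signed angle between its heading and the outward wall normal.  The *pair
frame* ``(d, psi, dphi)`` gives the distance to the neighbouring fish, the
signed viewing angle at which the focal fish sees it, and the signed
difference between the two headings.  Both frames are invariant under
global rotations of the arena and change sign (angles only) under a
mirror reflection, which is the symmetry the inference module exploits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ArenaSpec",
    "FishState",
    "WallFrame",
    "PairFrame",
    "wrap_angle",
    "wall_frame",
    "pair_frame",
    "mirror_record",
    "parallax_correct",
    "TRAJECTORY_COLUMNS",
    "KICK_TABLE_COLUMNS",
    "PAIR_KICK_COLUMNS",
]

# CSV dialects shared by the CLI tools: header mandatory, comma separated.
TRAJECTORY_COLUMNS = ["time_s", "fish_id", "x_mm", "y_mm"]
KICK_TABLE_COLUMNS = [
    "t_s",
    "fish_id",
    "x_mm",
    "y_mm",
    "phi_rad",
    "dphi_rad",
    "v_peak_mm_s",
    "l_mm",
    "tau_s",
    "r_w_mm",
    "theta_w_rad",
]
PAIR_KICK_COLUMNS = KICK_TABLE_COLUMNS + ["d_mm", "psi_rad", "dphi_pair_rad"]


@dataclass(frozen=True)
class ArenaSpec:
    """Circular arena of radius ``radius`` mm centred on the origin."""

    radius: float

    def __post_init__(self) -> None:
        if not (self.radius > 0 and math.isfinite(self.radius)):
            raise ValueError(f"arena radius must be positive, got {self.radius}")

    def contains(self, x: float, y: float) -> bool:
        return math.hypot(x, y) < self.radius


@dataclass
class FishState:
    """Pose of one fish: position (mm), heading (rad), clock (s)."""

    x: float
    y: float
    phi: float
    t: float = 0.0

    def __post_init__(self) -> None:
        self.phi = wrap_angle(self.phi)

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass(frozen=True)
class WallFrame:
    """Distance to the wall and signed angle to the outward normal."""

    r_w: float
    theta_w: float
    degenerate: bool = False


@dataclass(frozen=True)
class PairFrame:
    """Inter-fish distance, viewing angle and heading difference."""

    d: float
    psi: float
    dphi: float
    degenerate: bool = False


def wrap_angle(a):
    """Wrap an angle (rad) into the half-open interval ``(-pi, pi]``.

    Scalar or array input.  The convention is half-open so that a mirror
    image is single valued: ``-pi`` maps to ``+pi``.
    """
    a = np.asarray(a, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("wrap_angle requires finite input")
    two_pi = 2.0 * np.pi
    # sign-symmetric form: wrap(-a) == -wrap(a) to the last bit (except at
    # the boundary), which the simulator's mirror-equivariance relies on
    out = a - two_pi * np.round(a / two_pi)
    out = np.where(out <= -np.pi, out + two_pi, out)
    if out.ndim == 0:
        return float(out)
    return out


def wall_frame(state: FishState, arena: ArenaSpec) -> WallFrame:
    """Wall frame ``(r_w, theta_w)`` of a fish in a circular arena.

    ``r_w = R - |x|`` and ``theta_w`` is the heading measured from the
    outward normal at the fish's position, positive counter-clockwise.
    With this sign convention a positive ``dphi * sign(theta_w)`` means
    the fish turned away from the wall.  At the exact centre the normal
    is undefined; we return ``theta_w = 0`` with ``degenerate=True`` so
    that callers can drop the (measure-zero) record.
    """
    rho = math.hypot(state.x, state.y)
    if rho >= arena.radius:
        raise ValueError(f"fish at distance {rho} outside arena R={arena.radius}")
    r_w = arena.radius - rho
    if rho == 0.0:
        return WallFrame(r_w=r_w, theta_w=0.0, degenerate=True)
    theta_w = wrap_angle(state.phi - math.atan2(state.y, state.x))
    return WallFrame(r_w=r_w, theta_w=theta_w)


def pair_frame(focal: FishState, other: FishState) -> PairFrame:
    """Pair frame ``(d, psi, dphi)`` of the other fish as seen by the focal.

    ``psi`` is the bearing of the other fish relative to the focal
    heading; ``dphi = phi_other - phi_focal``.  Note the viewing angle of
    the other fish is in general *not* ``-psi`` (social influences break
    action-reaction).  Coincident positions give ``d = 0`` with a
    degenerate flag.
    """
    dx = other.x - focal.x
    dy = other.y - focal.y
    d = math.hypot(dx, dy)
    dphi = wrap_angle(other.phi - focal.phi)
    if d == 0.0:
        return PairFrame(d=0.0, psi=0.0, dphi=dphi, degenerate=True)
    psi = wrap_angle(math.atan2(dy, dx) - focal.phi)
    return PairFrame(d=d, psi=psi, dphi=dphi)


_MIRROR_FIELDS = ("theta_w", "psi", "dphi", "dphi_pair")
_MIRROR_COLUMNS = ("theta_w_rad", "psi_rad", "dphi_rad", "dphi_pair_rad")


def mirror_record(record):
    """Mirror image of a kick record: all signed angles are negated.

    Reflecting the whole trajectory about any line through the arena
    centre negates ``theta_w``, ``psi``, ``dphi`` (heading difference)
    and the response ``dphi`` while leaving distances, lengths and
    durations unchanged.  Accepts a mapping (dict-like) or a pandas
    DataFrame/Series; returns the same type.  Applying it twice is the
    identity.
    """
    import pandas as pd

    if isinstance(record, (pd.DataFrame, pd.Series)):
        out = record.copy()
        for col in _MIRROR_COLUMNS:
            if col in out:
                out[col] = -out[col]
        return out
    out = dict(record)
    for key in _MIRROR_FIELDS + ("dphi_rad",):
        if key in out:
            out[key] = -out[key]
    return out


def parallax_correct(r, h: float, D: float, r_ccd) -> np.ndarray:
    """Project a position tracked at the tank floor to swimming height ``h``.

    A camera at distance ``D`` above the floor images a fish swimming at
    height ``h`` displaced radially from the image centre ``r_ccd``; the
    corrected position is ``(1 + h/(h+D)) (r - r_ccd) + r_ccd``.  With
    ``h = 0`` this is the identity and ``r_ccd`` is always a fixed point.
    """
    if h + D <= 0:
        raise ValueError("camera distance plus height must be positive")
    if D <= 0:
        raise ValueError("camera distance D must be positive")
    if h < 0:
        raise ValueError("swimming height h must be non-negative")
    r = np.asarray(r, dtype=float)
    r_ccd = np.asarray(r_ccd, dtype=float)
    return (1.0 + h / (h + D)) * (r - r_ccd) + r_ccd
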