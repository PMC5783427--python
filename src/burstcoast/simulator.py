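"""Stochastic burst-and-coast swimming model for one or two fish.

The model describes swimming as a sequence of discrete *kicks*: at kick
``n`` the fish at position ``x_n`` selects a new heading ``phi_{n+1}``, a
peak speed ``v_n`` and a kick length ``l_n``, then glides in a straight
line while its speed relaxes exponentially with dissipation time
``tau0``, so that the kick duration is
``tau_n = -tau0 * log(1 - l_n / (v_n tau0))``.

The per-kick heading change is a sum of four contributions::

    dphi = dphi_R(r_w) + dphi_W(r_w, theta_w) + dphi_Att(d, psi, dphi)
         + dphi_Ali(d, psi, dphi)

* ``dphi_R``  -- spontaneous Gaussian turn, std ``gamma_r [1 - alpha f_w(r_w)]``
  (angular fluctuations are damped near the wall);
* ``dphi_W``  -- wall avoidance, ``gamma_w O_w(theta_w) f_w(r_w)`` with
  ``f_w(r) = exp(-(r/l_w)^2)`` and an odd angular shape
  ``O_w ∝ sin(theta_w)[1 + 0.7 cos(2 theta_w)]``;
* ``dphi_Att`` -- attraction to the neighbour,
  ``gamma_att F_att(d) O_att(psi) E_att(dphi)``;
* ``dphi_Ali`` -- alignment with the neighbour,
  ``gamma_ali F_ali(d) O_ali(dphi) E_ali(psi)``.

All angular shape functions are normalised to unit mean square over
``(-pi, pi]``; the odd (O) factors encode the left/right antisymmetry of
the response and the even (E) factors the anisotropy of perception.

Proposed moves whose end point (padded by a comfort length ``l_c``)
would leave the circular arena are rejected and redrawn; after
``max_rejections`` failures the spontaneous component is drawn uniformly
in ``[-pi, pi]`` until a valid move is found.  This rejection step is
what concentrates trajectories near the wall.

The simulator doubles as the synthetic-data generator for the
segmentation and inference modules: it can resample its kick sequences
into 50 Hz trajectories (with optional positional noise) that mimic
tracked video data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .geometry import ArenaSpec, FishState, wrap_angle

__all__ = [
    "KickKinematicsConfig",
    "ModelParams",
    "SimulationResult",
    "f_w",
    "odd_shape",
    "even_shape",
    "shape_norm_constant",
    "attraction_distance_profile",
    "alignment_distance_profile",
    "spontaneous_turn",
    "wall_turn",
    "attraction_turn",
    "alignment_turn",
    "sample_kick_kinematics",
    "continuous_position",
    "simulate",
    "resample_trajectory",
]

KICK_COLUMNS = [
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
    "d_mm",
    "psi_rad",
    "dphi_pair_rad",
    "dphi_r_rad",
    "dphi_w_rad",
    "dphi_att_rad",
    "dphi_ali_rad",
    "n_rejections",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class KickKinematicsConfig:
    """Distributions of per-kick peak speed and kick length.

    Peak speed ``v_n`` (mm/s) and kick length ``l_n`` (mm) are drawn from
    log-normal distributions parameterised by their mean and standard
    deviation; the kick duration follows from the exponential-glide
    relation.  Pairs with ``tau_n`` undefined (``l_n >= v_n tau0``) or
    longer than ``tau_max`` are redrawn; kick durations beyond ~2 s are
    not observed in this swimming mode.

    The defaults are calibrated on the *realized* kick statistics of
    arena simulations (rejections near the wall truncate long kicks, so
    realized means sit below the nominal ones): mean inter-kick duration
    of about 0.5 s and mean glide speed (length over duration, the
    active-phase speed) of order 140 mm/s, with slightly shorter kicks
    for two fish.
    """

    v_mean: float = 165.0
    v_sd: float = 41.0
    l_mean: float = 92.0
    l_sd: float = 41.0
    tau0: float = 0.80
    tau_max: float = 2.0
    family: str = "lognormal"

    def __post_init__(self) -> None:
        if min(self.v_mean, self.v_sd, self.l_mean, self.l_sd) <= 0:
            raise ValueError("kinematics means and sds must be positive")
        if self.tau0 <= 0:
            raise ValueError("dissipation time tau0 must be positive")
        if self.family not in ("lognormal", "gamma"):
            raise ValueError(f"unknown distribution family {self.family!r}")

    @classmethod
    def single(cls) -> "KickKinematicsConfig":
        return cls()

    @classmethod
    def pair(cls) -> "KickKinematicsConfig":
        return cls(v_mean=140.0, v_sd=35.0, l_mean=64.0, l_sd=29.0)


# Reference parameter sets (comfort length, spontaneous turn scale, its
# value at the wall, wall repulsion strength) per condition: (n_fish, R).
_REFERENCE_PARAMS = {
    (1, 176): (21.0, 0.35, 0.12, 0.40),
    (1, 250): (30.0, 0.35, 0.14, 0.12),
    (1, 353): (45.0, 0.35, 0.11, 0.10),
    (2, 250): (30.0, 0.45, 0.15, 0.15),
}


@dataclass(frozen=True)
class ModelParams:
    """Behavioural parameters of the burst-and-coast model.

    Angular anisotropies are given as cosine-series coefficients: an odd
    factor is ``sin(t) (1 + sum_k c_k cos(k t))`` and an even factor is
    ``1 + sum_k c_k cos(k t)``, each rescaled to unit mean square.  The
    defaults reproduce the measured shapes for the wall, attraction and
    alignment interactions of rummy-nose tetra.
    """

    gamma_r: float = 0.35        # spontaneous turn scale (rad)
    alpha: float = 2.0 / 3.0     # fluctuation damping at the wall
    gamma_w: float = 0.12        # wall repulsion amplitude (rad)
    l_w: float = 60.0            # wall interaction range (mm), ~2 BL
    eps_w: tuple = (0.0, 0.7)    # wall angular anisotropy (cos, cos2)
    l_c: float = 30.0            # comfort length (mm), ~1 BL
    gamma_att: float = 0.15      # attraction amplitude (rad)
    gamma_ali: float = 0.08      # alignment amplitude (rad)
    d_0: float = 30.0            # attraction zero crossing (mm), ~1 BL
    l_att: float = 200.0         # attraction range (mm)
    d_0p: float = 30.0           # alignment offset (mm)
    l_ali: float = 200.0         # alignment range (mm)
    att_psi_coeffs: tuple = (-0.33,)        # O_att(psi)
    att_dphi_coeffs: tuple = (0.48, -0.31)  # E_att(dphi)
    ali_dphi_coeffs: tuple = (0.0, 0.30)    # O_ali(dphi)
    ali_psi_coeffs: tuple = (0.60, -0.32)   # E_ali(psi)
    max_rejections: int = 1000
    hard_rejection_cap: int = 1_000_000

    def __post_init__(self) -> None:
        if self.gamma_r < 0:
            raise ValueError("gamma_r must be non-negative")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        for name in ("l_w", "l_c", "l_att", "l_ali"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def reference(cls, n_fish: int = 1, radius: float = 250.0, **overrides) -> "ModelParams":
        """Parameters measured for a given condition (fish count, tank radius)."""
        key = (int(n_fish), int(round(radius)))
        if key not in _REFERENCE_PARAMS:
            raise KeyError(
                f"no reference parameters for {n_fish} fish, R={radius} mm; "
                f"known conditions: {sorted(_REFERENCE_PARAMS)}"
            )
        l_c, gamma_r, gamma_r_wall, gamma_w = _REFERENCE_PARAMS[key]
        alpha = 1.0 - gamma_r_wall / gamma_r
        return cls(
            gamma_r=gamma_r, alpha=alpha, gamma_w=gamma_w, l_c=l_c, **overrides
        )


# ---------------------------------------------------------------------------
# interaction functions


def f_w(r_w, l_w: float):
    """Gaussian wall-proximity factor ``exp(-(r_w/l_w)^2)``; 1 at the wall."""
    if l_w <= 0:
        raise ValueError("wall range l_w must be positive")
    r_w = np.asarray(r_w, dtype=float)
    out = np.exp(-((r_w / l_w) ** 2))
    return float(out) if out.ndim == 0 else out


def _raw_odd(theta, coeffs):
    mod = np.ones_like(theta)
    for k, c in enumerate(coeffs, start=1):
        mod = mod + c * np.cos(k * theta)
    return np.sin(theta) * mod


def _raw_even(theta, coeffs):
    out = np.ones_like(theta)
    for k, c in enumerate(coeffs, start=1):
        out = out + c * np.cos(k * theta)
    return out


@lru_cache(maxsize=64)
def shape_norm_constant(coeffs: tuple, parity: str) -> float:
    """Constant C such that C * shape has unit mean square on ``(-pi, pi]``.

    The mean square is evaluated by trapezoidal quadrature on a fine
    grid; the shapes are trigonometric polynomials so this is accurate
    far beyond the 1e-6 convention tolerance.
    """
    theta = np.linspace(-np.pi, np.pi, 8193)
    raw = _raw_odd(theta, coeffs) if parity == "odd" else _raw_even(theta, coeffs)
    ms = np.trapezoid(raw**2, theta) / (2.0 * np.pi)
    if ms <= 0:
        raise ValueError("degenerate angular shape: zero mean square")
    return 1.0 / math.sqrt(ms)


def odd_shape(theta, coeffs=()):
    """Odd angular factor ``C sin(t)(1 + sum c_k cos kt)``, unit mean square."""
    theta = np.asarray(theta, dtype=float)
    out = shape_norm_constant(tuple(coeffs), "odd") * _raw_odd(theta, coeffs)
    return float(out) if out.ndim == 0 else out


def even_shape(theta, coeffs=()):
    """Even angular factor ``C (1 + sum c_k cos kt)``, unit mean square."""
    theta = np.asarray(theta, dtype=float)
    out = shape_norm_constant(tuple(coeffs), "even") * _raw_even(theta, coeffs)
    return float(out) if out.ndim == 0 else out


def attraction_distance_profile(d, d_0: float = 30.0, l_att: float = 200.0):
    """Attraction strength vs distance, ``(d - d_0)/(1 + (d/l_att)^2)``.

    Negative below ``d_0`` (short-range repulsion), rising to a maximum
    near ``l_att``, then decaying like ``1/d`` as expected for an
    interaction mediated by the apparent (angular) size of the
    neighbour.  Normalised so the value at ``d = l_att`` is 1.
    """
    d = np.asarray(d, dtype=float)
    scale = (l_att - d_0) / 2.0
    out = (d - d_0) / (1.0 + (d / l_att) ** 2) / scale
    return float(out) if out.ndim == 0 else out


def alignment_distance_profile(d, d_0p: float = 30.0, l_ali: float = 200.0):
    """Alignment strength vs distance, ``(d + d_0p) exp(-(d/l_ali)^2)``.

    Strong at short range with a Gaussian envelope of scale ``l_ali``;
    normalised to 1 at its maximum.
    """
    d = np.asarray(d, dtype=float)
    d_star = (-d_0p + math.sqrt(d_0p**2 + 2.0 * l_ali**2)) / 2.0
    peak = (d_star + d_0p) * math.exp(-((d_star / l_ali) ** 2))
    out = (d + d_0p) * np.exp(-((d / l_ali) ** 2)) / peak
    return float(out) if out.ndim == 0 else out


def spontaneous_turn(r_w: float, rng: np.random.Generator, params: ModelParams) -> float:
    """Random heading change, Gaussian with std ``gamma_r [1 - alpha f_w(r_w)]``."""
    sd = params.gamma_r * (1.0 - params.alpha * f_w(r_w, params.l_w))
    return sd * rng.standard_normal()


def wall_turn(frame, params: ModelParams) -> float:
    """Deterministic wall-avoidance turn.

    ``gamma_w sin(theta_w)[1 + eps_w(theta_w)] f_w(r_w)``: the amplitude
    ``gamma_w`` multiplies the *raw* angular shape (no unit-mean-square
    rescaling), which is the convention in which the reference values of
    ``gamma_w`` are calibrated.  The unit-mean-square convention applies
    only to factors measured by the inference module.
    """
    theta = np.asarray(frame.theta_w, dtype=float)
    return float(
        params.gamma_w
        * _raw_odd(theta, params.eps_w)
        * f_w(frame.r_w, params.l_w)
    )


def attraction_turn(frame, params: ModelParams) -> float:
    """Attraction turn ``gamma_att F_att(d) O_att(psi) E_att(dphi)``."""
    return (
        params.gamma_att
        * attraction_distance_profile(frame.d, params.d_0, params.l_att)
        * odd_shape(frame.psi, params.att_psi_coeffs)
        * even_shape(frame.dphi, params.att_dphi_coeffs)
    )


def alignment_turn(frame, params: ModelParams) -> float:
    """Alignment turn ``gamma_ali F_ali(d) O_ali(dphi) E_ali(psi)``."""
    return (
        params.gamma_ali
        * alignment_distance_profile(frame.d, params.d_0p, params.l_ali)
        * odd_shape(frame.dphi, params.ali_dphi_coeffs)
        * even_shape(frame.psi, params.ali_psi_coeffs)
    )


# ---------------------------------------------------------------------------
# kick kinematics


def tau_from_length(l: float, v: float, tau0: float) -> float:
    """Invert the glide relation ``l = v tau0 (1 - exp(-tau/tau0))``."""
    x = l / (v * tau0)
    if x >= 1.0:
        return math.inf
    return -tau0 * math.log1p(-x)


def sample_kick_kinematics(rng: np.random.Generator, config: KickKinematicsConfig,
                           min_v: float = 0.0):
    """Draw one ``(v_n, l_n, tau_n)`` triple from the configured distributions.

    ``min_v`` is the speed at the end of the previous glide: a kick is by
    definition a burst, so the new peak speed must exceed the current
    speed (otherwise the decision would produce no acceleration and be
    invisible in the speed trace).  The constraint is capped at the 98th
    percentile of the peak-speed distribution so that a fish already
    moving faster than almost any burst (e.g. after a chain of very
    short glides) is not pushed ever deeper into the tail.  Pairs with
    an undefined or over-long duration are also redrawn.
    """
    tau0 = config.tau0
    min_v = min(min_v, _v_cap(config))
    for _ in range(100_000):
        v = _draw_positive(rng, config.v_mean, config.v_sd, config.family)
        if v <= min_v:
            continue
        l = _draw_positive(rng, config.l_mean, config.l_sd, config.family)
        if l >= v * tau0:
            continue
        tau = tau_from_length(l, v, tau0)
        if tau <= config.tau_max:
            return v, l, tau
    raise RuntimeError("kick kinematics sampling failed: config inconsistent")


@lru_cache(maxsize=32)
def _v_cap_cached(v_mean, v_sd, family):
    from scipy import stats

    if family == "lognormal":
        sigma2 = math.log(1.0 + (v_sd / v_mean) ** 2)
        mu = math.log(v_mean) - sigma2 / 2.0
        return float(stats.lognorm.ppf(0.98, math.sqrt(sigma2), scale=math.exp(mu)))
    shape = (v_mean / v_sd) ** 2
    return float(stats.gamma.ppf(0.98, shape, scale=v_sd**2 / v_mean))


def _v_cap(config: KickKinematicsConfig) -> float:
    return _v_cap_cached(config.v_mean, config.v_sd, config.family)


def _draw_positive(rng, mean, sd, family):
    if family == "lognormal":
        sigma2 = math.log(1.0 + (sd / mean) ** 2)
        mu = math.log(mean) - sigma2 / 2.0
        return float(rng.lognormal(mu, math.sqrt(sigma2)))
    # gamma with matching mean/sd
    shape = (mean / sd) ** 2
    return float(rng.gamma(shape, sd**2 / mean))


def continuous_position(kick, t: float, tau0: float = 0.80) -> np.ndarray:
    """Position during the glide, ``0 <= t <= tau``, by exponential relaxation.

    ``kick`` is any mapping with keys ``x_mm``, ``y_mm`` (start of the
    glide), ``phi_rad`` (glide direction), ``l_mm`` and ``tau_s``.  The
    endpoints reproduce the decision points exactly and the speed at
    ``t = 0`` equals the peak speed.
    """
    tau = float(kick["tau_s"])
    if t < -1e-12 or t > tau + 1e-12:
        raise ValueError(f"glide time {t} outside [0, {tau}]")
    x0 = float(kick["x_mm"])
    y0 = float(kick["y_mm"])
    if tau <= 0.0:
        return np.array([x0, y0])
    frac = (1.0 - math.exp(-t / tau0)) / (1.0 - math.exp(-tau / tau0))
    l = float(kick["l_mm"])
    phi = float(kick["phi_rad"])
    return np.array([x0 + l * frac * math.cos(phi), y0 + l * frac * math.sin(phi)])


def _glide_fraction(t, tau, tau0):
    """Vectorised fraction of the kick length covered after time ``t``."""
    t = np.asarray(t, dtype=float)
    tau = np.asarray(tau, dtype=float)
    frac = np.zeros_like(t)
    ok = tau > 0
    frac[ok] = (1.0 - np.exp(-t[ok] / tau0)) / (1.0 - np.exp(-tau[ok] / tau0))
    return frac


# ---------------------------------------------------------------------------
# simulation


@dataclass
class SimulationResult:
    """Kick log of a run plus everything needed to rebuild the trajectory."""

    kicks: pd.DataFrame
    arena: ArenaSpec
    params: ModelParams
    kinematics: KickKinematicsConfig
    n_fish: int
    seed: int

    def trajectory(self, rate_hz: float = 50.0, noise_mm: float = 0.0,
                   noise_seed: int | None = None) -> pd.DataFrame:
        """Resample the run at ``rate_hz`` with optional positional noise."""
        rng = np.random.default_rng(
            self.seed + 7_654_321 if noise_seed is None else noise_seed
        )
        frames = [
            resample_trajectory(
                self.kicks[self.kicks.fish_id == fid],
                rate_hz=rate_hz,
                tau0=self.kinematics.tau0,
                noise_mm=noise_mm,
                rng=rng,
                fish_id=fid,
            )
            for fid in sorted(self.kicks.fish_id.unique())
        ]
        out = pd.concat(frames, ignore_index=True)
        return out.sort_values(["time_s", "fish_id"], ignore_index=True)


class _Fish:
    """Internal per-fish bookkeeping: last decision point and current glide."""

    __slots__ = ("x", "y", "phi", "t", "l", "tau", "v", "rng")

    def __init__(self, x, y, phi, rng):
        self.x = x
        self.y = y
        self.phi = wrap_angle(phi)
        self.t = 0.0
        self.l = 0.0
        self.tau = 0.0
        self.v = 0.0
        self.rng = rng

    @property
    def t_next(self):
        return self.t + self.tau

    def endpoint(self):
        return (
            self.x + self.l * math.cos(self.phi),
            self.y + self.l * math.sin(self.phi),
        )

    def pose_at(self, t, tau0):
        """Interpolated position along the current glide; heading is the
        glide direction."""
        if self.tau <= 0.0:
            return self.x, self.y, self.phi
        s = min(max(t - self.t, 0.0), self.tau)
        frac = (1.0 - math.exp(-s / tau0)) / (1.0 - math.exp(-self.tau / tau0))
        return (
            self.x + self.l * frac * math.cos(self.phi),
            self.y + self.l * frac * math.sin(self.phi),
            self.phi,
        )


def simulate(
    n_fish: int,
    n_kicks: int,
    arena: ArenaSpec | float,
    params: ModelParams | None = None,
    kinematics: KickKinematicsConfig | None = None,
    seed: int = 0,
    initial_states: list[FishState] | None = None,
    flip_angles: bool = False,
) -> SimulationResult:
    """Run the burst-and-coast model and return the kick log.

    ``n_kicks`` counts total kicks across fish.  Each fish consumes its
    own named random stream (derived from ``seed``) in a fixed order, so
    runs are reproducible bit for bit.  ``flip_angles`` negates every
    random angular draw, which maps a run started from the mirrored
    initial condition onto the exact mirror image of the original run
    (used by the symmetry test-suite).

    Two-fish runs are event driven: the fish whose current glide ends
    first kicks next, with its partner's pose interpolated along the
    partner's glide at that instant.

    The kick log has one row per decision: the decision point, the
    outgoing heading ``phi_rad``, the executed turn ``dphi_rad``, the
    glide kinematics, the stimulus frames evaluated with the *incoming*
    heading, the four turn components, and the rejection count.
    """
    if n_fish not in (1, 2):
        raise ValueError("n_fish must be 1 or 2")
    if not isinstance(arena, ArenaSpec):
        arena = ArenaSpec(float(arena))
    if params is None:
        params = (
            ModelParams.reference(n_fish, arena.radius)
            if (n_fish, int(round(arena.radius))) in _REFERENCE_PARAMS
            else ModelParams()
        )
    if kinematics is None:
        kinematics = (
            KickKinematicsConfig.pair() if n_fish == 2 else KickKinematicsConfig.single()
        )

    sign = -1.0 if flip_angles else 1.0
    streams = np.random.SeedSequence(seed).spawn(n_fish)
    R = arena.radius
    tau0 = kinematics.tau0

    if initial_states is None:
        init_rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[-1])
        fishes = []
        for i in range(n_fish):
            rho = 0.5 * R * math.sqrt(init_rng.uniform())
            ang = sign * init_rng.uniform(-math.pi, math.pi)
            fishes.append(
                _Fish(
                    rho * math.cos(ang),
                    rho * math.sin(ang),
                    sign * init_rng.uniform(-math.pi, math.pi),
                    np.random.default_rng(streams[i]),
                )
            )
    else:
        if len(initial_states) != n_fish:
            raise ValueError("initial_states length must equal n_fish")
        fishes = [
            _Fish(s.x, s.y, s.phi, np.random.default_rng(streams[i]))
            for i, s in enumerate(initial_states)
        ]
    for f in fishes:
        if math.hypot(f.x, f.y) >= R:
            raise ValueError("initial position outside the arena")

    norm_wall = 1.0  # gamma_w multiplies the raw sin-shape (see wall_turn)
    norm_o_att = shape_norm_constant(tuple(params.att_psi_coeffs), "odd")
    norm_e_att = shape_norm_constant(tuple(params.att_dphi_coeffs), "even")
    norm_o_ali = shape_norm_constant(tuple(params.ali_dphi_coeffs), "odd")
    norm_e_ali = shape_norm_constant(tuple(params.ali_psi_coeffs), "even")

    rows = np.empty((n_kicks, len(KICK_COLUMNS)))
    gamma_r, alpha = params.gamma_r, params.alpha
    gamma_w, l_w = params.gamma_w, params.l_w
    l_c = params.l_c
    eps_w = params.eps_w
    att_psi, att_dphi = params.att_psi_coeffs, params.att_dphi_coeffs
    ali_dphi, ali_psi = params.ali_dphi_coeffs, params.ali_psi_coeffs

    def _poly(theta, coeffs, norm, odd):
        mod = 1.0
        for k, c in enumerate(coeffs, start=1):
            mod += c * math.cos(k * theta)
        return norm * (math.sin(theta) * mod if odd else mod)

    for n in range(n_kicks):
        # fish whose glide ends first kicks next (ties: lower id)
        i = min(range(n_fish), key=lambda j: (fishes[j].t_next, j))
        fish = fishes[i]
        rng = fish.rng
        t_kick = fish.t_next
        x, y = fish.endpoint()
        phi_in = fish.phi  # incoming heading = direction of previous glide

        # stimulus: wall frame
        rho = math.hypot(x, y)
        r_w = R - rho
        theta_w = wrap_angle(phi_in - math.atan2(y, x)) if rho > 0 else 0.0
        fw = math.exp(-((r_w / l_w) ** 2))
        d_w = gamma_w * _poly(theta_w, eps_w, norm_wall, True) * fw

        # stimulus: pair frame (partner pose interpolated at t_kick)
        if n_fish == 2:
            other = fishes[1 - i]
            ox, oy, ophi = other.pose_at(t_kick, tau0)
            dx, dy = ox - x, oy - y
            d = math.hypot(dx, dy)
            dphi_pair = wrap_angle(ophi - phi_in)
            psi = wrap_angle(math.atan2(dy, dx) - phi_in) if d > 0 else 0.0
            scale_att = (params.l_att - params.d_0) / 2.0
            f_att = (d - params.d_0) / (1.0 + (d / params.l_att) ** 2) / scale_att
            d_star = (-params.d_0p + math.sqrt(params.d_0p**2 + 2 * params.l_ali**2)) / 2
            peak = (d_star + params.d_0p) * math.exp(-((d_star / params.l_ali) ** 2))
            f_ali = (d + params.d_0p) * math.exp(-((d / params.l_ali) ** 2)) / peak
            d_att = (
                params.gamma_att
                * f_att
                * _poly(psi, att_psi, norm_o_att, True)
                * _poly(dphi_pair, att_dphi, norm_e_att, False)
            )
            d_ali = (
                params.gamma_ali
                * f_ali
                * _poly(dphi_pair, ali_dphi, norm_o_ali, True)
                * _poly(psi, ali_psi, norm_e_ali, False)
            )
        else:
            d = psi = dphi_pair = math.nan
            d_att = d_ali = 0.0

        det_turn = d_w + d_att + d_ali
        sd_r = gamma_r * (1.0 - alpha * fw)

        # speed at the end of the incoming glide: the new burst must top it
        v_now = fish.v * math.exp(-fish.tau / tau0) if fish.tau > 0 else 0.0

        # propose, rejecting moves that would exit the arena
        rejections = 0
        while True:
            v, l, tau = sample_kick_kinematics(rng, kinematics, min_v=v_now)
            if rejections < params.max_rejections:
                d_r = sd_r * sign * rng.standard_normal()
            else:
                # fallback for fish trapped heading into the wall
                d_r = sign * rng.uniform(-math.pi, math.pi)
            dphi = d_r + det_turn
            phi_new = phi_in + dphi
            reach = l + l_c
            xe = x + reach * math.cos(phi_new)
            ye = y + reach * math.sin(phi_new)
            if xe * xe + ye * ye < R * R:
                break
            rejections += 1
            if rejections >= params.hard_rejection_cap:
                raise RuntimeError(
                    "rejection cap exceeded: no valid kick found "
                    f"(fish {i} at r_w={r_w:.1f} mm)"
                )

        phi_new = wrap_angle(phi_new)
        rows[n] = (
            t_kick, i, x, y, phi_new, wrap_angle(dphi), v, l, tau,
            r_w, theta_w, d, psi, dphi_pair, d_r, d_w, d_att, d_ali, rejections,
        )

        fish.x, fish.y = x, y
        fish.phi = phi_new
        fish.t = t_kick
        fish.l, fish.tau, fish.v = l, tau, v

    kicks = pd.DataFrame(rows, columns=KICK_COLUMNS)
    kicks["fish_id"] = kicks["fish_id"].astype(int)
    kicks["n_rejections"] = kicks["n_rejections"].astype(int)
    if n_fish == 1:
        kicks = kicks.drop(columns=["d_mm", "psi_rad", "dphi_pair_rad"])
    return SimulationResult(
        kicks=kicks, arena=arena, params=params, kinematics=kinematics,
        n_fish=n_fish, seed=seed,
    )


def resample_trajectory(
    kicks: pd.DataFrame,
    rate_hz: float = 50.0,
    tau0: float = 0.80,
    noise_mm: float = 0.0,
    rng: np.random.Generator | None = None,
    fish_id: int = 0,
) -> pd.DataFrame:
    """Turn one fish's kick log into a uniformly sampled trajectory.

    Positions between decision points follow the exponential glide;
    optional isotropic Gaussian noise of scale ``noise_mm`` per
    coordinate emulates tracking error.
    """
    kicks = kicks.sort_values("t_s")
    t0 = kicks["t_s"].to_numpy()
    x0 = kicks["x_mm"].to_numpy()
    y0 = kicks["y_mm"].to_numpy()
    phi = kicks["phi_rad"].to_numpy()
    l = kicks["l_mm"].to_numpy()
    tau = kicks["tau_s"].to_numpy()
    t_end = t0[-1] + tau[-1]

    dt = 1.0 / rate_hz
    t = np.arange(t0[0], t_end, dt)
    seg = np.clip(np.searchsorted(t0, t, side="right") - 1, 0, len(t0) - 1)
    s = np.clip(t - t0[seg], 0.0, tau[seg])
    frac = _glide_fraction(s, tau[seg], tau0)
    x = x0[seg] + l[seg] * frac * np.cos(phi[seg])
    y = y0[seg] + l[seg] * frac * np.sin(phi[seg])
    if noise_mm > 0.0:
        if rng is None:
            rng = np.random.default_rng()
        x = x + noise_mm * rng.standard_normal(len(x))
        y = y + noise_mm * rng.standard_normal(len(y))
    return pd.DataFrame(
        {"time_s": t, "fish_id": fish_id, "x_mm": x, "y_mm": y}
    )
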