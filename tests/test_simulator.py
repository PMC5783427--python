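import math

import numpy as np
import pytest

from burstcoast import (
    ArenaSpec,
    FishState,
    KickKinematicsConfig,
    ModelParams,
    PairFrame,
    WallFrame,
    alignment_turn,
    attraction_turn,
    continuous_position,
    even_shape,
    f_w,
    odd_shape,
    sample_kick_kinematics,
    simulate,
    spontaneous_turn,
    wall_turn,
)
from burstcoast.simulator import tau_from_length


class TestWallProximityFactor:
    def test_values(self):
        assert f_w(0.0, 60.0) == 1.0
        assert f_w(60.0, 60.0) == pytest.approx(math.exp(-1), abs=1e-12)
        assert f_w(60.0, 60.0) == pytest.approx(0.3679, abs=1e-4)

    def test_monotone_decreasing(self):
        r = np.linspace(0, 300, 100)
        assert np.all(np.diff(f_w(r, 60.0)) < 0)

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            f_w(10.0, 0.0)


class TestAngularShapes:
    """All angular factors are normalized to unit mean square on (-pi, pi]."""

    @pytest.mark.parametrize(
        "shape, coeffs",
        [
            (odd_shape, (0.0, 0.7)),     # wall
            (odd_shape, (-0.33,)),       # attraction, viewing angle
            (odd_shape, (0.0, 0.30)),    # alignment, heading difference
            (even_shape, (0.48, -0.31)),  # attraction, heading difference
            (even_shape, (0.60, -0.32)),  # alignment, viewing angle
        ],
    )
    def test_unit_mean_square(self, shape, coeffs):
        theta = np.linspace(-np.pi, np.pi, 200_001)
        ms = np.trapezoid(shape(theta, coeffs) ** 2, theta) / (2 * np.pi)
        assert ms == pytest.approx(1.0, abs=1e-6)

    def test_odd_parity(self):
        theta = np.linspace(0.1, 3.0, 50)
        np.testing.assert_allclose(
            odd_shape(-theta, (0.0, 0.7)), -odd_shape(theta, (0.0, 0.7))
        )

    def test_even_parity(self):
        theta = np.linspace(0.1, 3.0, 50)
        np.testing.assert_allclose(
            even_shape(-theta, (0.6, -0.32)), even_shape(theta, (0.6, -0.32))
        )


class TestTurnContributions:
    params = ModelParams()

    def test_spontaneous_sd_far_from_wall(self, rng):
        # far from the wall the std approaches gamma_r = 0.35
        draws = [spontaneous_turn(1e6, rng, self.params) for _ in range(4000)]
        assert np.std(draws) == pytest.approx(0.35, rel=0.05)

    def test_spontaneous_sd_at_wall(self, rng):
        p = ModelParams(gamma_r=0.35, alpha=2 / 3)
        draws = [spontaneous_turn(0.0, rng, p) for _ in range(4000)]
        assert np.std(draws) == pytest.approx(0.35 / 3, rel=0.07)

    def test_spontaneous_zero_scale(self, rng):
        p = ModelParams(gamma_r=0.0)
        assert spontaneous_turn(10.0, rng, p) == 0.0

    @pytest.mark.parametrize("theta", [0.0, math.pi, -math.pi])
    def test_wall_turn_odd_zeros(self, theta):
        frame = WallFrame(r_w=5.0, theta_w=theta)
        assert wall_turn(frame, self.params) == pytest.approx(0.0, abs=1e-12)

    def test_wall_turn_value_at_quarter(self):
        # raw-shape convention: gamma_w * sin(pi/2) * (1 + 0.7 cos(pi)) * f_w(0)
        p = ModelParams(gamma_w=0.40)
        frame = WallFrame(r_w=0.0, theta_w=math.pi / 2)
        assert wall_turn(frame, p) == pytest.approx(0.40 * 0.3, abs=1e-12)

    def test_attraction_zero_at_comfort_distance(self):
        frame = PairFrame(d=self.params.d_0, psi=1.0, dphi=0.5)
        assert attraction_turn(frame, self.params) == pytest.approx(0.0, abs=1e-12)

    def test_attraction_zero_at_psi_zero(self):
        frame = PairFrame(d=100.0, psi=0.0, dphi=0.5)
        assert attraction_turn(frame, self.params) == pytest.approx(0.0, abs=1e-12)

    def test_short_range_repulsion_sign(self):
        # below d_0 with the partner to the left, the focal fish turns away
        frame = PairFrame(d=10.0, psi=1.0, dphi=0.0)
        assert attraction_turn(frame, self.params) < 0

    def test_alignment_zero_when_aligned(self):
        frame = PairFrame(d=100.0, psi=1.0, dphi=0.0)
        assert alignment_turn(frame, self.params) == pytest.approx(0.0, abs=1e-12)

    def test_alignment_perception_ratio(self):
        # E_ali nearly vanishes behind: E(0)/E(pi) = 1.28/0.08 = 16
        ratio = even_shape(0.0, (0.60, -0.32)) / even_shape(math.pi, (0.60, -0.32))
        assert ratio == pytest.approx(16.0, rel=1e-9)

    def test_pair_turns_odd_under_joint_mirror(self):
        frame = PairFrame(d=80.0, psi=0.7, dphi=-0.4)
        mirror = PairFrame(d=80.0, psi=-0.7, dphi=0.4)
        assert attraction_turn(mirror, self.params) == pytest.approx(
            -attraction_turn(frame, self.params)
        )
        assert alignment_turn(mirror, self.params) == pytest.approx(
            -alignment_turn(frame, self.params)
        )


class TestKickKinematics:
    def test_glide_inversion(self):
        # l = v tau0 (1 - e^-1)  =>  tau = tau0
        tau0 = 0.8
        v = 150.0
        l = v * tau0 * (1 - math.exp(-1))
        assert tau_from_length(l, v, tau0) == pytest.approx(tau0)

    def test_samples_satisfy_glide_relation(self, rng):
        cfg = KickKinematicsConfig()
        for _ in range(200):
            v, l, tau = sample_kick_kinematics(rng, cfg)
            assert l < v * cfg.tau0
            assert l == pytest.approx(
                v * cfg.tau0 * (1 - math.exp(-tau / cfg.tau0)), rel=1e-9
            )
            assert 0 < tau <= cfg.tau_max

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            KickKinematicsConfig(v_mean=-1.0)
        with pytest.raises(ValueError):
            KickKinematicsConfig(family="cauchy")


class TestContinuousGlide:
    kick = {"x_mm": 10.0, "y_mm": -5.0, "phi_rad": math.pi / 3, "l_mm": 80.0,
            "tau_s": 0.6}

    def test_endpoints(self):
        start = continuous_position(self.kick, 0.0)
        assert start == pytest.approx([10.0, -5.0])
        end = continuous_position(self.kick, self.kick["tau_s"])
        expected = np.array([10.0, -5.0]) + 80.0 * np.array(
            [math.cos(math.pi / 3), math.sin(math.pi / 3)]
        )
        assert end == pytest.approx(expected, abs=1e-9)

    def test_initial_speed_is_peak_speed(self):
        tau0 = 0.8
        v = self.kick["l_mm"] / (
            tau0 * (1 - math.exp(-self.kick["tau_s"] / tau0))
        )
        dt = 1e-6
        p0 = continuous_position(self.kick, 0.0, tau0)
        p1 = continuous_position(self.kick, dt, tau0)
        assert np.hypot(*(p1 - p0)) / dt == pytest.approx(v, rel=1e-4)

    def test_speed_decays_exponentially(self):
        tau0 = 0.8
        t = np.linspace(0.01, 0.5, 20)
        dt = 1e-6
        speeds = [
            np.hypot(*(continuous_position(self.kick, ti + dt, tau0)
                       - continuous_position(self.kick, ti, tau0))) / dt
            for ti in t
        ]
        v0 = speeds[0] / math.exp(-t[0] / tau0)
        np.testing.assert_allclose(speeds, v0 * np.exp(-t / tau0), rtol=1e-4)

    def test_out_of_range_time(self):
        with pytest.raises(ValueError):
            continuous_position(self.kick, 0.7)


class TestSimulate:
    def test_all_positions_inside_arena(self, single_run, pair_run):
        for run in (single_run, pair_run):
            rho = np.hypot(run.kicks.x_mm, run.kicks.y_mm)
            assert np.all(rho < run.arena.radius)

    def test_deterministic_given_seed(self):
        a = simulate(1, 200, 250.0, seed=9).kicks
        b = simulate(1, 200, 250.0, seed=9).kicks
        assert a.equals(b)

    def test_glide_endpoint_consistency(self, single_run):
        """Interpolated position at tau reproduces the next decision point."""
        k = single_run.kicks
        tau0 = single_run.kinematics.tau0
        for i in range(0, 500):
            row = k.iloc[i]
            end = continuous_position(row, row.tau_s, tau0)
            nxt = k.iloc[i + 1]
            assert np.hypot(end[0] - nxt.x_mm, end[1] - nxt.y_mm) < 1e-9

    def test_mirror_equivariance(self):
        """A mirrored start with sign-flipped angular draws gives the exact
        mirror run."""
        init = [FishState(x=40.0, y=30.0, phi=0.8)]
        init_m = [FishState(x=40.0, y=-30.0, phi=-0.8)]
        a = simulate(1, 300, 250.0, seed=5, initial_states=init).kicks
        b = simulate(
            1, 300, 250.0, seed=5, initial_states=init_m, flip_angles=True
        ).kicks
        np.testing.assert_allclose(b.x_mm, a.x_mm, atol=1e-9)
        np.testing.assert_allclose(b.y_mm, -a.y_mm, atol=1e-9)
        np.testing.assert_allclose(b.dphi_rad, -a.dphi_rad, atol=1e-9)
        np.testing.assert_allclose(b.theta_w_rad, -a.theta_w_rad, atol=1e-9)

    def test_mirror_equivariance_pair(self):
        init = [FishState(60.0, 10.0, 0.3), FishState(-20.0, 40.0, -1.2)]
        init_m = [FishState(60.0, -10.0, -0.3), FishState(-20.0, -40.0, 1.2)]
        a = simulate(2, 400, 250.0, seed=8, initial_states=init).kicks
        b = simulate(
            2, 400, 250.0, seed=8, initial_states=init_m, flip_angles=True
        ).kicks
        np.testing.assert_allclose(b.y_mm, -a.y_mm, atol=1e-9)
        np.testing.assert_allclose(b.psi_rad, -a.psi_rad, atol=1e-9)
        np.testing.assert_allclose(b.dphi_pair_rad, -a.dphi_pair_rad, atol=1e-9)

    def test_free_turning_matches_wrapped_gaussian_walk(self):
        """With all interactions off the heading performs a Gaussian random
        walk: the circular resultant after n kicks is exp(-n gamma_r^2 / 2)."""
        gamma = 0.35
        params = ModelParams(gamma_r=gamma, alpha=0.0, gamma_w=0.0,
                             gamma_att=0.0, gamma_ali=0.0, l_c=1e-9)
        # huge arena so the wall rejection never bites
        kin = KickKinematicsConfig(l_mean=5.0, l_sd=1.0, v_mean=180.0, v_sd=30.0)
        run = simulate(1, 20_000, ArenaSpec(1e6), params=params,
                       kinematics=kin, seed=13,
                       initial_states=[FishState(0.0, 0.0, 0.0)])
        dphi = run.kicks.dphi_rad.to_numpy()
        assert run.kicks.n_rejections.sum() == 0
        assert np.std(dphi) == pytest.approx(gamma, rel=0.02)
        n = 10
        phi_n = np.cumsum(dphi)[n - 1 :: n]  # headings every n kicks, iid increments
        resultant = abs(np.mean(np.exp(1j * np.diff(phi_n))))
        assert resultant == pytest.approx(math.exp(-n * gamma**2 / 2), abs=0.03)

    def test_wall_accumulation(self, single_run):
        """Burst-and-coast plus wall avoidance concentrates the fish near the
        wall: the modal wall distance is within one body length."""
        hist, edges = np.histogram(
            single_run.kicks.r_w_mm, bins=40, range=(0, 250.0)
        )
        mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
        assert mode < 30.0

    def test_leader_closer_to_wall(self, pair_run):
        """The geometrical leader hugs the bend; the follower cuts inside."""
        from burstcoast.observables import kick_statistics

        stats = kick_statistics(pair_run.kicks, radius=250.0)
        assert stats["leader_mean_r_w_mm"] < stats["follower_mean_r_w_mm"]

    def test_trajectory_resampling_matches_kicks(self, single_run):
        traj = single_run.trajectory(rate_hz=50.0, noise_mm=0.0)
        k = single_run.kicks
        # sampled positions stay inside the arena and start near first kick
        assert np.all(np.hypot(traj.x_mm, traj.y_mm) < 250.0 + 1e-6)
        assert traj.time_s.diff().dropna().round(9).nunique() == 1
        first = traj.iloc[0]
        assert np.hypot(first.x_mm - k.iloc[0].x_mm,
                        first.y_mm - k.iloc[0].y_mm) < 1e-6

    def test_reference_params_alpha(self):
        p = ModelParams.reference(1, 353)
        assert p.gamma_r == 0.35 and p.gamma_w == 0.10 and p.l_c == 45.0
        # damped scale at the wall equals the tabulated near-wall value
        assert p.gamma_r * (1 - p.alpha) == pytest.approx(0.11)

    def test_unknown_condition_raises(self):
        with pytest.raises(KeyError):
            ModelParams.reference(2, 353)
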