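"""Detector tests: criteria examples, boundaries, oracle equivalence."""

import numpy as np
import pytest

from ifpkit.errors import ConfigurationError, GeometryError
from ifpkit.interactions import (Channel, InteractionSpec, detect_cation_pi,
                                 detect_hbond, detect_pi_pi, detect_salt_bridge,
                                 evaluate_channel)
from ifpkit.trajectory import Atom, Trajectory
from conftest import random_hexagon, random_rigid

import oracles

SPEC = InteractionSpec()


def hexagon(center=(0, 0, 0), radius=1.39, z=0.0):
    ang = np.arange(6) * np.pi / 3.0
    pts = np.stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(6)], axis=1)
    return pts + np.asarray(center, float) + np.array([0.0, 0.0, z])


def hbond_frame(da_dist, angle_deg, dh=1.0):
    """Exact D-H-A geometry: H at origin, given D-A distance and D-H-A angle."""
    h = np.zeros(3)
    d = np.array([dh, 0.0, 0.0])
    alpha = np.radians(angle_deg)
    # H-A length solving |D - A| = da_dist with the angle at H fixed
    r = dh * np.cos(alpha) + np.sqrt(da_dist ** 2 - dh ** 2 * np.sin(alpha) ** 2)
    a = r * np.array([np.cos(alpha), np.sin(alpha), 0.0])
    return np.stack([d, h, a])


class TestHbond:
    def test_inside_both_cutoffs(self):
        frame = hbond_frame(2.8, 160.0)
        assert detect_hbond(frame, 0, 1, 2, SPEC) is True

    def test_extended_cutoff_for_intramolecular(self):
        frame = hbond_frame(3.2, 170.0)
        assert detect_hbond(frame, 0, 1, 2, SPEC, intramolecular=False) is False
        assert detect_hbond(frame, 0, 1, 2, SPEC, intramolecular=True) is True

    def test_angle_below_threshold(self):
        frame = hbond_frame(2.8, 120.0)
        assert detect_hbond(frame, 0, 1, 2, SPEC) is False

    def test_constructed_angle_is_what_we_claim(self):
        d, h, a = hbond_frame(2.8, 147.0)
        v1, v2 = d - h, a - h
        ang = np.degrees(np.arccos(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))))
        assert ang == pytest.approx(147.0, abs=1e-9)
        assert np.linalg.norm(d - a) == pytest.approx(2.8, abs=1e-9)

    def test_far_hydrogen_warns(self):
        frame = hbond_frame(2.8, 160.0, dh=1.8)
        with pytest.warns(UserWarning, match="covalently"):
            detect_hbond(frame, 0, 1, 2, SPEC)

    def test_coincident_atoms_rejected(self):
        frame = np.zeros((3, 3))
        with pytest.raises(GeometryError):
            detect_hbond(frame, 0, 1, 2, SPEC)

    def test_distance_only_fallback_requires_flag(self):
        frame = hbond_frame(2.8, 160.0)
        with pytest.raises(ConfigurationError):
            detect_hbond(frame, 0, None, 2, SPEC)
        with pytest.warns(UserWarning, match="distance only"):
            assert detect_hbond(frame, 0, None, 2, SPEC, allow_no_hydrogen=True)


class TestSaltBridge:
    def test_single_pair(self):
        frame = np.array([[0, 0, 0], [3.9, 0, 0.0]])
        assert detect_salt_bridge(frame, [0], [1], SPEC) is True

    def test_min_rule_and_inclusive_boundary(self):
        frame = np.array([[0.0, 0, 0], [4.5, 0, 0], [0, 4.2, 0], [0, 0, 4.0]])
        assert detect_salt_bridge(frame, [0], [1, 2], SPEC) is False
        assert detect_salt_bridge(frame, [0], [1, 2, 3], SPEC) is True

    def test_two_by_two_matches_brute_force_min(self):
        # O1-N1 4.8, O1-N2 4.4, O2-N1 3.2, O2-N2 5.0
        o1, o2 = np.array([0.0, 0, 0]), np.array([6.0, 0, 0])
        n1 = np.array([4.0667, 2.5495, 0.0])
        n2 = np.array([2.53, 3.6, 0.0])
        frame = np.stack([o1, o2, n1, n2])
        dists = sorted(round(float(np.linalg.norm(frame[i] - frame[j])), 1)
                       for i in (0, 1) for j in (2, 3))
        assert dists == [3.2, 4.4, 4.8, 5.0]
        assert detect_salt_bridge(frame, [0, 1], [2, 3], SPEC) is \
            oracles.oracle_salt_bridge([o1, o2], [n1, n2]) is True

    def test_empty_set_rejected(self):
        with pytest.raises(ConfigurationError):
            detect_salt_bridge(np.zeros((2, 3)), [], [1], SPEC)


class TestCationPi:
    def test_on_axis(self):
        frame = np.vstack([hexagon(), [0.0, 0.0, 3.0]])
        assert detect_cation_pi(frame, 6, list(range(6)), SPEC) is True

    def test_in_plane_fails_on_angle(self):
        frame = np.vstack([hexagon(), [3.0, 0.0, 0.0]])
        assert detect_cation_pi(frame, 6, list(range(6)), SPEC) is False

    def test_45_degree_boundary_inclusive(self):
        frame = np.vstack([hexagon(), [3.0, 0.0, 3.0]])  # dist ~4.243, angle 45
        assert detect_cation_pi(frame, 6, list(range(6)), SPEC) is True

    def test_small_ring_rejected(self):
        with pytest.raises(GeometryError):
            detect_cation_pi(np.zeros((5, 3)), 4, [0, 1, 2, 3], SPEC)


class TestPiPi:
    def test_parallel_stack(self):
        frame = np.vstack([hexagon(), hexagon(z=3.8)])
        assert detect_pi_pi(frame, list(range(6)), list(range(6, 12)), SPEC) is True

    def test_perpendicular_rings(self):
        ring_b = hexagon()[:, [2, 1, 0]] + np.array([0.0, 0.0, 3.8])  # normal along x
        frame = np.vstack([hexagon(), ring_b])
        assert detect_pi_pi(frame, list(range(6)), list(range(6, 12)), SPEC) is False

    def test_offset_beyond_distance_cutoff(self):
        frame = np.vstack([hexagon(), hexagon(center=(6.0, 0, 0))])
        assert detect_pi_pi(frame, list(range(6)), list(range(6, 12)), SPEC) is False


class TestBoundaryDeterminism:
    """Exact-cutoff geometries are inclusive; 1e-6 beyond is exclusive."""

    EPS = 1e-6

    def test_hbond_distance_boundary(self):
        # collinear geometry so the D-A distance is exactly representable
        assert detect_hbond(hbond_frame(3.0, 180.0), 0, 1, 2, SPEC) is True
        assert detect_hbond(hbond_frame(3.0 + self.EPS, 180.0), 0, 1, 2, SPEC) is False

    def test_hbond_angle_boundary(self):
        assert detect_hbond(hbond_frame(2.8, 135.0), 0, 1, 2, SPEC) is True
        assert detect_hbond(hbond_frame(2.8, 135.0 - 1e-4), 0, 1, 2, SPEC) is False

    def test_intramolecular_distance_boundary(self):
        f_in = hbond_frame(3.5, 180.0)
        f_out = hbond_frame(3.5 + self.EPS, 180.0)
        assert detect_hbond(f_in, 0, 1, 2, SPEC, intramolecular=True) is True
        assert detect_hbond(f_out, 0, 1, 2, SPEC, intramolecular=True) is False

    def test_salt_bridge_boundary(self):
        f = lambda d: np.array([[0.0, 0, 0], [d, 0, 0]])
        assert detect_salt_bridge(f(4.0), [0], [1], SPEC) is True
        assert detect_salt_bridge(f(4.0 + self.EPS), [0], [1], SPEC) is False

    def test_cation_pi_distance_boundary(self):
        ring = list(range(6))
        f = lambda d: np.vstack([hexagon(), [0.0, 0.0, d]])
        assert detect_cation_pi(f(6.0), 6, ring, SPEC) is True
        assert detect_cation_pi(f(6.0 + self.EPS), 6, ring, SPEC) is False

    def test_cation_pi_angle_boundary(self):
        ring = list(range(6))
        on = np.vstack([hexagon(), [3.0, 0.0, 3.0]])          # exactly 45 deg
        off = np.vstack([hexagon(), [3.0, 0.0, 3.0 - 1e-5]])  # just past 45
        assert detect_cation_pi(on, 6, ring, SPEC) is True
        assert detect_cation_pi(off, 6, ring, SPEC) is False


def _random_hbond_case(rng):
    d = np.zeros(3)
    dist = rng.uniform(2.0, 4.0)
    ang = rng.uniform(100.0, 180.0)
    theta = np.radians(180.0 - ang)
    h = np.array([np.cos(theta), np.sin(theta), 0.0])
    a = np.array([dist, 0.0, 0.0])
    R, t = random_rigid(rng)
    pts = np.stack([d, h, a]) @ R.T + t
    return pts


class TestOracleEquivalence:
    """1,000 random geometries per detector match the independent oracle."""

    N = 1000

    def test_hbond_vs_oracle(self, rng):
        for intr in (False, True):
            for _ in range(self.N // 2):
                pts = _random_hbond_case(rng)
                assert detect_hbond(pts, 0, 1, 2, SPEC, intramolecular=intr) == \
                    oracles.oracle_hbond(pts[0], pts[1], pts[2], intramolecular=intr)

    def test_salt_bridge_vs_oracle(self, rng):
        for _ in range(self.N):
            O = rng.uniform(-3, 3, size=(2, 3))
            N = O.mean(axis=0) + rng.uniform(-5, 5, size=(2, 3))
            frame = np.vstack([O, N])
            assert detect_salt_bridge(frame, [0, 1], [2, 3], SPEC) == \
                oracles.oracle_salt_bridge(O.tolist(), N.tolist())

    def test_cation_pi_vs_oracle(self, rng):
        for _ in range(self.N):
            ring = random_hexagon(rng)
            cation = ring.mean(axis=0) + rng.uniform(-7, 7, size=3)
            frame = np.vstack([ring, cation])
            assert detect_cation_pi(frame, 6, list(range(6)), SPEC) == \
                oracles.oracle_cation_pi(cation.tolist(), ring.tolist())

    def test_pi_pi_vs_oracle(self, rng):
        for _ in range(self.N):
            a = random_hexagon(rng)
            b = random_hexagon(rng)
            b = b - b.mean(axis=0) + a.mean(axis=0) + rng.uniform(-6, 6, size=3)
            frame = np.vstack([a, b])
            assert detect_pi_pi(frame, list(range(6)), list(range(6, 12)), SPEC) == \
                oracles.oracle_pi_pi(a.tolist(), b.tolist())


class TestMonotonicity:
    """With angles fixed, larger separation can only switch true -> false."""

    def test_hbond_distance_monotone(self):
        prev = True
        for dist in np.linspace(2.0, 4.0, 60):
            cur = detect_hbond(hbond_frame(dist, 170.0), 0, 1, 2, SPEC)
            assert not (cur and not prev)
            prev = cur

    def test_cation_pi_distance_monotone(self):
        prev = True
        for d in np.linspace(2.0, 8.0, 60):
            frame = np.vstack([hexagon(), [0.0, 0.0, d]])
            cur = detect_cation_pi(frame, 6, list(range(6)), SPEC)
            assert not (cur and not prev)
            prev = cur


def _mini_traj(frames):
    atoms = [Atom(i + 1, n, e, rn, 1, c) for i, (n, e, rn, c) in enumerate(
        [("OD1", "O", "ASP", "A"), ("N1", "N", "LIG", "L")])]
    return Trajectory(atoms=atoms, coords=np.asarray(frames, dtype=float))


class TestEvaluateChannel:
    def test_alternating_fixture(self):
        frames = [[[0, 0, 0], [0, 0, 3.0]],
                  [[0, 0, 0], [0, 0, 5.0]],
                  [[0, 0, 0], [0, 0, 3.9]],
                  [[0, 0, 0], [0, 0, 4.6]]]
        ch = Channel(kind="salt_bridge", label="sb",
                     participants={"anion_oxygens": [0], "cation_nitrogens": [1]})
        out = evaluate_channel(_mini_traj(frames), ch, SPEC)
        assert out.tolist() == [True, False, True, False]

    def test_single_frame_series(self):
        ch = Channel(kind="salt_bridge", label="sb",
                     participants={"anion_oxygens": [0], "cation_nitrogens": [1]})
        out = evaluate_channel(_mini_traj([[[0, 0, 0], [0, 0, 3.0]]]), ch, SPEC)
        assert out.shape == (1,) and out[0]

    def test_fused_ring_or_rule(self):
        # tryptophan-like: 5-ring and 6-ring declared for one channel;
        # the cation sits over the 6-ring only
        six = hexagon(center=(0, 0, 0))
        ang5 = 2 * np.pi * np.arange(5) / 5
        five = np.stack([1.2 * np.cos(ang5) + 10.0, 1.2 * np.sin(ang5),
                         np.zeros(5)], axis=1)
        cation = np.array([0.0, 0.0, 3.0])
        frame = np.vstack([six, five, cation])
        atoms = [Atom(i + 1, f"C{i}", "C", "TRP", 151, "A") for i in range(11)]
        atoms.append(Atom(12, "NP", "N", "LIG", 1, "L"))
        traj = Trajectory(atoms=atoms, coords=frame[None])
        ch = Channel(kind="cation_pi", label="cp",
                     participants={"cation": [11],
                                   "ring": [list(range(6)), list(range(6, 11))]})
        assert evaluate_channel(traj, ch, SPEC).tolist() == [True]
        # and neither ring alone over-counts: the 5-ring fails on distance
        assert not detect_cation_pi(frame, 11, list(range(6, 11)), SPEC)

    def test_error_carries_frame_index(self):
        frames = [[[0, 0, 0], [0, 0, 3.0]], [[0, 0, 0], [0, 0, 0]]]
        atoms = [Atom(1, "ND", "N", "LIG", 1, "L"), Atom(2, "OM", "O", "LIG", 1, "L")]
        traj = Trajectory(atoms=atoms, coords=np.asarray(frames, float))
        ch = Channel(kind="hbond", label="hb",
                     participants={"donor": [0], "hydrogen": [1], "acceptor": [1]})
        with pytest.raises(GeometryError, match="frame"):
            evaluate_channel(traj, ch, SPEC)


class TestChannelValidation:
    def test_missing_role_rejected(self):
        with pytest.raises(ConfigurationError, match="missing roles"):
            Channel(kind="salt_bridge", label="x",
                    participants={"anion_oxygens": [0]})

    def test_small_ring_rejected(self):
        with pytest.raises(ConfigurationError, match="ring"):
            Channel(kind="cation_pi", label="x",
                    participants={"cation": [0], "ring": [[1, 2, 3]]})

    def test_spec_validation(self):
        with pytest.raises(ConfigurationError):
            InteractionSpec(salt_bridge_cutoff=-1.0)
        with pytest.raises(ConfigurationError):
            InteractionSpec(cation_pi_angle_cutoff=120.0)
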