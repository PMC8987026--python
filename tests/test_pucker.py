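"""Cremer–Pople coordinates, conformer labels, and path tracking."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import rincluster as rc
from rincluster.pucker import (CANONICAL_CONFORMERS, angular_distance,
                               classify_conformer, cremer_pople, ideal_ring,
                               pucker_state, track_path, PuckerState)


def _hexagon(radius=1.5):
    j = np.arange(6)
    return np.column_stack([radius * np.cos(2 * np.pi * j / 6),
                            -radius * np.sin(2 * np.pi * j / 6),
                            np.zeros(6)])


def _rigid(coords, rng):
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = rng.uniform(0, 2 * np.pi)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + math.sin(ang) * K + (1 - math.cos(ang)) * K @ K
    return coords @ R.T + rng.normal(size=3) * 5.0


def cp_oracle(coords):
    """Loop-level evaluation of the published puckering definitions."""
    center = [sum(c[k] for c in coords) / 6.0 for k in range(3)]
    rc_ = [[c[k] - center[k] for k in range(3)] for c in coords]
    rp = [sum(rc_[j][k] * math.sin(2 * math.pi * j / 6) for j in range(6))
          for k in range(3)]
    rpp = [sum(rc_[j][k] * math.cos(2 * math.pi * j / 6) for j in range(6))
           for k in range(3)]
    n = [rp[1] * rpp[2] - rp[2] * rpp[1],
         rp[2] * rpp[0] - rp[0] * rpp[2],
         rp[0] * rpp[1] - rp[1] * rpp[0]]
    norm = math.sqrt(sum(x * x for x in n))
    n = [x / norm for x in n]
    z = [sum(rc_[j][k] * n[k] for k in range(3)) for j in range(6)]
    a = math.sqrt(1 / 3) * sum(z[j] * math.cos(4 * math.pi * j / 6) for j in range(6))
    b = -math.sqrt(1 / 3) * sum(z[j] * math.sin(4 * math.pi * j / 6) for j in range(6))
    q2 = math.hypot(a, b)
    q3 = math.sqrt(1 / 6) * sum((-1) ** j * z[j] for j in range(6))
    return (math.hypot(q2, q3),
            math.degrees(math.atan2(q2, q3)),
            math.degrees(math.atan2(b, a)) % 360.0)


def test_planar_hexagon_has_zero_amplitude():
    s = cremer_pople(_hexagon())
    assert s.Q < 1e-8
    assert classify_conformer(s).label == "planar"


def test_ideal_chair_amplitude_and_polar_angle():
    ring = _hexagon()
    ring[:, 2] = [0.25, -0.25, 0.25, -0.25, 0.25, -0.25]  # even-index atoms up
    s = cremer_pople(ring)
    assert s.Q == pytest.approx(math.sqrt(6) * 0.25, abs=1e-12)
    assert s.theta == pytest.approx(0.0, abs=1e-9)
    assert classify_conformer(s).label == "4C1"
    ring[:, 2] *= -1
    s_inv = cremer_pople(ring)
    assert s_inv.theta == pytest.approx(180.0, abs=1e-9)
    assert classify_conformer(s_inv).label == "1C4"


def test_rigid_motion_invariance():
    rng = np.random.default_rng(11)
    for _ in range(10):
        ring = ideal_ring(rng.uniform(10, 170), rng.uniform(0, 360), Q=0.5)
        ring += rng.normal(0, 0.03, ring.shape)
        s0 = cremer_pople(ring)
        s1 = cremer_pople(_rigid(ring, rng))
        assert s1.Q == pytest.approx(s0.Q, abs=1e-9)
        assert s1.theta == pytest.approx(s0.theta, abs=1e-9)
        assert abs((s1.phi - s0.phi + 180) % 360 - 180) < 1e-9


def test_agrees_with_brute_force_oracle_on_random_puckers():
    rng = np.random.default_rng(23)
    for _ in range(100):
        ring = _hexagon()
        ring[:, 2] = rng.normal(0, 0.2, 6)
        ring = _rigid(ring, rng)
        s = cremer_pople(ring)
        Q, theta, phi = cp_oracle([list(map(float, row)) for row in ring])
        assert s.Q == pytest.approx(Q, abs=1e-9)
        assert s.theta == pytest.approx(theta, abs=1e-9)
        assert abs((s.phi - phi + 180) % 360 - 180) < 1e-9


def test_cyclic_reindex_and_inversion_transformations():
    """Re-indexing by one: (θ,φ)→(180−θ, φ+120°); inversion: (180−θ, φ+180°);
    their composition fixes θ and shifts φ by 60° (mod 360)."""
    rng = np.random.default_rng(5)
    for _ in range(20):
        ring = ideal_ring(rng.uniform(15, 165), rng.uniform(0, 360), Q=0.5)
        s = cremer_pople(ring)
        rolled = cremer_pople(np.roll(ring, -1, axis=0))
        assert rolled.theta == pytest.approx(180.0 - s.theta, abs=1e-9)
        assert abs((rolled.phi - (s.phi + 120.0) + 180) % 360 - 180) < 1e-9
        inverted = ring.copy()
        inverted[:, 2] *= -1
        si = cremer_pople(inverted)
        assert si.theta == pytest.approx(180.0 - s.theta, abs=1e-9)
        assert abs((si.phi - (s.phi + 180.0) + 180) % 360 - 180) < 1e-9
        both = np.roll(inverted, -1, axis=0)
        sb = cremer_pople(both)
        assert sb.theta == pytest.approx(s.theta, abs=1e-9)
        assert abs((sb.phi - (s.phi - 60.0) + 180) % 360 - 180) < 1e-9


def test_open_ring_rejected():
    ring = _hexagon()
    ring[3] += [5.0, 0, 0]
    with pytest.raises(ValueError, match="open"):
        cremer_pople(ring)


def test_canonical_table_has_38_conformers():
    assert len(CANONICAL_CONFORMERS) == 38
    letters = {}
    for name in CANONICAL_CONFORMERS:
        core = [c for c in name if c in "CBSEH"]
        letters[core[0]] = letters.get(core[0], 0) + 1
    assert letters == {"C": 2, "B": 6, "S": 6, "E": 12, "H": 12}


@pytest.mark.parametrize("label", sorted(CANONICAL_CONFORMERS))
def test_constructed_vertex_geometry_recovers_its_label(label):
    theta, phi = CANONICAL_CONFORMERS[label]
    s = pucker_state(ideal_ring(theta, phi, Q=0.5))
    assert s.label == label
    assert s.label_distance == pytest.approx(0.0, abs=1e-6)


def test_boat_label_stable_under_small_phi_perturbation():
    theta, phi = CANONICAL_CONFORMERS["B2,5"]
    assert pucker_state(ideal_ring(theta, phi + 1.0, Q=0.5)).label == "B2,5"


@given(st.floats(0.12, 0.7))
def test_label_is_scale_invariant_in_Q(q):
    s = pucker_state(ideal_ring(54.74, 240.0, Q=q))
    assert s.label == "4E"


def test_small_amplitude_is_planar():
    s = classify_conformer(PuckerState(Q=0.05, theta=90.0, phi=0.0))
    assert s.label == "planar"


class TestTrackPath:
    def _frames(self):
        return [ideal_ring(*CANONICAL_CONFORMERS["4C1"], Q=0.55),
                ideal_ring(*CANONICAL_CONFORMERS["4H3"], Q=0.5),
                ideal_ring(*CANONICAL_CONFORMERS["4E"], Q=0.5)]

    def test_chair_halfchair_envelope_sequence(self):
        states = track_path(self._frames(), list(range(6)))
        assert [s.label for s in states] == ["4C1", "4H3", "4E"]

    def test_single_frame(self):
        states = track_path(self._frames()[:1], list(range(6)))
        assert len(states) == 1 and states[0].label == "4C1"

    def test_reversed_order_reverses_labels(self):
        fwd = [s.label for s in track_path(self._frames(), list(range(6)))]
        rev = [s.label for s in track_path(self._frames()[::-1], list(range(6)))]
        assert rev == fwd[::-1]

    def test_frame_size_mismatch_rejected(self):
        frames = self._frames()
        frames[1] = np.vstack([frames[1], [0.0, 0.0, 9.0]])
        with pytest.raises(ValueError, match="atoms"):
            track_path(frames, list(range(6)))


def test_angular_distance_degenerate_at_poles():
    assert angular_distance(0.0, 10.0, 0.0, 250.0) == pytest.approx(0.0, abs=1e-9)
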