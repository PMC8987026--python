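"""Cremer–Pople puckering coordinates and IUPAC conformer labels.

For a six-membered ring the out-of-plane displacements z_j from the
centroid-anchored mean plane decompose into one m=2 Fourier pair (q2, φ2)
and one alternating-sum amplitude (q3):

    q2 cos φ2 =  sqrt(1/3) Σ z_j cos(4πj/6)
    q2 sin φ2 = −sqrt(1/3) Σ z_j sin(4πj/6)
    q3        =  sqrt(1/6) Σ (−1)^j z_j
    Q = sqrt(q2² + q3²),  θ = atan2(q2, q3) ∈ [0°, 180°],  φ = φ2 ∈ [0°, 360°)

Ring atoms are indexed j = 0…5 in the fixed pyranose order
**O5, C1, C2, C3, C4, C5**; with this convention the ⁴C₁ chair sits at
θ ≈ 0° and ¹C₄ at θ ≈ 180°.  Labels flip if the ordering convention
changes, so the ordering is part of the contract.

The 38 canonical conformers (2 chairs C, 6 boats B, 6 twist-boats S,
12 half-chairs H, 12 envelopes E) are generated at import time from their
defining up/down displacement patterns and classified by nearest spherical
(θ, φ) distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .structure import Fragment

RING_ORDER = ("O5", "C1", "C2", "C3", "C4", "C5")
PLANARITY_THRESHOLD = 0.1  # Å on Q
_RING_CLOSURE = 1.8  # Å, max consecutive-atom distance

# position index (j) -> IUPAC locant used in conformer names
_LOCANT = ("O", "1", "2", "3", "4", "5")


@dataclass(frozen=True)
class RingSelection:
    """Six atom names (or indices) in the fixed order O5, C1 … C5."""

    atom_names: tuple = RING_ORDER
    fragment: str | None = None

    def __post_init__(self) -> None:
        if len(self.atom_names) != 6:
            raise ValueError("a pyranose ring selection needs exactly 6 atoms")


@dataclass(frozen=True)
class PuckerState:
    Q: float            # total puckering amplitude, Å
    theta: float        # polar angle, degrees in [0, 180]
    phi: float          # azimuthal angle, degrees in [0, 360)
    label: str | None = None
    label_distance: float | None = None  # angular distance to the vertex, degrees

    def __post_init__(self) -> None:
        if self.Q < 0:
            raise ValueError("Q must be non-negative")


def cremer_pople(coords: np.ndarray) -> PuckerState:
    """Puckering coordinates for six ring atoms ordered O5, C1 … C5.

    ``coords`` is a (6, 3) array.  Raises if the ring is open (consecutive
    atoms further apart than 1.8 Å) or coordinates are not finite.
    """
    r = np.asarray(coords, dtype=float)
    if r.shape != (6, 3):
        raise ValueError("expected a (6, 3) coordinate array")
    if not np.all(np.isfinite(r)):
        raise ValueError("ring coordinates must be finite")
    gaps = np.linalg.norm(r - np.roll(r, -1, axis=0), axis=1)
    if np.any(gaps > _RING_CLOSURE):
        j = int(np.argmax(gaps))
        raise ValueError(
            f"ring is open: atoms {j} and {(j + 1) % 6} are {gaps[j]:.2f} Å apart")

    center = r.mean(axis=0)
    rc = r - center
    j = np.arange(6)
    # mean plane from the two first-harmonic lattice vectors
    rp = (rc * np.sin(2 * np.pi * j / 6)[:, None]).sum(axis=0)
    rpp = (rc * np.cos(2 * np.pi * j / 6)[:, None]).sum(axis=0)
    n = np.cross(rp, rpp)
    n = n / np.linalg.norm(n)
    z = rc @ n

    q2, phi2 = _q2_phi2(z)
    q3 = math.sqrt(1.0 / 6.0) * float(((-1.0) ** j * z).sum())
    Q = math.hypot(q2, q3)
    theta = math.degrees(math.atan2(q2, q3))
    return PuckerState(Q=Q, theta=theta, phi=phi2)


def _q2_phi2(z: np.ndarray) -> tuple[float, float]:
    j = np.arange(6)
    a = math.sqrt(1.0 / 3.0) * float((z * np.cos(4 * np.pi * j / 6)).sum())
    b = -math.sqrt(1.0 / 3.0) * float((z * np.sin(4 * np.pi * j / 6)).sum())
    q2 = math.hypot(a, b)
    phi2 = math.degrees(math.atan2(b, a)) % 360.0
    return q2, phi2


# ---------------------------------------------------------------------------
# Canonical conformer table, generated from defining displacement patterns

def _project(z: np.ndarray) -> tuple[float, float]:
    """(θ, φ) of an abstract displacement pattern (amplitude-free)."""
    j = np.arange(6)
    z = z - z.mean()
    q2, phi2 = _q2_phi2(z)
    q3 = math.sqrt(1.0 / 6.0) * float(((-1.0) ** j * z).sum())
    theta = math.degrees(math.atan2(q2, q3))
    return theta, phi2


def _name(sup: list[int], sub: list[int], letter: str) -> str:
    up = ",".join(_LOCANT[k] for k in sorted(sup))
    dn = ",".join(_LOCANT[k] for k in sorted(sub))
    return f"{up}{letter}{dn}" if up or dn else letter


def _build_canonical() -> dict[str, tuple[float, float]]:
    table: dict[str, tuple[float, float]] = {}

    def add(letter: str, up: list[int], down: list[int]) -> None:
        z = np.zeros(6)
        z[up] += 1.0
        z[down] -= 1.0
        table[_name(up, down, letter)] = _project(z)

    # chairs: full alternation; ⁴C₁ has C4 (j=4) up and C1 (j=1) down
    add("C", [0, 2, 4], [1, 3, 5])   # 4C1 → named O,2,4C1,3,5 below; fixed after
    add("C", [1, 3, 5], [0, 2, 4])
    # boats: one para pair out of plane
    for a in range(3):
        add("B", [a, a + 3], [])
        add("B", [], [a, a + 3])
    # twist-boats (skew): the six canonical meta up/down pairs
    for up, down in [(0, 2), (1, 3), (1, 5), (2, 0), (3, 1), (5, 1)]:
        add("S", [up], [down])
    # envelopes: a single atom out of plane
    for a in range(6):
        add("E", [a], [])
        add("E", [], [a])
    # half-chairs: adjacent pair, one up one down, both orientations
    for a in range(6):
        add("H", [a], [(a + 1) % 6])
        add("H", [(a + 1) % 6], [a])
    return table


def _fix_chair_names(table: dict[str, tuple[float, float]]) -> dict[str, tuple[float, float]]:
    """Chairs are conventionally named by the atoms flanking the reference
    plane: the all-alternating patterns map to ⁴C₁ and ¹C₄."""
    out = {}
    for name, tp in table.items():
        if "C" in name and len(name) > 5:  # the raw alternation names
            out["4C1" if tp[0] < 90 else "1C4"] = tp
        else:
            out[name] = tp
    return out


CANONICAL_CONFORMERS: dict[str, tuple[float, float]] = _fix_chair_names(_build_canonical())


def angular_distance(t1: float, p1: float, t2: float, p2: float) -> float:
    """Great-circle distance on the puckering sphere, degrees."""
    t1, p1, t2, p2 = map(math.radians, (t1, p1, t2, p2))
    c = (math.cos(t1) * math.cos(t2)
         + math.sin(t1) * math.sin(t2) * math.cos(p1 - p2))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def classify_conformer(state: PuckerState,
                       planarity_threshold: float = PLANARITY_THRESHOLD) -> PuckerState:
    """Attach the nearest canonical IUPAC conformer label.

    Rings with Q below the planarity threshold are labeled "planar".
    The angular distance to the winning vertex is recorded so near-ties
    (e.g. ⁴E vs ⁴H₃) are visible to the caller.
    """
    if state.Q < planarity_threshold:
        return replace(state, label="planar", label_distance=None)
    best_label, best_d = None, None
    for label in sorted(CANONICAL_CONFORMERS):
        t, p = CANONICAL_CONFORMERS[label]
        d = angular_distance(state.theta, state.phi, t, p)
        if best_d is None or d < best_d - 1e-12:
            best_label, best_d = label, d
    return replace(state, label=best_label, label_distance=best_d)


# ---------------------------------------------------------------------------
# Convenience entry points

def ring_coords(fragment: Fragment, ring: RingSelection | None = None) -> np.ndarray:
    ring = ring or RingSelection()
    return np.array([fragment.atom(n).coords for n in ring.atom_names])


def pucker_state(coords: np.ndarray) -> PuckerState:
    return classify_conformer(cremer_pople(coords))


def track_path(frames: list[np.ndarray], indices: list[int]) -> list[PuckerState]:
    """Labeled pucker states along an ordered series of geometries.

    ``frames`` are (n_atoms, 3) arrays sharing one atom order; ``indices``
    are the six ring-atom indices in O5, C1 … C5 order.
    """
    if len(indices) != 6:
        raise ValueError("need 6 ring atom indices")
    n_atoms = None
    out = []
    for i, frame in enumerate(frames):
        arr = np.asarray(frame, float)
        if n_atoms is None:
            n_atoms = arr.shape[0]
        elif arr.shape[0] != n_atoms:
            raise ValueError(f"frame {i} has {arr.shape[0]} atoms, expected {n_atoms}")
        out.append(pucker_state(arr[list(indices)]))
    return out


def ideal_ring(theta: float, phi: float, Q: float = 0.55,
               bond: float = 1.5) -> np.ndarray:
    """Construct ring coordinates with prescribed (Q, θ, φ).

    A regular hexagon in the xy-plane is displaced along z by the CP basis
    functions; used for fixtures and canonical-vertex cross-checks.
    """
    th, ph = math.radians(theta), math.radians(phi)
    j = np.arange(6)
    q2, q3 = Q * math.sin(th), Q * math.cos(th)
    z = (math.sqrt(1.0 / 3.0) * q2 * np.cos(ph + 4 * np.pi * j / 6)
         + math.sqrt(1.0 / 6.0) * q3 * (-1.0) ** j)
    # clockwise in xy so the Cremer–Pople mean-plane normal points +z,
    # making the prescribed z-pattern the positive puckering side
    radius = bond
    ring = np.column_stack([radius * np.cos(2 * np.pi * j / 6),
                            -radius * np.sin(2 * np.pi * j / 6), z])
    return ring
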