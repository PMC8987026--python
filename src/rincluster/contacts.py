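"""Small-probe-style contact dots and residue interaction networks.

The interaction statistic is a deterministic surrogate for Richardson-style
contact-dot counting: each atom's van der Waals sphere is covered with a
Fibonacci lattice at a fixed dot density, dots buried inside neighboring
spheres are removed, and a dot counts as a contact when the gap between it
and the nearest partner-atom surface is at most ``max_gap``.  Counts are
symmetrized over the two fragments.

The lattice is anchored in a per-atom local frame built from the atom's two
nearest neighbors, so counts are exactly invariant under rigid motion of
the structure (isolated atoms fall back to the global axes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .structure import Atom, FragKey, Fragment, Structure, parse_key

_GOLDEN = math.pi * (3.0 - math.sqrt(5.0))


@dataclass(frozen=True)
class ContactParams:
    """Dot density (Å⁻²), probe radius (Å) and surface-gap cutoff (Å).

    Defaults: 16 dots/Å², probe 0.25 Å, max_gap = 2 × probe = 0.5 Å.
    """

    dot_density: float = 16.0
    probe_radius: float = 0.25
    max_gap: float = 0.5

    def __post_init__(self) -> None:
        if self.dot_density < 0 or self.probe_radius <= 0 or self.max_gap <= 0:
            raise ValueError("contact parameters must be positive")


@dataclass(frozen=True)
class ContactEdge:
    frag_a: FragKey
    frag_b: FragKey
    dot_count: int

    def __post_init__(self) -> None:
        if self.frag_a == self.frag_b:
            raise ValueError("self-edges are not allowed")
        if self.dot_count < 0:
            raise ValueError("dot_count must be non-negative")


@dataclass
class RIN:
    """Weighted fragment-contact graph with a distinguished seed set."""

    nodes: list[FragKey]
    edges: list[ContactEdge]
    seed: set[FragKey]

    def __post_init__(self) -> None:
        if not self.seed <= set(self.nodes):
            raise ValueError("seed must be a subset of nodes")

    def seed_contact(self, key: FragKey) -> int:
        """Total dot count between ``key`` and all seed fragments."""
        total = 0
        for e in self.edges:
            if e.frag_a == key and e.frag_b in self.seed:
                total += e.dot_count
            elif e.frag_b == key and e.frag_a in self.seed:
                total += e.dot_count
        return total

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.frag_a, e.frag_b, dot_count=e.dot_count)
        for n in self.seed:
            g.nodes[n]["seed"] = True
        return g


@dataclass
class Selection:
    chosen: list[FragKey]
    mode: str  # threshold | maximal
    threshold_value: int | None = None
    bridging: list[FragKey] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode == "threshold" and self.threshold_value is None:
            raise ValueError("threshold mode requires threshold_value")
        if set(self.chosen) & set(self.bridging):
            raise ValueError("chosen and bridging overlap")


# ---------------------------------------------------------------------------
# Dot generation

def _fibonacci_directions(n: int) -> np.ndarray:
    """n near-uniform unit vectors on the sphere (deterministic)."""
    if n <= 0:
        return np.zeros((0, 3))
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = _GOLDEN * i
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _local_frame(atom: Atom, others: list[Atom]) -> np.ndarray:
    """Rotation matrix whose columns are the atom's local axes.

    Built from the directions to the two nearest neighbors (rotation-
    equivariant); falls back to the identity for isolated/collinear cases.
    """
    c = atom.coords
    # distances rounded so the neighbor ordering is stable under the
    # floating-point noise of rigid motions; serials break exact ties
    cands = sorted(
        (o for o in others if o is not atom),
        key=lambda o: (round(float(np.linalg.norm(o.coords - c)), 6), o.serial),
    )
    if not cands:
        return np.eye(3)
    z = cands[0].coords - c
    nz = np.linalg.norm(z)
    if nz < 1e-8:  # coincident neighbor: fall back to global axes
        return np.eye(3)
    z = z / nz
    x = None
    for o in cands[1:]:
        v = o.coords - c
        v = v - np.dot(v, z) * z
        nv = np.linalg.norm(v)
        if nv > 1e-6:
            x = v / nv
            break
    if x is None:
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(z, ref)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        x = np.cross(z, ref)
        x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def generate_surface_dots(atom: Atom, neighbors: list[Atom],
                          params: ContactParams,
                          frame_atoms: list[Atom] | None = None) -> np.ndarray:
    """Surviving vdW-surface dots for one atom.

    Dots lie exactly on the atom's vdW sphere; dots strictly inside any
    neighbor's vdW sphere are removed.  ``frame_atoms`` (default: the
    neighbors) anchor the lattice orientation.
    """
    r = atom.vdw_radius
    n = int(round(4.0 * math.pi * r * r * params.dot_density))
    dirs = _fibonacci_directions(n)
    frame = _local_frame(atom, frame_atoms if frame_atoms is not None else neighbors)
    dots = atom.coords + r * (dirs @ frame.T)
    keep = np.ones(len(dots), dtype=bool)
    for nb in neighbors:
        if nb is atom:
            continue
        d = np.linalg.norm(dots - nb.coords, axis=1)
        keep &= d > nb.vdw_radius + 1e-9  # buried when on or inside the sphere
    return dots[keep]


def _directed_count(frag_a: Fragment, frag_b: Fragment, params: ContactParams) -> int:
    occluders = frag_a.atoms + frag_b.atoms
    b_coords = np.array([a.coords for a in frag_b.atoms])
    b_radii = np.array([a.vdw_radius for a in frag_b.atoms])
    total = 0
    for atom in frag_a.atoms:
        dots = generate_surface_dots(atom, occluders, params, frame_atoms=frag_a.atoms)
        if len(dots) == 0:
            continue
        gaps = np.linalg.norm(dots[:, None, :] - b_coords[None, :, :], axis=2) - b_radii
        total += int(np.sum(gaps.min(axis=1) <= params.max_gap))
    return total


def count_contacts(structure: Structure, frag_a: FragKey | str,
                   frag_b: FragKey | str, params: ContactParams | None = None) -> int:
    """Symmetrized contact-dot count between two fragments."""
    params = params or ContactParams()
    fa = structure.fragment(frag_a)
    fb = structure.fragment(frag_b)
    return _directed_count(fa, fb, params) + _directed_count(fb, fa, params)


# ---------------------------------------------------------------------------
# Network construction and selection

def build_rin(structure: Structure, seed: set[FragKey | str],
              params: ContactParams | None = None) -> RIN:
    """RIN around a seed: every fragment with nonzero seed contact.

    Seed-seed contacts are recorded as edges but never enter selection
    ranking (which uses only seed↔non-seed counts).
    """
    if not seed:
        raise ValueError("seed must not be empty")
    params = params or ContactParams()
    seed_keys = {parse_key(k) for k in seed}
    for k in seed_keys:
        structure.fragment(k)  # raises on unknown key
    edges: list[ContactEdge] = []
    nodes: set[FragKey] = set(seed_keys)
    others = [f.key for f in structure.fragments if f.key not in seed_keys]
    for key in others:
        for s in sorted(seed_keys):
            c = count_contacts(structure, key, s, params)
            if c > 0:
                edges.append(ContactEdge(frag_a=s, frag_b=key, dot_count=c))
                nodes.add(key)
    seed_sorted = sorted(seed_keys)
    for i, sa in enumerate(seed_sorted):
        for sb in seed_sorted[i + 1:]:
            c = count_contacts(structure, sa, sb, params)
            if c > 0:
                edges.append(ContactEdge(frag_a=sa, frag_b=sb, dot_count=c))
    ordered = [f.key for f in structure.fragments if f.key in nodes]
    return RIN(nodes=ordered, edges=edges, seed=seed_keys)


def select_residues(rin: RIN, mode: str = "threshold",
                    threshold: int | None = 50) -> Selection:
    """Rank non-seed fragments by total seed contact and keep the top set.

    ``threshold`` mode keeps counts strictly greater than the threshold;
    ``maximal`` keeps every nonzero count.  Ordering is by descending count
    with ties broken by ascending residue number.
    """
    if mode not in ("threshold", "maximal"):
        raise ValueError(f"unknown selection mode {mode!r}")
    if mode == "threshold":
        if threshold is None or threshold < 0:
            raise ValueError("threshold must be a non-negative integer")
    candidates = [k for k in rin.nodes if k not in rin.seed]
    counts = {k: rin.seed_contact(k) for k in candidates}
    if mode == "maximal":
        kept = [k for k in candidates if counts[k] > 0]
    else:
        kept = [k for k in candidates if counts[k] > threshold]
    kept.sort(key=lambda k: (-counts[k], k[1]))
    return Selection(chosen=kept, mode=mode,
                     threshold_value=None if mode == "maximal" else int(threshold))


def add_bridging_residues(selection: Selection, structure: Structure) -> Selection:
    """Bridge single-residue gaps between chosen residues along each chain.

    For every pair of chosen amino acids at positions i and i+2 on the same
    chain, the intervening residue i+1 (if present and not already chosen)
    is added to the bridging set, keeping the peptide chain covalently
    connected in the assembled model.
    """
    chosen = set(selection.chosen)
    aa_keys = {f.key for f in structure.fragments if f.kind == "amino_acid"}
    bridging: list[FragKey] = list(selection.bridging)
    for chain, resnum in sorted(chosen & aa_keys):
        upper = (chain, resnum + 2)
        middle = (chain, resnum + 1)
        if upper in chosen and middle in aa_keys and middle not in chosen \
                and middle not in bridging:
            bridging.append(middle)
    return Selection(chosen=list(selection.chosen), mode=selection.mode,
                     threshold_value=selection.threshold_value, bridging=bridging)
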