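"""Synthetic, download-free test inputs.

Three families of fixtures:

* miniature active sites — a glucosyl ligand (single ring or β-1,4 chain)
  surrounded by shell residues built from idealized internal-coordinate
  templates at controlled distances, written as PDB text;
* the six packaged trimming schemes transcribing the study's model table
  (per-residue retain/freeze/charge rows, including italic bridging rows);
* a packaged energy ledger encoding the printed relative free energies of
  the wild-type (E) and E217Q-mutant (Q) models as absolute pseudo-Hartree
  values plus an isolated-water reference, so diagram assembly exercises
  unit conversion and composition balancing.

Fixture geometries are idealized constructions, not copies of deposited
coordinates; they emulate contact ranking, trimming, capping and charge
bookkeeping, not real active-site geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .cluster import TrimScheme
from .energetics import EnergyLedger
from .qmio import read_energy_ledger
from .structure import (Atom, Fragment, GlycosidicLink, Structure,
                        perceive_links, write_pdb)

_CLASH_LIMIT = 2.0  # Å, minimum allowed inter-fragment heavy-atom distance


# ---------------------------------------------------------------------------
# Internal-coordinate (Z-matrix style) construction

def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           r: float, theta_deg: float, phi_deg: float) -> np.ndarray:
    """NeRF placement: new atom at distance r from c, angle θ (new-c-b),
    dihedral φ (new-c-b-a)."""
    theta, phi = math.radians(theta_deg), math.radians(phi_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-r * math.cos(theta),
                  r * math.sin(theta) * math.cos(phi),
                  r * math.sin(theta) * math.sin(phi)])
    return c + d[0] * bc + d[1] * m + d[2] * n


# side-chain Z-matrices: atom -> (ref1, ref2, ref3, r, angle, dihedral)
_Z = {
    "ALA": [("CB", "CA", "N", "C", 1.53, 110.5, 122.5)],
    "SER": [("CB", "CA", "N", "C", 1.53, 110.5, 122.5),
            ("OG", "CB", "CA", "N", 1.42, 110.5, 180.0)],
    "THR": [("CB", "CA", "N", "C", 1.53, 110.5, 122.5),
            ("OG1", "CB", "CA", "N", 1.42, 109.5, 180.0),
            ("CG2", "CB", "CA", "N", 1.52, 110.5, 60.0)],
    "LEU": [("CB", "CA", "N", "C", 1.53, 110.5, 122.5),
            ("CG", "CB", "CA", "N", 1.53, 112.0, 60.0),
            ("CD1", "CG", "CB", "CA", 1.53, 110.0, 60.0),
            ("CD2", "CG", "CB", "CA", 1.53, 110.0, 300.0)],
    "ASP": [("CB", "CA", "N", "C", 1.53, 110.5, 122.5),
            ("CG", "CB", "CA", "N", 1.52, 112.0, 180.0),
            ("OD1", "CG", "CB", "CA", 1.25, 118.5, 0.0),
            ("OD2", "CG", "CB", "CA", 1.25, 118.5, 180.0)],
    "GLU": [("CB", "CA", "N", "C", 1.53, 110.5, 122.5),
            ("CG", "CB", "CA", "N", 1.52, 112.0, 180.0),
            ("CD", "CG", "CB", "CA", 1.52, 112.0, 180.0),
            ("OE1", "CD", "CG", "CB", 1.25, 118.5, 0.0),
            ("OE2", "CD", "CG", "CB", 1.25, 118.5, 180.0)],
    "GLN": [("CB", "CA", "N", "C", 1.53, 110.5, 122.5),
            ("CG", "CB", "CA", "N", 1.52, 112.0, 180.0),
            ("CD", "CG", "CB", "CA", 1.52, 112.0, 180.0),
            ("OE1", "CD", "CG", "CB", 1.23, 121.0, 0.0),
            ("NE2", "CD", "CG", "CB", 1.33, 117.0, 180.0)],
    "ARG": [("CB", "CA", "N", "C", 1.53, 110.5, 122.5),
            ("CG", "CB", "CA", "N", 1.52, 112.0, 180.0),
            ("CD", "CG", "CB", "CA", 1.52, 112.0, 180.0),
            ("NE", "CD", "CG", "CB", 1.46, 112.0, 180.0),
            ("CZ", "NE", "CD", "CG", 1.33, 124.0, 180.0),
            ("NH1", "CZ", "NE", "CD", 1.33, 120.0, 0.0),
            ("NH2", "CZ", "NE", "CD", 1.33, 120.0, 180.0)],
    "HIS": [("CB", "CA", "N", "C", 1.53, 110.5, 122.5),
            ("CG", "CB", "CA", "N", 1.50, 113.0, 180.0),
            ("ND1", "CG", "CB", "CA", 1.38, 122.0, 90.0),
            ("CD2", "CG", "CB", "CA", 1.36, 131.0, 270.0),
            ("CE1", "ND1", "CG", "CB", 1.32, 108.0, 180.0),
            ("NE2", "CD2", "CG", "CB", 1.37, 107.0, 180.0)],
    "GLY": [],
}

FIXTURE_RESIDUES = tuple(sorted(_Z))


def build_residue(restype: str, chain: str = "A", resnum: int = 1,
                  c_terminal: bool = True) -> Fragment:
    """One free-standing residue from its idealized template (heavy atoms).

    ``c_terminal`` adds OXT so the carboxyl terminus is chemically complete
    as a neutral acid after hydrogen addition.
    """
    res = restype.upper()
    if res not in _Z:
        raise ValueError(f"no fixture template for residue {res}; "
                         f"available: {', '.join(FIXTURE_RESIDUES)}")
    coords: dict[str, np.ndarray] = {}
    coords["N"] = np.array([0.0, 0.0, 0.0])
    coords["CA"] = np.array([1.458, 0.0, 0.0])
    ang = math.radians(180.0 - 111.2)
    coords["C"] = coords["CA"] + 1.525 * np.array([math.cos(ang), math.sin(ang), 0.0])
    coords["O"] = _place(coords["N"], coords["CA"], coords["C"], 1.231, 120.5, -45.0)
    if c_terminal:
        coords["OXT"] = _place(coords["N"], coords["CA"], coords["C"], 1.34, 117.0, 135.0)
    for name, r1, r2, r3, r, th, ph in _Z[res]:
        coords[name] = _place(coords[r3], coords[r2], coords[r1], r, th, ph)
    atoms = [Atom(serial=i + 1, name=n, element=n[0], coords=c)
             for i, (n, c) in enumerate(coords.items())]
    return Fragment(chain=chain, resnum=resnum, resname=res,
                    kind="amino_acid", atoms=atoms)


def build_peptide(sequence: list[str], chain: str = "A",
                  first_resnum: int = 1) -> Structure:
    """Extended-conformation peptide with ideal backbone geometry."""
    fragments: list[Fragment] = []
    prev: dict[str, np.ndarray] | None = None
    serial = 0
    for i, restype in enumerate(sequence):
        res = restype.upper()
        if res not in _Z:
            raise ValueError(f"no fixture template for residue {res}")
        coords: dict[str, np.ndarray] = {}
        if prev is None:
            coords["N"] = np.array([0.0, 0.0, 0.0])
            coords["CA"] = np.array([1.458, 0.0, 0.0])
            ang = math.radians(180.0 - 111.2)
            coords["C"] = coords["CA"] + 1.525 * np.array([math.cos(ang), math.sin(ang), 0.0])
        else:
            coords["N"] = _place(prev["N"], prev["CA"], prev["C"], 1.329, 116.2, 135.0)
            coords["CA"] = _place(prev["CA"], prev["C"], coords["N"], 1.458, 121.7, 180.0)
            coords["C"] = _place(prev["C"], coords["N"], coords["CA"], 1.525, 111.2, -139.0)
        coords["O"] = _place(coords["N"], coords["CA"], coords["C"], 1.231, 120.5, -45.0)
        if i == len(sequence) - 1:
            coords["OXT"] = _place(coords["N"], coords["CA"], coords["C"], 1.34, 117.0, 135.0)
        for name, r1, r2, r3, r, th, ph in _Z[res]:
            coords[name] = _place(coords[r3], coords[r2], coords[r1], r, th, ph)
        atoms = []
        for n, c in coords.items():
            serial += 1
            atoms.append(Atom(serial=serial, name=n, element=n[0], coords=c))
        fragments.append(Fragment(chain=chain, resnum=first_resnum + i,
                                  resname=res, kind="amino_acid", atoms=atoms))
        prev = coords
    st = Structure(fragments=fragments)
    perceive_links(st)
    return st


# ---------------------------------------------------------------------------
# Glycan chains

_RING_BOND = 1.52
_GLYCOSIDIC = 1.43
# hexagon angle (degrees) for each ring atom, C1 toward +x, C4 toward −x
_RING_ANGLES = {"C1": 0.0, "C2": 60.0, "C3": 120.0, "C4": 180.0,
                "C5": 240.0, "O5": 300.0}
# alternating chair displacement (⁴C₁-like): ring-order-even atoms up
_RING_Z = {"O5": 0.25, "C1": -0.25, "C2": 0.25, "C3": -0.25,
           "C4": 0.25, "C5": -0.25}


def _glucosyl_unit(chain: str, resnum: int, x_offset: float) -> Fragment:
    atoms = []
    serial = 0
    for name in ("O5", "C1", "C2", "C3", "C4", "C5"):
        a = math.radians(_RING_ANGLES[name])
        serial += 1
        atoms.append(Atom(serial=serial, name=name, element=name[0],
                          coords=np.array([x_offset + _RING_BOND * math.cos(a),
                                           _RING_BOND * math.sin(a),
                                           _RING_Z[name]])))
    c4 = atoms[4].coords
    serial += 1
    # O4 sits at the z-level of the neighboring unit's C1 so the glycosidic
    # C1-O4 bond is exactly _GLYCOSIDIC long and axis-aligned
    atoms.append(Atom(serial=serial, name="O4", element="O",
                      coords=c4 + np.array([-_GLYCOSIDIC, 0.0, -2 * _RING_Z["C4"]])))
    return Fragment(chain=chain, resnum=resnum, resname="BGC",
                    kind="glycosyl_unit", atoms=atoms)


def build_glycan_chain(positions: list[int], chain: str = "X",
                       first_resnum: int = 1) -> Structure:
    """β-1,4-style chain of simplified glucosyl units.

    ``positions`` are subsite labels from nonreducing to reducing end
    (e.g. [-2, -1, 1, 2]); the unit at position p donates its C1 to the O4
    of the unit at the next (more positive) position.
    """
    if sorted(positions) != positions or 0 in positions:
        raise ValueError("positions must be increasing and exclude 0")
    spacing = 2 * _RING_BOND + 2 * _GLYCOSIDIC
    fragments = []
    for i, pos in enumerate(positions):
        frag = _glucosyl_unit(chain, first_resnum + i, i * spacing)
        frag.glycan_position = pos
        fragments.append(frag)
    # renumber serials globally
    serial = 0
    for f in fragments:
        for a in f.atoms:
            serial += 1
            a.serial = serial
    st = Structure(fragments=fragments)
    for a, b in zip(fragments, fragments[1:]):
        st.glycosidic_links.append(
            GlycosidicLink(donor=a.key, c1_name="C1", acceptor=b.key, o4_name="O4"))
    return st


# ---------------------------------------------------------------------------
# Synthetic active sites

@dataclass(frozen=True)
class ShellResidue:
    restype: str
    distance: float          # Å, closest heavy-atom approach to the ligand
    direction: tuple[float, float, float]
    resnum: int
    chain: str = "A"


@dataclass
class SiteSpec:
    """Recipe for a miniature active site around a glucosyl ligand."""

    ligand: str = "glucose"          # glucose | disaccharide
    shell: list[ShellResidue] = field(default_factory=list)
    waters: list[tuple[float, tuple[float, float, float]]] = field(default_factory=list)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for s in self.shell:
            if s.distance <= _CLASH_LIMIT:
                raise ValueError(
                    f"shell residue {s.restype}{s.resnum} at {s.distance} Å "
                    f"violates the {_CLASH_LIMIT} Å clash limit")


def _ligand_fragments(kind: str) -> list[Fragment]:
    if kind == "glucose":
        st = build_glycan_chain([1], chain="X")
    elif kind == "disaccharide":
        st = build_glycan_chain([-1, 1], chain="X")
    else:
        raise ValueError(f"unknown ligand template {kind!r}")
    return st.fragments


def _placed_residue(site: ShellResidue, ligand_heavy: np.ndarray,
                    rng: np.random.Generator) -> Fragment:
    frag = build_residue(site.restype, chain=site.chain, resnum=site.resnum)
    u = np.asarray(site.direction, float)
    u = u / np.linalg.norm(u)
    # orient the template's N→CA axis along the outward direction, with a
    # seed-controlled spin about it for variety
    ca = frag.atom("CA").coords
    n = frag.atom("N").coords
    axis = ca - n
    rot = _rotation_between(axis / np.linalg.norm(axis), u)
    spin = _axis_rotation(u, float(rng.uniform(0, 2 * math.pi)))
    for a in frag.atoms:
        a.coords = spin @ (rot @ (a.coords - ca))
    # translate along u until the nearest heavy-atom pair sits at `distance`
    coords = np.array([a.coords for a in frag.heavy_atoms()])

    def min_gap(t: float) -> float:
        moved = coords + t * u
        d = np.linalg.norm(moved[:, None, :] - ligand_heavy[None, :, :], axis=2)
        return float(d.min())

    lo, hi = 0.0, 100.0
    while min_gap(lo) > site.distance:
        lo -= 5.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if min_gap(mid) < site.distance:
            lo = mid
        else:
            hi = mid
    t = 0.5 * (lo + hi)
    for a in frag.atoms:
        a.coords = a.coords + t * u
    return frag


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else -np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _axis_rotation(u: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    ux = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return c * np.eye(3) + s * ux + (1 - c) * np.outer(u, u)


def make_synthetic_site(spec: SiteSpec) -> str:
    """PDB text for a synthetic active site (deterministic per rng_seed)."""
    rng = np.random.default_rng(spec.rng_seed)
    fragments = _ligand_fragments(spec.ligand)
    ligand_heavy = np.array([a.coords for f in fragments for a in f.heavy_atoms()])
    for site in spec.shell:
        fragments.append(_placed_residue(site, ligand_heavy, rng))
    wat_num = 900
    for dist, direction in spec.waters:
        u = np.asarray(direction, float)
        u = u / np.linalg.norm(u)
        anchor = ligand_heavy[np.argmax(ligand_heavy @ u)]
        wat_num += 1
        fragments.append(Fragment(chain="W", resnum=wat_num, resname="HOH",
                                  kind="water",
                                  atoms=[Atom(serial=1, name="O", element="O",
                                              coords=anchor + dist * u)]))
    serial = 0
    for f in fragments:
        for a in f.atoms:
            serial += 1
            a.serial = serial
    st = Structure(fragments=fragments)
    _check_clashes(st)
    perceive_links(st)
    return write_pdb(st)


def _check_clashes(st: Structure) -> None:
    frags = st.fragments
    for i, fa in enumerate(frags):
        ca = np.array([a.coords for a in fa.heavy_atoms()])
        for fb in frags[i + 1:]:
            if fa.kind == fb.kind == "glycosyl_unit":
                continue  # covalently linked chain
            if fa.kind == fb.kind == "amino_acid" and abs(fa.resnum - fb.resnum) == 1:
                continue
            cb = np.array([a.coords for a in fb.heavy_atoms()])
            d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)
            if d.min() < _CLASH_LIMIT:
                raise ValueError(
                    f"clash: {fa.resname}{fa.resnum} and {fb.resname}{fb.resnum} "
                    f"approach to {d.min():.2f} Å")


# ---------------------------------------------------------------------------
# Packaged study data

_SCHEME_FILES = {
    "Res16-E": "scheme_res16e.yaml",
    "Res21-E": "scheme_res21e.yaml",
    "Res16-Q": "scheme_res16q.yaml",
    "Res20-Q": "scheme_res20q.yaml",
    "Res21-Q": "scheme_res21q.yaml",
    "Res23-Q": "scheme_res23q.yaml",
}


def packaged_schemes() -> dict[str, TrimScheme]:
    """The six study trimming schemes, transcribed row-for-row."""
    out = {}
    for name, fname in _SCHEME_FILES.items():
        text = resources.files("rincluster.data").joinpath(fname).read_text()
        out[name] = TrimScheme.from_yaml(text)
    return out


def packaged_ledger() -> EnergyLedger:
    """Energy ledger reproducing the printed relative free energies.

    Encoded as absolute pseudo-Hartree values with an isolated-water
    reference so that diagram assembly must perform unit conversion and
    water balancing to recover the printed kcal mol⁻¹ numbers.
    """
    text = resources.files("rincluster.data").joinpath("ledger_printed.csv").read_text()
    return read_energy_ledger(text)
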