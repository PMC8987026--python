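"""Template-based hydrogen addition and protonation-state assignment.

Hydrogens are placed at idealized internal coordinates (C–H 1.09 Å,
N–H 1.01 Å, O–H 0.96 Å; tetrahedral or trigonal angles by hybridization),
deterministically: the same structure always yields byte-identical
hydrogens.  Flip optimization of Asn/Gln/His orientations is not performed.

Default protonation reflects a mildly acidic crystallization pH (~6):
Asp/Glu ionized, Lys/Arg protonated, His singly protonated at Nε.  The
catalytically motivated exceptions used for glycoside hydrolase models —
doubly protonated His, neutral (protonated) Asp/Glu, a protonated Gln
mimicking a protonated Glu — are expressed as per-fragment overrides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import covalent_radius, xh_length, BOND_TOLERANCE
from .structure import Atom, FragKey, Fragment, Structure, parse_key

# Expected hydrogen counts on side-chain heavy atoms (default states).
# Backbone atoms are handled separately (N:1 except PRO, CA:1 except GLY:2).
_SIDECHAIN_H: dict[str, dict[str, int]] = {
    "ALA": {"CB": 3},
    "ARG": {"CB": 2, "CG": 2, "CD": 2, "NE": 1, "CZ": 0, "NH1": 2, "NH2": 2},
    "ASN": {"CB": 2, "CG": 0, "OD1": 0, "ND2": 2},
    "ASP": {"CB": 2, "CG": 0, "OD1": 0, "OD2": 0},
    "CYS": {"CB": 2, "SG": 1},
    "GLN": {"CB": 2, "CG": 2, "CD": 0, "OE1": 0, "NE2": 2},
    "GLU": {"CB": 2, "CG": 2, "CD": 0, "OE1": 0, "OE2": 0},
    "GLY": {},
    "HIS": {"CB": 2, "CG": 0, "ND1": 0, "CD2": 1, "CE1": 1, "NE2": 1},
    "ILE": {"CB": 1, "CG1": 2, "CG2": 3, "CD1": 3},
    "LEU": {"CB": 2, "CG": 1, "CD1": 3, "CD2": 3},
    "LYS": {"CB": 2, "CG": 2, "CD": 2, "CE": 2, "NZ": 3},
    "MET": {"CB": 2, "CG": 2, "SD": 0, "CE": 3},
    "PHE": {"CB": 2, "CG": 0, "CD1": 1, "CD2": 1, "CE1": 1, "CE2": 1, "CZ": 1},
    "PRO": {"CB": 2, "CG": 2, "CD": 2},
    "SER": {"CB": 2, "OG": 1},
    "THR": {"CB": 1, "OG1": 1, "CG2": 3},
    "TRP": {"CB": 2, "CG": 0, "CD1": 1, "CD2": 0, "NE1": 1, "CE2": 0,
            "CE3": 1, "CZ2": 1, "CZ3": 1, "CH2": 1},
    "TYR": {"CB": 2, "CG": 0, "CD1": 1, "CD2": 1, "CE1": 1, "CE2": 1, "CZ": 0, "OH": 1},
    "VAL": {"CB": 1, "CG1": 3, "CG2": 3},
}

# (residue, state) -> (formal charge, H-count overrides on named atoms)
PROTONATION_STATES: dict[tuple[str, str], tuple[int, dict[str, int]]] = {
    ("ASP", "ionized"): (-1, {}),
    ("ASP", "neutral"): (0, {"OD2": 1}),
    ("GLU", "ionized"): (-1, {}),
    ("GLU", "neutral"): (0, {"OE2": 1}),
    ("HIS", "epsilon"): (0, {}),
    ("HIS", "delta"): (0, {"ND1": 1, "NE2": 0}),
    ("HIS", "doubly_protonated"): (1, {"ND1": 1, "NE2": 1}),
    ("GLN", "standard"): (0, {}),
    ("GLN", "protonated"): (1, {"NE2": 3}),
    ("LYS", "protonated"): (1, {}),
    ("LYS", "neutral"): (0, {"NZ": 2}),
    ("ARG", "protonated"): (1, {}),
}

_DEFAULT_STATE: dict[str, str] = {
    "ASP": "ionized", "GLU": "ionized", "HIS": "epsilon",
    "LYS": "protonated", "ARG": "protonated", "GLN": "standard",
}

_DEFAULT_CHARGE: dict[str, int] = {"ASP": -1, "GLU": -1, "LYS": 1, "ARG": 1}

_GENERIC_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2}

_TET = math.radians(109.471)


@dataclass
class ProtonationSpec:
    """Per-fragment protonation overrides: fragment key -> state name."""

    overrides: dict[FragKey, str] = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "ProtonationSpec":
        return cls(overrides={parse_key(k): v for k, v in mapping.items()})


def state_charge(resname: str, state: str) -> int:
    key = (resname.upper(), state)
    if key in PROTONATION_STATES:
        return PROTONATION_STATES[key][0]
    if state == "standard":
        return _DEFAULT_CHARGE.get(resname.upper(), 0)
    raise ValueError(f"unknown protonation state {state!r} for {resname}")


# ---------------------------------------------------------------------------
# Bond perception

def bond_graph(structure: Structure) -> dict[int, list[Atom]]:
    """Map atom id() -> bonded partners, perceived from covalent radii."""
    atoms = structure.all_atoms()
    coords = np.array([a.coords for a in atoms])
    radii = np.array([covalent_radius(a.element) for a in atoms])
    graph: dict[int, list[Atom]] = {id(a): [] for a in atoms}
    if len(atoms) < 2:
        return graph
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    cut = BOND_TOLERANCE * (radii[:, None] + radii[None, :])
    np.fill_diagonal(dist, np.inf)
    ii, jj = np.where(dist <= cut)
    for i, j in zip(ii, jj):
        if atoms[i].is_hydrogen and atoms[j].is_hydrogen:
            continue
        graph[id(atoms[i])].append(atoms[j])
    return graph


def heavy_neighbors(atom: Atom, graph: dict[int, list[Atom]]) -> list[Atom]:
    return [b for b in graph.get(id(atom), []) if not b.is_hydrogen]


def hydrogen_neighbors(atom: Atom, graph: dict[int, list[Atom]]) -> list[Atom]:
    return [b for b in graph.get(id(atom), []) if b.is_hydrogen]


# ---------------------------------------------------------------------------
# Expected hydrogen counts

def _expected_h_amino(frag: Fragment, atom: Atom, state: str, n_term: bool) -> int:
    res = frag.resname.upper()
    name = atom.name
    if name == "N":
        if res == "PRO":
            return 1 if n_term else 0
        return 2 if n_term else 1
    if name == "CA":
        return 2 if res == "GLY" else 1
    if name in ("C", "O"):
        return 0
    if name == "OXT":
        return 1  # neutral C-terminal carboxylic acid
    table = _SIDECHAIN_H.get(res)
    if table is None:
        raise ValueError(f"no hydrogen template for residue {res}")
    base = table.get(name)
    if base is None:
        raise ValueError(f"no template entry for atom {name} of {res}")
    overrides = PROTONATION_STATES.get((res, state), (0, {}))[1]
    return overrides.get(name, base)


def _expected_h_generic(atom: Atom, n_heavy: int) -> int:
    val = _GENERIC_VALENCE.get(atom.element.capitalize())
    if val is None:
        raise ValueError(
            f"no generic valence rule for element {atom.element!r} (atom {atom.name})")
    return max(val - n_heavy, 0)


# ---------------------------------------------------------------------------
# Geometric placement

def _perp(v: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(v, ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    p = np.cross(v, ref)
    return p / np.linalg.norm(p)


def place_hydrogens(center: np.ndarray, element: str,
                    neighbor_coords: list[np.ndarray], n_h: int,
                    ref: np.ndarray | None = None) -> list[np.ndarray]:
    """Idealized positions for ``n_h`` hydrogens on one heavy atom.

    ``ref`` is a second-shell atom fixing rotational freedom (hydroxyl
    dihedrals, methyl staggering, amide planes); when absent a deterministic
    global-frame fallback is used.
    """
    L = xh_length(element)
    c = np.asarray(center, float)
    us = []
    for n in neighbor_coords:
        v = np.asarray(n, float) - c
        us.append(v / np.linalg.norm(v))
    k = len(us)
    steric = k + n_h

    if n_h == 0:
        return []
    if k == 0:
        # free molecule (water, ions): fixed orientation in the global frame
        out = [c + L * np.array([1.0, 0.0, 0.0])]
        if n_h >= 2:
            ang = math.radians(104.5 if element.upper() == "O" else 109.471)
            out.append(c + L * np.array([math.cos(ang), math.sin(ang), 0.0]))
        if n_h >= 3:
            out.append(c + L * np.array([math.cos(ang), -math.sin(ang) * 0.5,
                                         math.sin(ang) * math.sqrt(3) / 2]))
        return out[:n_h]
    if k == 1:
        u = us[0]
        if ref is not None:
            w = np.asarray(ref, float) - (c + us[0] * 0.0)
            w = w - np.dot(w, u) * u
            nw = np.linalg.norm(w)
            p = w / nw if nw > 1e-8 else _perp(u)
            p = -p  # anti-periplanar to the reference
        else:
            p = _perp(u)
        if n_h == 1:
            ang = _TET if element.upper() in ("O", "S") else math.radians(120.0)
            # tilt away from the neighbor direction u by the X–H angle
            d = math.cos(ang) * u + math.sin(ang) * p
            return [c + L * d]
        if n_h == 2:  # planar NH2 / terminal amine
            ang = math.radians(120.0)
            d1 = math.cos(ang) * u + math.sin(ang) * p
            d2 = math.cos(ang) * u - math.sin(ang) * p
            return [c + L * d1, c + L * d2]
        # methyl / NH3+: tetrahedral cone, staggered about u
        q = np.cross(u, p)
        out = []
        for i in range(n_h):
            phi = math.radians(180.0 + 120.0 * i)
            rim = math.cos(phi) * p + math.sin(phi) * q
            d = math.cos(_TET) * u + math.sin(_TET) * rim
            out.append(c + L * d)
        return out
    if k == 2:
        u1, u2 = us
        b = -(u1 + u2)
        nb = np.linalg.norm(b)
        b = b / nb if nb > 1e-8 else _perp(u1)
        if n_h == 1:
            return [c + L * b]
        p = np.cross(u1, u2)
        npn = np.linalg.norm(p)
        p = p / npn if npn > 1e-8 else _perp(u1)
        half = _TET / 2.0
        return [c + L * (b * math.cos(half) + p * math.sin(half)),
                c + L * (b * math.cos(half) - p * math.sin(half))]
    # k >= 3: single completion along the negative vector sum
    b = -np.sum(us, axis=0)
    nb = np.linalg.norm(b)
    b = b / nb if nb > 1e-8 else _perp(us[0])
    return [c + L * b]


_H_NAME_MAP = {"N": "H", "CA": "HA", "OXT": "HXT"}


def _h_names(atom: Atom, frag: Fragment, count: int) -> list[str]:
    base = _H_NAME_MAP.get(atom.name, "H" + atom.name[1:] if len(atom.name) > 1 else "H1")
    if count == 1 and not frag.has_atom(base):
        return [base]
    names, i = [], 1
    while len(names) < count:
        cand = f"{base}{i}"
        if not frag.has_atom(cand):
            names.append(cand)
        i += 1
    return names


# ---------------------------------------------------------------------------
# Public operations

def add_hydrogens(structure: Structure, spec: ProtonationSpec | None = None) -> Structure:
    """Return a copy with every heavy atom completed to template valence.

    Added atoms carry ``origin='added_hydrogen'``; fragment formal charges
    are set from the (default or overridden) protonation state.
    """
    spec = spec or ProtonationSpec()
    out = structure.copy()
    for frag in out.fragments:
        state = spec.overrides.get(frag.key, _default_state(frag))
        _validate_state(frag, state)
    _protonate(out, {f.key: spec.overrides.get(f.key, _default_state(f))
                     for f in out.fragments})
    return out


def set_protonation(structure: Structure, overrides: ProtonationSpec) -> Structure:
    """Re-template the named fragments only; all others are untouched."""
    out = structure.copy()
    for key, state in overrides.overrides.items():
        frag = out.fragment(key)
        _validate_state(frag, state)
    _protonate(out, dict(overrides.overrides))
    return out


def _default_state(frag: Fragment) -> str:
    return _DEFAULT_STATE.get(frag.resname.upper(), "standard")


def _validate_state(frag: Fragment, state: str) -> None:
    if frag.kind != "amino_acid" and state != "standard":
        raise ValueError(
            f"protonation state {state!r} targets {frag.label} ({frag.kind}); "
            "amino-acid states apply only to amino acids")
    if frag.kind == "amino_acid":
        res = frag.resname.upper()
        if state != "standard" and (res, state) not in PROTONATION_STATES:
            raise ValueError(f"unknown protonation state {state!r} for {res}")


def _protonate(structure: Structure, states: dict[FragKey, str]) -> None:
    serial = max((a.serial for a in structure.all_atoms()), default=0)
    targets = [f for f in structure.fragments if f.key in states]
    for frag in targets:
        frag.atoms = [a for a in frag.atoms if not (a.is_hydrogen and a.origin == "added_hydrogen")]
    graph = bond_graph(structure)
    n_term = _n_terminal_keys(structure)
    for frag in targets:
        state = states[frag.key]
        new_atoms: list[Atom] = []
        for atom in frag.atoms:
            if atom.is_hydrogen:
                continue
            hn = heavy_neighbors(atom, graph)
            if frag.kind == "amino_acid":
                want = _expected_h_amino(frag, atom, state, frag.key in n_term)
            else:
                want = _expected_h_generic(atom, len(hn))
            have = len(hydrogen_neighbors(atom, graph))
            missing = want - have
            if missing <= 0:
                continue
            ref = _dihedral_reference(atom, hn, graph)
            positions = place_hydrogens(atom.coords, atom.element,
                                        [n.coords for n in hn], missing,
                                        ref=ref)
            for name, pos in zip(_h_names(atom, frag, missing), positions):
                serial += 1
                new_atoms.append(Atom(serial=serial, name=name, element="H",
                                      coords=pos, origin="added_hydrogen"))
        frag.atoms.extend(new_atoms)
        if frag.kind == "amino_acid":
            frag.formal_charge = state_charge(frag.resname, state)
        else:
            frag.formal_charge = 0


def _n_terminal_keys(structure: Structure) -> set[FragKey]:
    has_prev = {b for (_, b) in structure.backbone_links}
    return {f.key for f in structure.fragments
            if f.kind == "amino_acid" and f.key not in has_prev}


def _dihedral_reference(atom: Atom, hn: list[Atom],
                        graph: dict[int, list[Atom]]) -> np.ndarray | None:
    if len(hn) != 1:
        return None
    second = [b for b in heavy_neighbors(hn[0], graph) if b is not atom]
    if not second:
        return None
    return min(second, key=lambda a: a.serial).coords


# ---------------------------------------------------------------------------
# Valence audit

_VALENCE_RANGE = {"H": (1, 1), "C": (3, 4), "N": (2, 4), "O": (1, 2), "S": (1, 2)}


def neighbor_counts(atoms: list[Atom]) -> dict[int, int]:
    """Bond count per atom (by id) under covalent-radius perception."""
    coords = np.array([a.coords for a in atoms])
    radii = np.array([covalent_radius(a.element) for a in atoms])
    counts = {id(a): 0 for a in atoms}
    if len(atoms) < 2:
        return counts
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    np.fill_diagonal(dist, np.inf)
    cut = BOND_TOLERANCE * (radii[:, None] + radii[None, :])
    h = np.array([a.is_hydrogen for a in atoms])
    ok = (dist <= cut) & ~(h[:, None] & h[None, :])
    for i, a in enumerate(atoms):
        counts[id(a)] = int(ok[i].sum())
    return counts


def audit_valences(atoms: list[Atom]) -> list[str]:
    """Return a list of valence violations (empty when the set is closed)."""
    counts = neighbor_counts(atoms)
    problems = []
    for a in atoms:
        lo_hi = _VALENCE_RANGE.get(a.element.capitalize())
        if lo_hi is None:
            continue
        n = counts[id(a)]
        if not (lo_hi[0] <= n <= lo_hi[1]):
            problems.append(f"{a.name} ({a.element}) has {n} bonds, expected {lo_hi}")
    return problems
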