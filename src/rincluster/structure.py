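"""Structure model: PDB reading/writing, fragments, and glycan-chain surgery.

A :class:`Structure` is an ordered collection of :class:`Fragment` objects
(amino-acid residues, glycosyl units, waters), each an ordered collection of
:class:`Atom`.  PDB parsing and serialization go through :mod:`gemmi`;
this module adds the bookkeeping the model builder needs: alternate-location
resolution, peptide/glycosidic connectivity, formal charges, and the
glycan-chain truncation used to prepare cellulose fragments for QM-cluster
models (keeping only the catalytically relevant −1/+1 glucosyl units, with
the severed glycosidic oxygens retained or protonated as hydroxyls).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .constants import BOND_TOLERANCE, covalent_radius, vdw_radius, xh_length

FragKey = tuple[str, int]

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
WATER_CODES = {"HOH", "WAT", "H2O", "TIP", "DOD"}
GLYCAN_CODES = {"BGC", "GLC", "NAG", "GAL", "MAN", "BMA"}


@dataclass
class Atom:
    """One atom with PDB-style metadata.

    origin distinguishes experimentally observed atoms from hydrogens added
    by templates and from link-replacing caps.
    """

    serial: int
    name: str
    element: str
    coords: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0
    origin: str = "experimental"  # experimental | added_hydrogen | cap

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial} {self.name}: bad coordinates")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"

    @property
    def vdw_radius(self) -> float:
        return vdw_radius(self.element)

    def copy(self) -> "Atom":
        return replace(self, coords=self.coords.copy())


@dataclass
class Fragment:
    chain: str
    resnum: int
    resname: str
    kind: str  # amino_acid | glycosyl_unit | water | other
    atoms: list[Atom] = field(default_factory=list)
    formal_charge: int = 0
    glycan_position: int | None = None

    @property
    def key(self) -> FragKey:
        return (self.chain, self.resnum)

    @property
    def label(self) -> str:
        return f"{self.chain}:{self.resnum}"

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"{self.label}/{self.resname} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def copy(self) -> "Fragment":
        return replace(self, atoms=[a.copy() for a in self.atoms])


@dataclass(frozen=True)
class GlycosidicLink:
    """β-1,4 link: the donor's anomeric C1 bonds the acceptor's O4."""

    donor: FragKey
    c1_name: str
    acceptor: FragKey
    o4_name: str


@dataclass
class Structure:
    fragments: list[Fragment] = field(default_factory=list)
    backbone_links: set[tuple[FragKey, FragKey]] = field(default_factory=set)
    glycosidic_links: list[GlycosidicLink] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for f in self.fragments:
            k = (f.chain, f.resnum, f.resname)
            if k in seen:
                raise ValueError(f"duplicate fragment key {k}")
            seen.add(k)

    def fragment(self, key: FragKey | str) -> Fragment:
        key = parse_key(key)
        for f in self.fragments:
            if f.key == key:
                return f
        raise KeyError(f"no fragment {key}")

    def has_fragment(self, key: FragKey | str) -> bool:
        key = parse_key(key)
        return any(f.key == key for f in self.fragments)

    @property
    def keys(self) -> list[FragKey]:
        return [f.key for f in self.fragments]

    def all_atoms(self) -> list[Atom]:
        return [a for f in self.fragments for a in f.atoms]

    @property
    def total_charge(self) -> int:
        return sum(f.formal_charge for f in self.fragments)

    def copy(self) -> "Structure":
        return Structure(
            fragments=[f.copy() for f in self.fragments],
            backbone_links=set(self.backbone_links),
            glycosidic_links=list(self.glycosidic_links),
        )


def parse_key(key: FragKey | str) -> FragKey:
    """Accept ('A', 143) or the CLI form 'A:143'."""
    if isinstance(key, str):
        chain, _, num = key.partition(":")
        if not num:
            raise ValueError(f"bad fragment key {key!r}; expected 'CHAIN:RESNUM'")
        return (chain, int(num))
    return (key[0], int(key[1]))


def classify_residue(resname: str) -> str:
    name = resname.upper()
    if name in WATER_CODES:
        return "water"
    if name in GLYCAN_CODES:
        return "glycosyl_unit"
    if name in AMINO_ACIDS:
        return "amino_acid"
    return "other"


def bonded(a: Atom, b: Atom) -> bool:
    cutoff = BOND_TOLERANCE * (covalent_radius(a.element) + covalent_radius(b.element))
    return float(np.linalg.norm(a.coords - b.coords)) <= cutoff


# ---------------------------------------------------------------------------
# PDB input / output

def read_pdb(pdb_text: str, altloc_policy: str = "A") -> Structure:
    """Parse PDB text into a Structure, resolving alternate locations.

    altloc_policy is either a one-character altloc label (atoms with a
    different, nonblank label are dropped) or ``"highest-occupancy"``.
    Fragments are partitioned by (chain, resnum, resname); peptide and
    glycosidic connectivity is perceived geometrically.
    """
    _check_serials(pdb_text)
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:  # gemmi names the bad line
        raise ValueError(f"PDB parse error: {exc}") from None
    st.setup_entities()

    fragments: list[Fragment] = []
    for model in st:
        for chain in model:
            for res in chain:
                atoms = _select_altlocs(res, altloc_policy)
                if not atoms:
                    continue
                fragments.append(
                    Fragment(
                        chain=chain.name,
                        resnum=res.seqid.num,
                        resname=res.name,
                        kind=classify_residue(res.name),
                        atoms=atoms,
                    )
                )
        break  # first model only
    structure = Structure(fragments=fragments)
    perceive_links(structure)
    return structure


def _check_serials(pdb_text: str) -> None:
    seen: set[int] = set()
    for i, line in enumerate(pdb_text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            try:
                serial = int(line[6:11])
                for col in (line[30:38], line[38:46], line[46:54]):
                    float(col)
            except ValueError:
                raise ValueError(f"malformed coordinate/serial field at line {i}") from None
            if serial in seen:
                raise ValueError(f"duplicate atom serial {serial} at line {i}")
            seen.add(serial)


def _altloc_label(at: gemmi.Atom) -> str:
    al = at.altloc
    return "" if al in ("", "\x00") else al


def _select_altlocs(res: gemmi.Residue, policy: str) -> list[Atom]:
    by_name: dict[str, list[gemmi.Atom]] = {}
    for at in res:
        by_name.setdefault(at.name, []).append(at)
    out: list[Atom] = []
    for name, group in by_name.items():
        if len(group) == 1 and not _altloc_label(group[0]):
            chosen = group[0]
        elif policy == "highest-occupancy":
            chosen = max(group, key=lambda a: (a.occ, -ord(_altloc_label(a) or "A")))
        else:
            matches = [a for a in group if _altloc_label(a) in ("", policy)]
            if not matches:
                continue
            chosen = matches[0]
        element = chosen.element.name if chosen.element else name.strip()[0]
        out.append(
            Atom(
                serial=chosen.serial,
                name=name,
                element=element,
                coords=np.array([chosen.pos.x, chosen.pos.y, chosen.pos.z]),
                altloc=_altloc_label(chosen),
                occupancy=chosen.occ,
            )
        )
    out.sort(key=lambda a: a.serial)
    return out


def perceive_links(structure: Structure) -> None:
    """Fill backbone_links and glycosidic_links from geometry."""
    structure.backbone_links.clear()
    structure.glycosidic_links.clear()
    aa = [f for f in structure.fragments if f.kind == "amino_acid"]
    for fa in aa:
        for fb in aa:
            if fa is fb or fa.chain != fb.chain:
                continue
            if fa.has_atom("C") and fb.has_atom("N") and bonded(fa.atom("C"), fb.atom("N")):
                structure.backbone_links.add((fa.key, fb.key))
    sugars = [f for f in structure.fragments if f.kind == "glycosyl_unit"]
    for fa in sugars:
        if not fa.has_atom("C1"):
            continue
        for fb in sugars:
            if fa is fb or not fb.has_atom("O4"):
                continue
            if bonded(fa.atom("C1"), fb.atom("O4")):
                structure.glycosidic_links.append(
                    GlycosidicLink(donor=fa.key, c1_name="C1", acceptor=fb.key, o4_name="O4")
                )


def write_pdb(structure: Structure) -> str:
    """Serialize a Structure back to PDB text (ATOM/HETATM/TER/END)."""
    lines: list[str] = []
    serial = 0
    last_chain = None
    for frag in structure.fragments:
        record = "ATOM  " if frag.kind == "amino_acid" else "HETATM"
        if last_chain is not None and frag.chain != last_chain:
            lines.append("TER")
        last_chain = frag.chain
        for atom in frag.atoms:
            serial += 1
            name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
            x, y, z = atom.coords
            lines.append(
                f"{record}{serial:5d} {name:<4s}{atom.altloc or ' '}{frag.resname:<3s} "
                f"{frag.chain:1s}{frag.resnum:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                f"          {atom.element.upper():>2s}"
            )
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Glycan chains

def assign_glycan_positions(structure: Structure, positions: dict) -> Structure:
    """Attach signed subsite positions (+2, +1, −1, −2, …) to glycosyl units."""
    for key, pos in positions.items():
        frag = structure.fragment(key)
        if frag.kind != "glycosyl_unit":
            raise ValueError(f"{frag.label} is not a glycosyl unit")
        frag.glycan_position = int(pos)
    return structure


def infer_glycan_positions(structure: Structure, reducing_end: int) -> Structure:
    """Walk the glycosidic links from the reducing end, assigning positions.

    The reducing-end unit (free anomeric C1, i.e. never a donor) gets
    ``reducing_end``; each acceptor-to-donor step toward the nonreducing end
    decrements the position, skipping 0 (subsites are …, −1, +1, …).
    """
    sugars = {f.key for f in structure.fragments if f.kind == "glycosyl_unit"}
    donors = {l.donor for l in structure.glycosidic_links}
    acceptor_of = {l.donor: l.acceptor for l in structure.glycosidic_links}
    donor_of = {l.acceptor: l.donor for l in structure.glycosidic_links}
    ends = sorted(sugars - donors)
    if len(ends) != 1:
        raise ValueError(f"expected one reducing end, found {len(ends)}")
    pos = int(reducing_end)
    key = ends[0]
    while True:
        structure.fragment(key).glycan_position = pos
        if key not in donor_of:
            break
        key = donor_of[key]
        pos -= 1
        if pos == 0:
            pos = -1
    # sanity: acceptor_of is the inverse walk
    del acceptor_of
    return structure


def truncate_glycan_chain(structure: Structure, keep_positions: set[int]) -> Structure:
    """Trim a glycan chain to ``keep_positions``, capping the cut bonds.

    At each severed glycosidic link with exactly one side kept: if the
    bridging O4 belongs to the removed unit it is retained (reassigned to the
    kept fragment) and capped with H toward its severed C4; if it belongs to
    the kept unit, that O4 simply receives one H along the severed C1
    direction.  Coordinates of retained experimental atoms are untouched.
    """
    keep = {int(p) for p in keep_positions}
    out = structure.copy()
    sugars = {f.key: f for f in out.fragments if f.kind == "glycosyl_unit"}
    if any(f.glycan_position is None for f in sugars.values()):
        raise ValueError("glycan positions not assigned; call assign_glycan_positions first")
    present = {f.glycan_position for f in sugars.values()}
    missing = keep - present
    if missing:
        raise ValueError(f"keep_positions {sorted(missing)} not present in chain {sorted(present)}")

    kept_key = {k for k, f in sugars.items() if f.glycan_position in keep}
    removed_key = set(sugars) - kept_key
    max_serial = max((a.serial for a in out.all_atoms()), default=0)

    def _cap_oxygen(oxygen: Atom, toward: np.ndarray, host: Fragment) -> None:
        nonlocal max_serial
        direction = toward - oxygen.coords
        direction = direction / np.linalg.norm(direction)
        max_serial += 1
        host.atoms.append(
            Atom(
                serial=max_serial,
                name=_unique_h_name(host),
                element="H",
                coords=oxygen.coords + xh_length("O") * direction,
                origin="cap",
            )
        )

    surviving_links: list[GlycosidicLink] = []
    for link in out.glycosidic_links:
        d_kept, a_kept = link.donor in kept_key, link.acceptor in kept_key
        if d_kept and a_kept:
            surviving_links.append(link)
        elif d_kept and not a_kept:
            # acceptor removed: its bridging O4 is retained on the kept donor
            acceptor = out.fragment(link.acceptor)
            donor = out.fragment(link.donor)
            o4 = acceptor.atom(link.o4_name)
            kept_o4 = o4.copy()
            kept_o4.name = _unique_name(donor, "O4R")
            donor.atoms.append(kept_o4)
            if acceptor.has_atom("C4"):
                toward = acceptor.atom("C4").coords
            else:  # no C4 recorded: point away from the kept anomeric carbon
                toward = 2.0 * o4.coords - donor.atom(link.c1_name).coords
            _cap_oxygen(kept_o4, toward, donor)
        elif a_kept and not d_kept:
            # donor removed: the kept acceptor's O4 is freed and protonated
            acceptor = out.fragment(link.acceptor)
            donor = out.fragment(link.donor)
            o4 = acceptor.atom(link.o4_name)
            _cap_oxygen(o4, donor.atom(link.c1_name).coords, acceptor)
    out.glycosidic_links = surviving_links
    out.fragments = [f for f in out.fragments if f.key not in removed_key]
    return out


def _unique_h_name(frag: Fragment) -> str:
    i = 1
    while frag.has_atom(f"HO{i}"):
        i += 1
    return f"HO{i}"


def _unique_name(frag: Fragment, base: str) -> str:
    if not frag.has_atom(base):
        return base
    i = 2
    while frag.has_atom(f"{base}{i}"):
        i += 1
    return f"{base}{i}"
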