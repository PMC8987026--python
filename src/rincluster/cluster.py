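"""Turn a residue selection into a QM-cluster model.

Residues are trimmed (typically truncated at Cα, keeping the side chain),
severed bonds are capped with hydrogens along the original bond vectors
(link-H convention), Cα/Cβ atoms are flagged frozen per the trimming
scheme, and the total charge is the sum of the included fragments' formal
charges.  Frozen flags are metadata here; their "freeze code" semantics are
realized when writing QM inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .constants import xh_length
from .hydrogens import bond_graph, heavy_neighbors
from .structure import Atom, FragKey, Fragment, Structure, parse_key

_BACKBONE = {"N", "CA", "C", "O", "OXT"}
_BACKBONE_H = {"H", "H1", "H2", "H3", "HA", "HA1", "HA2", "HA3", "HXT"}
_RETAIN_MODES = ("sidechain_Calpha", "backbone_only", "whole_fragment")


@dataclass(frozen=True)
class TrimRule:
    retain: str = "whole_fragment"
    frozen: tuple[str, ...] = ()
    charge: int | None = None  # bookkeeping charge for summary tables
    bridging: bool = False

    def __post_init__(self) -> None:
        if self.retain not in _RETAIN_MODES:
            raise ValueError(f"unknown retain mode {self.retain!r}")
        bad = set(self.frozen) - {"CA", "CB"}
        if bad:
            raise ValueError(f"frozen atoms must be CA/CB, got {sorted(bad)}")


@dataclass
class TrimScheme:
    """Per-residue trimming/freezing rules (one Table-style model column).

    Rules are keyed by residue label ("GLU212" style); an optional default
    covers unlisted members.
    """

    name: str
    rules: dict[str, TrimRule]
    default: TrimRule | None = None

    def rule_for(self, frag: Fragment) -> TrimRule:
        for key in (f"{frag.resname.upper()}{frag.resnum}", frag.label,
                    frag.resname.upper()):
            if key in self.rules:
                return self.rules[key]
        if self.default is not None:
            return self.default
        raise KeyError(f"scheme {self.name!r} has no rule for {frag.resname}{frag.resnum}")

    def frozen_totals(self) -> tuple[int, int]:
        """(n frozen Cα, n frozen Cβ) recomputed from the rules."""
        n_ca = sum(1 for r in self.rules.values() if "CA" in r.frozen)
        n_cb = sum(1 for r in self.rules.values() if "CB" in r.frozen)
        return n_ca, n_cb

    def charge_total(self) -> int:
        return sum(r.charge or 0 for r in self.rules.values())

    @classmethod
    def from_yaml(cls, text: str) -> "TrimScheme":
        doc = yaml.safe_load(text)
        rules = {}
        for block in doc["residues"]:
            rules[str(block["res"]).upper()] = TrimRule(
                retain=block.get("retain", "whole_fragment"),
                frozen=tuple(block.get("frozen", [])),
                charge=block.get("charge"),
                bridging=bool(block.get("bridging", False)),
            )
        default = None
        if "default" in doc:
            d = doc["default"]
            default = TrimRule(retain=d.get("retain", "whole_fragment"),
                               frozen=tuple(d.get("frozen", [])))
        return cls(name=doc.get("name", "scheme"), rules=rules, default=default)

    def to_yaml(self) -> str:
        blocks = []
        for res, rule in self.rules.items():
            b: dict = {"res": res, "retain": rule.retain}
            if rule.frozen:
                b["frozen"] = list(rule.frozen)
            if rule.charge is not None:
                b["charge"] = rule.charge
            if rule.bridging:
                b["bridging"] = True
        # preserve insertion order for byte-stable output
            blocks.append(b)
        doc: dict = {"name": self.name, "residues": blocks}
        return yaml.safe_dump(doc, sort_keys=False)


@dataclass
class ModelAtom:
    atom: Atom
    frozen: bool = False
    source: str = ""  # fragment label, or "cap" for link hydrogens


@dataclass
class ClusterModel:
    name: str
    atoms: list[ModelAtom]
    total_charge: int
    multiplicity: int = 1

    @property
    def frozen_counts(self) -> tuple[int, int]:
        n_ca = sum(1 for m in self.atoms if m.frozen and m.atom.name == "CA")
        n_cb = sum(1 for m in self.atoms if m.frozen and m.atom.name == "CB")
        return n_ca, n_cb

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def __post_init__(self) -> None:
        for m in self.atoms:
            if m.frozen and m.atom.name not in ("CA", "CB"):
                raise ValueError(f"frozen flag on non-Cα/Cβ atom {m.atom.name}")
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be positive")


@dataclass
class ModelSummary:
    model_name: str
    rows: list[tuple[str, int, str, bool]]  # (residue, charge, frozen marks, included)
    n_atoms: int
    total_charge: int
    frozen_ca: int
    frozen_cb: int


@dataclass(frozen=True)
class OpenSite:
    anchor: Atom
    removed_coords: np.ndarray
    source: str


# ---------------------------------------------------------------------------
# Trimming

def _retained_names(frag: Fragment, rule: TrimRule) -> set[str]:
    names = {a.name for a in frag.atoms}
    if rule.retain == "whole_fragment":
        return names
    if frag.kind != "amino_acid":
        raise ValueError(
            f"rule {rule.retain!r} is only valid for amino acids, not {frag.kind}")
    if rule.retain == "sidechain_Calpha":
        return {n for n in names
                if n not in (_BACKBONE - {"CA"}) and n not in (_BACKBONE_H - {"HA", "HA1", "HA2", "HA3"})}
    # backbone_only
    return {n for n in names if n in _BACKBONE or n in _BACKBONE_H}


def trim_residue(frag: Fragment, rule: TrimRule) -> tuple[list[Atom], list[OpenSite]]:
    """Apply one trimming rule; returns retained atoms and open-valence sites.

    Open sites arising at inter-fragment junctions (peptide or glycosidic
    bonds to fragments outside this one) are resolved by
    :func:`assemble_model`, which sees the whole structure.
    """
    keep = _retained_names(frag, rule)
    retained = [a for a in frag.atoms if a.name in keep]
    if len(retained) == len(frag.atoms):
        return retained, []
    graph = bond_graph(Structure(fragments=[frag]))
    sites: list[OpenSite] = []
    for a in retained:
        if a.is_hydrogen:
            continue
        for nb in heavy_neighbors(a, graph):
            if nb.name not in keep:
                sites.append(OpenSite(anchor=a, removed_coords=nb.coords.copy(),
                                      source=frag.label))
    return retained, sites


def cap_with_hydrogens(atoms: list[Atom], sites: list[OpenSite],
                       start_serial: int | None = None) -> list[Atom]:
    """Replace each open valence with an H along the original bond vector.

    Caps are flagged ``origin='cap'``.  Two caps closer than 0.8 Å indicate
    a chemically impossible trim and raise an error naming both sites.
    """
    serial = start_serial if start_serial is not None else (
        max((a.serial for a in atoms), default=0) + 1)
    caps: list[Atom] = []
    for site in sites:
        d = site.removed_coords - site.anchor.coords
        d = d / np.linalg.norm(d)
        pos = site.anchor.coords + xh_length(site.anchor.element) * d
        caps.append(Atom(serial=serial, name=f"HL{len(caps) + 1}", element="H",
                         coords=pos, origin="cap"))
        serial += 1
    for i in range(len(caps)):
        for j in range(i + 1, len(caps)):
            dist = float(np.linalg.norm(caps[i].coords - caps[j].coords))
            if dist < 0.8:
                raise ValueError(
                    f"cap collision ({dist:.2f} Å) between sites "
                    f"{sites[i].anchor.name}@{sites[i].source} and "
                    f"{sites[j].anchor.name}@{sites[j].source}")
    return atoms + caps


# ---------------------------------------------------------------------------
# Model assembly

def assemble_model(structure: Structure, selection, scheme: TrimScheme,
                   name: str, seed: set | None = None) -> ClusterModel:
    """Build a capped, charge-audited cluster model from a selection.

    Chosen and bridging fragments are trimmed per the scheme; seed
    fragments (glycosyl units/ligand) and waters are included whole.
    Severed bonds — including peptide and glycosidic bonds to fragments
    outside the model — are detected on the full structure's bond graph and
    capped with hydrogens.
    """
    seed_keys = {parse_key(k) for k in (seed or set())}
    member_keys = list(dict.fromkeys(
        [parse_key(k) for k in selection.chosen]
        + [parse_key(k) for k in selection.bridging]
        + sorted(seed_keys)))
    members: list[Fragment] = []
    for key in member_keys:
        members.append(structure.fragment(key))
    members.sort(key=lambda f: (f.chain, f.resnum))

    graph = bond_graph(structure)
    retained: list[ModelAtom] = []
    retained_ids: set[int] = set()
    frag_of_atom: dict[int, Fragment] = {}
    for f in structure.fragments:
        for a in f.atoms:
            frag_of_atom[id(a)] = f

    total_charge = 0
    for frag in members:
        if frag.key in seed_keys or frag.kind in ("water",):
            rule = TrimRule(retain="whole_fragment")
        else:
            rule = scheme.rule_for(frag)
        keep = _retained_names(frag, rule)
        for a in frag.atoms:
            if a.name in keep:
                retained.append(ModelAtom(
                    atom=a, frozen=(a.name in rule.frozen), source=frag.label))
                retained_ids.add(id(a))
        total_charge += frag.formal_charge

    # hydrogens orphaned by a removed heavy atom are dropped; severed
    # heavy-heavy bonds become cap sites
    kept: list[ModelAtom] = []
    sites: list[OpenSite] = []
    for m in retained:
        a = m.atom
        if a.is_hydrogen:
            anchors = [b for b in graph.get(id(a), []) if not b.is_hydrogen]
            if anchors and id(anchors[0]) not in retained_ids:
                continue
            kept.append(m)
            continue
        kept.append(m)
        for nb in heavy_neighbors(a, graph):
            if id(nb) not in retained_ids:
                sites.append(OpenSite(anchor=a, removed_coords=nb.coords.copy(),
                                      source=frag_of_atom[id(nb)].label))
    atoms = [m.atom for m in kept]
    capped = cap_with_hydrogens(atoms, sites)
    model_atoms = kept + [ModelAtom(atom=c, frozen=False, source="cap")
                          for c in capped[len(atoms):]]
    return ClusterModel(name=name, atoms=model_atoms, total_charge=total_charge)


def summarize_model(model: ClusterModel) -> ModelSummary:
    """Table-style per-residue summary with totals recomputed from atoms."""
    rows: list[tuple[str, int, str, bool]] = []
    seen: dict[str, tuple[int, set[str]]] = {}
    order: list[str] = []
    for m in model.atoms:
        src = m.source
        if src not in seen:
            seen[src] = (0, set())
            order.append(src)
        if m.frozen:
            seen[src][1].add(m.atom.name)
    for src in order:
        marks = " ".join(sorted(seen[src][1]))
        rows.append((src, 0, marks, True))
    n_ca, n_cb = model.frozen_counts
    return ModelSummary(model_name=model.name, rows=rows,
                        n_atoms=len(model.atoms),
                        total_charge=model.total_charge,
                        frozen_ca=n_ca, frozen_cb=n_cb)
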