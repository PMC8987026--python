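"""Geometry and QM-engine input writers, and energy-ledger reading.

Writers are byte-deterministic: no timestamps, fixed 6-decimal coordinate
precision, stable ordering.  The QM input dialect is a Gaussian-compatible
template: route line, charge/multiplicity, a coordinate block with a
per-atom freeze column (−1 frozen, 0 free — the "freeze code" convention,
under which Hessian elements involving frozen coordinates are zeroed by
the engine), and trailing per-element basis-set blocks.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import ClusterModel
from .energetics import EnergyLedger, parse_state_label

# basis assignment used for the bundled glycoside-hydrolase template:
# polarized double-zeta on heteroatoms, plain double-zeta on C and H
DEFAULT_BASIS_MAP = {"N": "6-31G(d')", "O": "6-31G(d')", "S": "6-31G(d')",
                     "C": "6-31G", "H": "6-31G"}

DEFAULT_ROUTE = ("#P B3LYP/Gen EmpiricalDispersion=GD3BJ "
                 "SCRF=(CPCM,Solvent=Water,Read) Opt Freq")


@dataclass
class QMJobSpec:
    """Method keywords, element→basis map, and solvation settings."""

    route: str = DEFAULT_ROUTE
    basis_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_BASIS_MAP))
    dielectric: float = 4.0
    electrostatic_scaling: float = 1.2
    template_name: str = "gaussian-compatible"


def write_xyz(model: ClusterModel, precision: int = 6) -> str:
    """Standard xyz text: count, comment (name/charge/multiplicity), rows."""
    lines = [str(model.n_atoms),
             f"{model.name} charge={model.total_charge} multiplicity={model.multiplicity}"]
    for m in model.atoms:
        x, y, z = m.atom.coords
        lines.append(f"{m.atom.element.capitalize():<2s} "
                     f"{x:14.{precision}f} {y:14.{precision}f} {z:14.{precision}f}")
    return "\n".join(lines) + "\n"


def read_xyz(text: str) -> list[tuple[str, np.ndarray]]:
    """Parse one xyz frame into (element, coords) pairs."""
    lines = text.strip().splitlines()
    n = int(lines[0])
    out = []
    for row in lines[2:2 + n]:
        parts = row.split()
        out.append((parts[0], np.array([float(p) for p in parts[1:4]])))
    if len(out) != n:
        raise ValueError(f"xyz declares {n} atoms but has {len(out)} rows")
    return out


def read_xyz_frames(text: str) -> list[list[tuple[str, np.ndarray]]]:
    """Parse a multi-frame xyz file."""
    lines = text.strip().splitlines()
    frames = []
    i = 0
    while i < len(lines):
        n = int(lines[i])
        frames.append(read_xyz("\n".join(lines[i:i + n + 2])))
        i += n + 2
    return frames


def model_to_frames(model: ClusterModel) -> tuple[list[str], np.ndarray]:
    elements = [m.atom.element.capitalize() for m in model.atoms]
    coords = np.array([m.atom.coords for m in model.atoms])
    return elements, coords


def write_qm_input(model: ClusterModel, spec: QMJobSpec | None = None) -> str:
    """Gaussian-style input with freeze codes and per-element basis blocks."""
    spec = spec or QMJobSpec()
    elements_present = []
    for m in model.atoms:
        el = m.atom.element.capitalize()
        if el not in elements_present:
            elements_present.append(el)
    missing = [el for el in elements_present if el not in spec.basis_map]
    if missing:
        raise ValueError(f"no basis set assigned for element(s): {', '.join(missing)}")

    buf = io.StringIO()
    buf.write(f"%chk={model.name}.chk\n")
    buf.write(spec.route + "\n\n")
    buf.write(f"{model.name}\n\n")
    buf.write(f"{model.total_charge} {model.multiplicity}\n")
    for m in model.atoms:
        code = -1 if m.frozen else 0
        x, y, z = m.atom.coords
        buf.write(f"{m.atom.element.capitalize():<2s} {code:2d} "
                  f"{x:14.6f} {y:14.6f} {z:14.6f}\n")
    buf.write("\n")
    # per-element basis blocks, grouped by basis name in element order
    by_basis: dict[str, list[str]] = {}
    for el in elements_present:
        by_basis.setdefault(spec.basis_map[el], []).append(el)
    for basis, els in by_basis.items():
        buf.write(" ".join(els) + " 0\n")
        buf.write(basis + "\n")
        buf.write("****\n")
    buf.write(f"\neps={spec.dielectric}\nalpha={spec.electrostatic_scaling}\n")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Energy ledgers

def _parse_composition(text: str) -> int:
    """'model' → 0 extra waters; 'model+1w' → 1; 'model+2w' → 2."""
    t = str(text).strip().lower()
    if t in ("model", "", "nan"):
        return 0
    if t.startswith("model+") and t.endswith("w"):
        return int(t[len("model+"):-1])
    raise ValueError(f"unrecognized composition {text!r}")


def read_energy_ledger(text: str) -> EnergyLedger:
    """Parse a CSV/TSV ledger: state_label, G_value, unit, composition.

    A row whose state_label is ``water`` supplies the isolated-water
    reference energy.  State labels are validated; duplicate states and
    unknown units are errors.
    """
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(io.StringIO(text), sep=sep, comment="#",
                     skipinitialspace=True)
    required = {"state_label", "G_value", "unit"}
    if not required <= set(df.columns):
        raise ValueError(f"ledger must have columns {sorted(required)}")
    ledger = EnergyLedger()
    for i, row in df.iterrows():
        label = str(row["state_label"]).strip()
        value = float(row["G_value"])
        unit = str(row["unit"]).strip()
        comp = _parse_composition(row.get("composition", "model"))
        if label.lower() in ("water", "h2o"):
            if ledger.water_G is not None:
                raise ValueError("duplicate water reference row")
            ledger.water_G = value
            ledger.water_unit = unit
            continue
        try:
            parse_state_label(label)
            ledger.add(label, value, unit=unit, extra_waters=comp)
        except ValueError as exc:
            raise ValueError(f"ledger row {i + 1}: {exc}") from None
    return ledger


def write_energy_ledger(ledger: EnergyLedger) -> str:
    lines = ["state_label,G_value,unit,composition"]
    for label, e in ledger.entries.items():
        comp = "model" if e.extra_waters == 0 else f"model+{e.extra_waters}w"
        lines.append(f"{label},{e.G},{e.unit},{comp}")
    if ledger.water_G is not None:
        lines.append(f"water,{ledger.water_G},{ledger.water_unit},model")
    return "\n".join(lines) + "\n"
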