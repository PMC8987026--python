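"""Eyring rate↔barrier conversion and mechanism free-energy diagrams.

Transition-state theory with unit transmission coefficient:

    k = (kB·T / h) · exp(−ΔG‡ / (R·T))   ⇔   ΔG‡ = R·T · ln(kB·T / (h·k))

Rates may be given in s⁻¹ or min⁻¹.  Diagram assembly implements the
two-step retaining glycoside hydrolase mechanism: glycosylation
(R1 → TS1 → P1) and, after adding one explicit water, deglycosylation
(R2 → TS2 → P2).  All states are placed on a common composition (model +
one water), so a state whose recorded composition lacks the extra water is
shifted by the reference free energy of an isolated water molecule.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

from .constants import CONSTANTS

_RATE_UNITS = {"1/s": 1.0, "s-1": 1.0, "s^-1": 1.0, "per_s": 1.0,
               "1/min": 1.0 / 60.0, "min-1": 1.0 / 60.0, "min^-1": 1.0 / 60.0}

_ENERGY_UNITS = {"kcal/mol": 1.0, "kcal_mol": 1.0,
                 "hartree": CONSTANTS.hartree_to_kcal, "au": CONSTANTS.hartree_to_kcal}


def _rate_to_per_second(k: float, unit: str) -> float:
    try:
        return k * _RATE_UNITS[unit.lower()]
    except KeyError:
        raise ValueError(f"unrecognized rate unit {unit!r}; use 1/s or 1/min") from None


@dataclass(frozen=True)
class RateMeasurement:
    k: float
    unit: str = "1/s"
    T: float = 310.0
    uncertainty: float | None = None

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("rate constant must be positive")
        if self.T <= 0:
            raise ValueError("temperature must be positive")
        _rate_to_per_second(1.0, self.unit)

    @property
    def k_per_second(self) -> float:
        return _rate_to_per_second(self.k, self.unit)


@dataclass(frozen=True)
class BarrierEstimate:
    dG: float                     # kcal mol⁻¹
    T: float
    range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.dG):
            raise ValueError("dG must be finite")
        if self.T <= 0:
            raise ValueError("temperature must be positive")
        if self.range is not None and self.range[0] > self.range[1]:
            raise ValueError("range must be ordered (low, high)")


def eyring_barrier(m: RateMeasurement) -> BarrierEstimate:
    """Activation free energy from a rate constant, ΔG‡ = RT·ln(kB·T/(h·k)).

    A rate uncertainty propagates to a barrier range: the faster rate
    (k + σ) gives the lower barrier.
    """
    c = CONSTANTS

    def dg(k_s: float) -> float:
        return c.R * m.T * math.log(c.kB * m.T / (c.h * k_s))

    center = dg(m.k_per_second)
    rng = None
    if m.uncertainty is not None:
        hi_rate = _rate_to_per_second(m.k + m.uncertainty, m.unit)
        lo_rate = _rate_to_per_second(m.k - m.uncertainty, m.unit)
        if lo_rate <= 0:
            raise ValueError("uncertainty exceeds the rate constant")
        rng = (dg(hi_rate), dg(lo_rate))
    return BarrierEstimate(dG=center, T=m.T, range=rng)


def eyring_rate(b: BarrierEstimate, unit: str = "1/s") -> RateMeasurement:
    """Inverse transform: k = (kB·T/h)·exp(−ΔG‡/(R·T))."""
    c = CONSTANTS
    k_s = (c.kB * b.T / c.h) * math.exp(-b.dG / (c.R * b.T))
    return RateMeasurement(k=k_s / _RATE_UNITS[unit.lower()], unit=unit, T=b.T)


# ---------------------------------------------------------------------------
# Mechanism state labels (ResV-W(X)-YZ)

_LABEL_RE = re.compile(
    r"^Res(?P<n>\d+)-(?P<variant>[EQ])(?P<conf>[A-C]?)-(?P<role>R|TS|INT|P)(?P<step>[12])$",
    re.IGNORECASE)


@dataclass(frozen=True)
class StateLabel:
    """Parsed mechanism-state label, e.g. Res16-EA-R1 or Res23-Q-TS2.

    n_residues: model size; variant: E (wild-type Glu217) or Q (E217Q
    mutant); conformer: A/B/C or None; role: R/TS/Int/P; step: 1
    (glycosylation) or 2 (deglycosylation).
    """

    n_residues: int
    variant: str
    conformer: str | None
    role: str
    step: int

    def __str__(self) -> str:
        return (f"Res{self.n_residues}-{self.variant}{self.conformer or ''}"
                f"-{self.role}{self.step}")

    @property
    def model(self) -> str:
        return f"Res{self.n_residues}-{self.variant}{self.conformer or ''}"


def parse_state_label(text: str) -> StateLabel:
    m = _LABEL_RE.match(text.strip())
    if not m:
        raise ValueError(f"malformed state label {text!r} "
                         "(expected ResV-W(X)-YZ, e.g. Res16-EA-R1)")
    role = m.group("role").upper()
    return StateLabel(
        n_residues=int(m.group("n")),
        variant=m.group("variant").upper(),
        conformer=m.group("conf").upper() or None,
        role="Int" if role == "INT" else role,
        step=int(m.group("step")),
    )


# ---------------------------------------------------------------------------
# Energy ledgers and diagrams

@dataclass
class LedgerEntry:
    G: float          # in `unit`
    unit: str = "kcal/mol"
    extra_waters: int = 0  # explicit waters beyond the reference composition

    @property
    def G_kcal(self) -> float:
        try:
            return self.G * _ENERGY_UNITS[self.unit.lower()]
        except KeyError:
            raise ValueError(f"unrecognized energy unit {self.unit!r}") from None


@dataclass
class EnergyLedger:
    """State label → free energy, with composition bookkeeping.

    ``water_G`` is the reference free energy of one isolated water in the
    same unit system (required whenever entries differ in extra_waters).
    """

    entries: dict[str, LedgerEntry] = field(default_factory=dict)
    water_G: float | None = None
    water_unit: str = "kcal/mol"

    def add(self, label: str, G: float, unit: str = "kcal/mol",
            extra_waters: int = 0) -> None:
        parse_state_label(label)  # validates
        if label in self.entries:
            raise ValueError(f"duplicate state {label}")
        self.entries[label] = LedgerEntry(G=G, unit=unit, extra_waters=extra_waters)

    @property
    def water_G_kcal(self) -> float | None:
        if self.water_G is None:
            return None
        return self.water_G * _ENERGY_UNITS[self.water_unit.lower()]


@dataclass
class DiagramState:
    label: StateLabel
    rel_G: float  # kcal mol⁻¹ vs the R1 reference (plus water, if balanced)


@dataclass
class MechanismDiagram:
    """Water-balanced relative free energies for one model/conformer."""

    model: str
    states: list[DiagramState]

    def rel(self, role: str, step: int) -> float:
        for s in self.states:
            if s.label.role == role and s.label.step == step:
                return s.rel_G
        raise KeyError(f"{self.model} has no state {role}{step}")

    def has(self, role: str, step: int) -> bool:
        return any(s.label.role == role and s.label.step == step
                   for s in self.states)

    @property
    def steps(self) -> set[int]:
        return {s.label.step for s in self.states if s.label.role == "TS"}

    def overall_barrier(self, step: int) -> float:
        """TS free energy relative to the common R1(+water) reference."""
        return self.rel("TS", step)

    def elementary_barrier(self, step: int) -> float:
        return self.rel("TS", step) - self.rel("R", step)

    @property
    def rate_limiting(self) -> StateLabel:
        ts = [s for s in self.states if s.label.role == "TS"]
        if not ts:
            raise ValueError(f"{self.model} has no transition states")
        return max(ts, key=lambda s: s.rel_G).label


_ROLE_ORDER = {("R", 1): 0, ("TS", 1): 1, ("Int", 1): 2, ("P", 1): 3,
               ("R", 2): 4, ("TS", 2): 5, ("Int", 2): 6, ("P", 2): 7}


def assemble_diagram(ledger: EnergyLedger,
                     conformers: set[str | None] | None = None) -> dict[str, MechanismDiagram]:
    """Build one diagram per model/conformer present in the ledger.

    Every state's relative G is measured against its model's R1 on the
    common composition; states carrying extra explicit waters are
    referenced to G(R1) + n·G(H₂O).  Raises if compositions differ and no
    water reference energy is available, or if a model lacks R1.
    """
    groups: dict[str, dict[StateLabel, LedgerEntry]] = {}
    for text, entry in ledger.entries.items():
        lab = parse_state_label(text)
        if conformers is not None and lab.conformer not in conformers:
            continue
        groups.setdefault(lab.model, {})[lab] = entry
    if not groups:
        raise ValueError("ledger contains no matching states")

    diagrams: dict[str, MechanismDiagram] = {}
    for model, entries in groups.items():
        r1 = [(l, e) for l, e in entries.items() if l.role == "R" and l.step == 1]
        if not r1:
            raise ValueError(f"model {model} has no glycosylation reactant (R1)")
        ref_label, ref_entry = r1[0]
        ref_G = ref_entry.G_kcal
        ref_waters = ref_entry.extra_waters
        states = []
        for lab, e in sorted(entries.items(),
                             key=lambda kv: _ROLE_ORDER.get((kv[0].role, kv[0].step), 99)):
            dw = e.extra_waters - ref_waters
            if dw != 0:
                if ledger.water_G_kcal is None:
                    raise ValueError(
                        f"state {lab} and {ref_label} differ in composition by "
                        f"{dw} water(s) but the ledger has no water reference energy")
                shift = dw * ledger.water_G_kcal
            else:
                shift = 0.0
            states.append(DiagramState(label=lab, rel_G=e.G_kcal - ref_G - shift))
        diagrams[model] = MechanismDiagram(model=model, states=states)
    return diagrams


@dataclass
class VariantComparison:
    step: int
    barriers: dict[str, float]   # variant -> overall barrier, kcal mol⁻¹
    faster: str                  # variant with the lower barrier
    difference: float            # |ΔΔG‡|, kcal mol⁻¹


def compare_variants(diagrams: dict[str, MechanismDiagram]) -> list[VariantComparison]:
    """Per-step comparison of overall barriers across E/Q variants.

    ``diagrams`` maps a variant tag (e.g. 'E', 'Q') to its diagram; steps
    must overlap between the variants being compared.
    """
    if len(diagrams) < 2:
        raise ValueError("need at least two variants to compare")
    step_sets = [d.steps for d in diagrams.values()]
    common = set.intersection(*step_sets)
    if not common:
        raise ValueError("variants share no mechanism steps")
    out = []
    for step in sorted(common):
        barriers = {v: d.overall_barrier(step) for v, d in diagrams.items()}
        faster = min(barriers, key=lambda v: barriers[v])
        slowest = max(barriers.values())
        out.append(VariantComparison(step=step, barriers=barriers, faster=faster,
                                     difference=slowest - barriers[faster]))
    return out
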