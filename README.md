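# rincluster

Tools for building and analyzing **QM-cluster models** of enzyme active
sites, written around the two-step retaining mechanism of glycoside
hydrolases (GH7 cellobiohydrolases and their point mutants).

Quantum-cluster modelling treats a few hundred active-site atoms with
quantum chemistry and replaces the rest of the protein with two boundary
devices: hydrogen caps on severed bonds and frozen Cα/Cβ atoms that mimic
the scaffold. The hard part is deciding *which* residues belong in the
model. `rincluster` automates that decision with a **residue interaction
network (RIN)**: every fragment (residue, glycosyl unit, water) becomes a
node, and edge weights are **contact-dot counts** — the number of points on
one fragment's van der Waals surface lying within a small gap (default
0.5 Å) of the other's, in the spirit of the Richardson small-probe method.
Residues are ranked by their dot count with a chosen *seed* (here the −1/+1
glucosyl units flanking the scissile glycosidic bond) and selected either
above a count threshold or maximally (every nonzero contact).

The package covers the full workflow around that idea:

* **`structure`** — PDB I/O (via gemmi), altloc resolution, fragment
  typing, glycan-chain truncation with hydroxyl capping of severed
  glycosidic links;
* **`hydrogens`** — deterministic template-based hydrogen addition and
  protonation-state assignment (doubly protonated His, neutral Asp/Glu,
  cationic "protonated Gln" mimicking a protonated Glu), with a
  bond-perception valence audit;
* **`contacts`** — the contact-dot surrogate (Fibonacci surface lattices,
  occlusion, gap counting), RIN construction, threshold/maximal selection,
  and bridging of single-residue chain gaps;
* **`cluster`** — trimming (side chain + Cα), hydrogen capping along the
  original bond vectors, frozen-atom flags, charge bookkeeping, and
  packaged trimming schemes for the six published GH7 models
  (Res16-E … Res23-Q);
* **`pucker`** — Cremer–Pople puckering coordinates (Q, θ, φ) for
  six-membered sugar rings and IUPAC conformer labels (⁴C₁, ⁴H₃, ⁴E,
  B₂,₅, …) over the full 38-vertex canonical table, with ring order
  **O5, C1, …, C5** so the ⁴C₁ chair sits at θ ≈ 0°;
* **`energetics`** — Eyring conversion k ↔ ΔG‡
  (ΔG‡ = RT·ln(k_B·T/(h·k)), transmission coefficient 1) and assembly of
  composition-balanced free-energy diagrams for the glycosylation /
  deglycosylation steps, including the explicit-water bookkeeping that
  connects the two steps;
* **`qmio`** — byte-deterministic xyz and Gaussian-compatible input
  writers (freeze codes, per-element basis blocks: 6-31G(d′) on N/O/S,
  6-31G on C/H) and energy-ledger parsing;
* **`fixtures`** — synthetic active sites built from idealized
  internal-coordinate residue templates, so the whole pipeline is testable
  offline with no structure downloads.

## Worked example

```python
import rincluster as rc
from rincluster import fixtures as fx

# a synthetic active site: disaccharide ligand + Glu/Asp/His shell + water
pdb = fx.make_synthetic_site(fx.SiteSpec(
    ligand="disaccharide",
    shell=[fx.ShellResidue("GLU", 3.2, (0, 1, 0), 212),
           fx.ShellResidue("ASP", 3.8, (0, -1, 0), 214),
           fx.ShellResidue("HIS", 12.0, (0, 0, 1), 228)],
    waters=[(2.8, (1, 0, 0))], rng_seed=7))

site = rc.add_hydrogens(rc.read_pdb(pdb))
net = rc.build_rin(site, {"X:1", "X:2"})          # seed: the two sugar units
for key in net.nodes:
    if key not in net.seed:
        print(key, net.seed_contact(key))
```

prints the seed-contact ranking (the 12 Å histidine is out of contact
range and does not appear):

```
('A', 212) 191
('A', 214) 37
('W', 901) 125
```

Converting the wild-type turnover number to a barrier, and assembling the
published free-energy diagram from the packaged ledger:

```python
b = rc.eyring_barrier(rc.RateMeasurement(k=12.8, unit="1/min", T=310.0))
print(f"{b.dG:.2f}")                      # 19.12 kcal/mol

d = rc.assemble_diagram(fx.packaged_ledger())["Res21-E"]
print(d.overall_barrier(1), round(d.elementary_barrier(2), 1))   # 19.5 1.9
print(d.rate_limiting)                    # Res21-E-TS1
```

A command-line interface mirrors the library
(`rincluster prep | rin | build | pucker | eyring | diagram`); try
`rincluster eyring --k 12.8 --k-unit 1/min -T 37 --celsius`.

## Scope

The package writes QM inputs and ingests resulting energies; it does not
run electronic-structure calculations. Contact-dot counts are a
deterministic surrogate whose absolute values differ from the original
small-probe implementation; the selection threshold is exposed as a
parameter for calibration. See `docs/methods.md` for models, conventions
and limitations.
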