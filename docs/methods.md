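# Methods

This note records the models, conventions and numerical choices behind
`rincluster`, and what the test suite does and does not establish.

## Structures and protonation

PDB parsing goes through gemmi; one model is read, fragments are
partitioned by (chain, residue number, residue name), and alternate
locations are resolved either by a named label (default "A") or by
highest occupancy. Peptide and glycosidic connectivity is perceived
geometrically: two atoms are bonded when their distance is at most 1.3 ×
the sum of their Cordero covalent radii. The 1.3 factor accepts stretched
bonds while excluding nonbonded contacts (shortest heavy-atom nonbonded
approaches are ≈ 2.4 Å).

Hydrogens are placed at idealized internal coordinates (C–H 1.09 Å, N–H
1.01 Å, O–H 0.96 Å; tetrahedral or trigonal angles from the heavy-atom
coordination), with rotational freedom (hydroxyl dihedrals, methyl
staggering) fixed deterministically by a second-shell reference atom.
Expected hydrogen counts come from per-residue templates for the twenty
amino acids plus a generic valence rule (C 4, N 3, O 2, S 2 minus heavy
neighbors) for sugars, waters and other fragments; an element with no
rule is an error. This is a deliberate simplification relative to
dedicated protonation tools: there is no flip optimization of Asn/Gln/His
orientations and no pKa prediction. Default states assume a mildly acidic
medium (pH ≈ 6): Asp/Glu ionized, Lys/Arg protonated, His neutral at Nε.
Catalytic exceptions are expressed as overrides: `doubly_protonated` His
(+1), `neutral` Asp/Glu (carboxylic acid), and `protonated` Gln (+1, a
third proton on Nε2), the mimic used when a catalytic Glu is mutated to
Gln.

Glycan chains are truncated by subsite position. Positions increase
toward the reducing end and skip zero; each glycosidic link is stored as
(donor C1, acceptor O4). At a severed link with exactly one side kept,
the generic rule is: if the bridging O4 belongs to the removed unit it is
retained (reassigned to the kept fragment) and capped with H toward its
severed C4; if it belongs to the kept unit it simply receives one H along
the old C1 direction. Both published truncation behaviors (keeping only
the bridging oxygen of a deleted terminal unit; protonating the freed O4
of a kept unit) are instances of this rule. Retained experimental
coordinates are never moved.

## Contact dots and residue interaction networks

The interaction statistic is a deterministic surrogate for small-probe
contact-dot counting. Each atom's van der Waals sphere (Bondi radii,
H = 1.10 Å) carries a Fibonacci lattice of round(4πr²ρ) points at density
ρ = 16 Å⁻²; dots on or inside any neighbor sphere are buried; a surviving
dot on fragment A counts when the gap to the nearest atom surface of
fragment B is at most max_gap = 2 × probe radius = 0.5 Å. Counts are
symmetrized (A→B plus B→A). Occlusion is evaluated within the union of
the two fragments, which keeps the count a pure function of the pair.

The lattice is anchored in a per-atom local frame built from the
directions to the two nearest neighboring atoms (distances rounded to
10⁻⁶ Å for a stable ordering, serials breaking ties), so counts are
exactly invariant under rigid motion of the structure; isolated atoms
fall back to the global axes. Counts *rise* as two fragments approach
until their surfaces interpenetrate (burial then removes dots), so
monotonicity with separation holds in the separated regime — the property
tests sample distance ladders beyond surface contact.

Absolute counts are not comparable to the original probe program (whose
flags and dot chemistry differ); the ">50" selection threshold is
therefore a parameter, not a constant. Selection is deterministic:
descending seed-contact count, ties by ascending residue number;
`maximal` keeps every nonzero count. Bridging adds the intervening
residue wherever two chosen residues sit exactly two apart on a chain.
The packaged study schemes additionally contain bridging rows that
extend contiguous chain blocks; those rows are transcription, not output
of the gap rule.

## Cluster assembly

Trim rules are `sidechain_Calpha` (side chain + Cα + Hα; the backbone
N/C(=O) are severed), `backbone_only`, and `whole_fragment`. Severed
bonds — including peptide and glycosidic bonds to fragments outside the
model — are found on the full structure's bond graph, and each open
valence is capped with hydrogen along the original bond vector at the
standard X–H length (link-H convention). Two caps closer than 0.8 Å
abort the build. Frozen flags are restricted to Cα/Cβ and are metadata
until the QM input writer emits them as freeze codes (−1 in the
coordinate block; the engine zeroes Hessian elements involving frozen
coordinates). Model charge is the sum of included fragment formal
charges; multiplicity is fixed at 1 (all models closed-shell).

The six packaged schemes transcribe the published per-residue table
row-for-row (retain mode, frozen marks, charge, bridging italics). Two
arithmetic conflicts inside that table are preserved rather than
resolved: the Res16-Q column's rows sum to +1 and the Res21-E column's
rows (which include bridging Asp257 at −1) sum to −1, while both column
headers print 0. The code always reports the recomputed row sums. The
Res20-Q frozen counts follow the table (17 Cα / 12 Cβ), not the prose
variant.

## Ring puckering

Cremer–Pople coordinates for N = 6: out-of-plane displacements z_j from
the centroid-anchored mean plane give q₂, φ₂ (m = 2 Fourier pair), q₃
(alternating sum), Q = √(q₂²+q₃²), θ = atan2(q₂, q₃). Ring atoms are
ordered **O5, C1 … C5**; with the standard mean-plane normal this places
⁴C₁ at θ ≈ 0° and ¹C₄ at 180°. Labels flip with the ordering convention,
so the order is part of the API contract. The 38 canonical conformers are
generated at import from their defining up/down patterns (chairs: full
alternation; boats: para pair; skews: the six canonical meta pairs;
envelopes: single atom; half-chairs: adjacent pair, both orientations)
and classification is nearest-vertex by great-circle distance on (θ, φ),
with the distance reported so near-ties (e.g. ⁴E vs ⁴H₃) are visible.
Q < 0.1 Å is labeled "planar" (the convention is ours; the threshold is
far below typical pyranose amplitudes of ~0.5–0.6 Å). Useful exact
transformations, verified by the property tests: cyclic re-indexing by
one position maps (θ, φ) → (180°−θ, φ+120°); ring inversion maps
(θ, φ) → (180°−θ, φ+180°); their composition fixes θ and shifts φ by 60°.

## Energetics

Eyring with transmission coefficient 1 and CODATA-2018 constants;
R is carried in kcal mol⁻¹ K⁻¹ so barriers are in kcal mol⁻¹ directly.
Rate uncertainties map to barrier ranges ((k+σ) → lower edge). The
default replication temperature is 310 K — the thermochemistry
temperature that reproduces the published conversion bands; 310.15 K
does not, at the printed precision. Hartree→kcal mol⁻¹ is pinned at
627.5094740631.

Diagrams use the state labels ResV-W(X)-YZ (V residues; W = E wild-type /
Q mutant; X conformer; Y role R/TS/Int/P; Z step 1 = glycosylation,
2 = deglycosylation). One explicit water joins the model between P1 and
R2, so every state is referenced to G(R1) plus, when its composition
carries the extra water, G(isolated H₂O); the ledger's composition column
(`model`, `model+1w`) makes the convention explicit and mixing units
(hartree / kcal mol⁻¹) is allowed per entry. Overall step-2 barrier is
G_rel(TS2); elementary is G(TS2) − G(R2); `rate_limiting` is the argmax
over TS states. Note that with the published energies the small
wild-type model's deglycosylation TS (23.9) lies above its TS1 (15.5):
"glycosylation rate-limiting" is a statement about elementary barriers
(15.5 > 14.1 and 19.5 > 1.9), and the tests phrase it that way.

The packaged ledger encodes the published relative free energies as
absolute pseudo-Hartree values with a water reference, so assembling it
exercises unit conversion and composition balancing end to end; the
recovered numbers (e.g. wild-type maximal model: TS1 19.5; TS2 overall
13.9 = 12.0 + 1.9, vs the published rounded 13.8) are computed, not
stored, in kcal mol⁻¹.

## Synthetic fixtures

Fixture sites are idealized constructions: amino-acid templates built
from internal coordinates (NeRF placement; extended backbone φ = −139°,
ψ = 135°, ω = 180°; template set GLY/ALA/SER/THR/LEU/ASP/GLU/GLN/HIS/ARG),
simplified glucosyl units (chair-puckered ring + bridging O4 only), and
shell residues positioned so their closest heavy-atom approach to the
ligand matches a requested distance along a requested direction, with a
seed-controlled spin about that axis. Generation is byte-deterministic
per seed; placements closer than 2.0 Å between fragments are rejected.
The default contact ladder (3.2 / 3.8 / 12 Å) yields a strict ranking
with the far residue at zero dots; at 5 Å closest approach the surrogate
(like real small-probe contacts) already counts zero. These fixtures
emulate contact ranking, trimming, capping and charge bookkeeping — not
real active-site geometry, crystallographic disorder, or the energetics
of any specific enzyme — so green tests certify the machinery, not
agreement with experiment on downloaded structures.

## Problem sizes and limitations

The shipped tests and the acceptance script run on fixture-scale inputs
(single-ring or two-ring ligands, 3–6 fragment sites, ≈ 60–90 atoms per
assembled model) — sizes chosen so the full pipeline, not sampled parts
of it, is exercised on every run. DFT optimizations, transition-state
searches and frequency analyses on few-hundred-atom cluster models are
out of scope by design: the package writes the inputs and consumes the
resulting energies through ledgers. Reproducing the original probe dot
counts bit-for-bit is likewise out of scope; network construction on
deposited structures is supported but requires the user to supply the
PDB files.
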