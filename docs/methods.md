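# Methods

This note documents the models, conventions and numerical choices behind
glycurate, and what the synthetic-fixture tests do and do not demonstrate.

## Structure model

Residues are identified by the author triple (chain, seq_num, insertion
code), matching LINK-record semantics. Only the highest-occupancy alternate
conformer of each atom is kept (ties: first in file); hydrogens are retained
on read but excluded from every geometry and density computation, since
deposited carbohydrate models are almost always hydrogen-free. Symmetry
operators come from the recorded space group when gemmi can resolve it,
otherwise only the identity is present; `min_symmetry_distance` enumerates
all operators times lattice translations in {−1,0,1}³, which is exact for
any contact shorter than one cell edge. A "flat-B" model is detected when
all atomic B values agree to 10⁻³ Å².

## Ring puckering and the three-tier status

Cremer–Pople parameters use the canonical O5, C1…C5 atom order. The
mean-plane normal is oriented so that the ideal ⁴C₁ chair (alternating
displacements, +z at O5) gives θ = 0 exactly; the inverted chair gives
θ = 180. L-sugars (FUC, FUL) prefer ¹C₄ in this atom order, so their
expected θ is near 180; the status logic mirrors every θ window around 180
for them.

The three-tier status is an *emulation* of the yes/check/no decision surface
the pipeline consumes, not a clone of any external validator:

* `yes` — complete ring, θ ≤ 30° from the expected pole, geometric anomer
  matching the component code;
* `check` — only the chair test fails, softly (30° < θ < 45°);
* `no` — anything else (incomplete ring, undefined pucker, boat/skew
  region, anomer mismatch).

The 30°/45° windows are this package's convention, chosen so that ideal
chairs and the small θ values typical of well-built sugars are deep inside
`yes` while boats (θ ≈ 90°) are unambiguously `no`. Acceptance tests avoid
the window boundaries.

The geometric anomer at C1 is read as the cis/trans relation, across the
ring mean plane, between the C1 substituent (glycosidic O/N, or O1) and the
C5→C6 bond: same side = β, opposite = α. This formulation is valid for both
D- and L-sugars because both projections flip together under mirroring.
Residues without a C6 (xylose) fall back to the declared anomer.

## Monosaccharide templates

Templates are generated analytically at import time from an ideal chair
(ring bond 1.52 Å, out-of-plane amplitude 0.25 Å) plus tetrahedral
axial/equatorial substituents encoding each sugar's stereochemistry (axial
O2 for mannose, axial O4 for galactose/fucose, anomeric O1 axial for α in
the ⁴C₁ D-frame, etc.). L-fucoses are mirror images of the corresponding
6-deoxy-D-galactose frames, which inverts every center and the chair
simultaneously. Every template satisfies ring closure and validates `yes`;
the O1 pseudo-atom only defines the attachment direction and is stripped on
placement. Generating templates in code (rather than shipping coordinate
files) keeps them exactly consistent with the validation conventions above.

## Tree grammars

The five standard tree types are explicit finite trees over a shared
five-residue core, stored in `data/tree_types.json`. The beyond-core
productions (mannose arms; NAG/GAL antennae; bisecting NAG; β1–2 xylose on
the core BMA; core fucose α1–6 for mammal types and α1–3 for plant types)
follow the trees used by the interactive carbohydrate-building tools this
module emulates; the encoding is data, so it can be audited or extended
without touching code. The default building type is high-mannose with both
fucose productions enabled; when an existing tree extends beyond the core,
the type covering the most beyond-core residues wins, with ties broken
high-mannose → mammal → plant (a stated convention — no external source
prescribes the tie order).

Chain breaks (sequence gaps or C–N > 2.5 Å) suppress sequon detection,
since building at a broken sequon tends to place sugars into main-chain
density.

## Density engine

Model maps are sums of per-atom Gaussians from the IT92 four-Gaussian X-ray
form factors, B-smeared and occupancy-weighted, accumulated on a periodic
grid (per-axis margins derived from reciprocal row norms, so triclinic
cells are handled); the constant form-factor term is smeared by max(B, 2 Å²)
to avoid a grid-scale spike. Band-limiting to d_min zeroes all spatial
frequencies beyond 1/d_min via FFT. Point probes use tri-linear periodic
interpolation.

RSCC is the plain Pearson correlation of observed and calculated maps over
grid points within 2.0 Å of any residue atom. EDIA support for an atom uses
a density radius computed on the fly from resolution and B,
r = clamp(0.7 + 0.25·d_min + 0.008·B, 0.9, 3.0) Å — an adopted linear
profile, recorded here as the package's constant. Within r the capped
density (saturating at +1.2σ) counts with quadratic distance weight; in the
shell out to 1.25·r only *negative* density is penalized (weight 0.2), so an
atom is punished for difference-density holes next to it but not for its own
density tail; grid points nearer to a competing atom are not counted. EDIA
is floored at 0. EDIAm is the power mean with exponent −2 (floored at 0.01
per atom and capped at the best single atom), which makes one unsupported
atom dominate the residue score. The density ratio divides the mean observed
density at the residue's atoms by that at protein main-chain atoms
(N, CA, C, O).

Scoring always recomputes the model map with every carbohydrate B set to
30.0 Å², making all three scores independent of the incoming B values;
this compensates for the absence of B refinement and ensures good scores
require density at healthy contour levels. Reflection-data handling,
bulk-solvent correction, anisotropic scaling and electron scattering
factors are out of scope: the engine is purely real-space, and observed
maps come either from a CCP4/MRC file or from the fixture generator.

## Builder

A child residue is attached by placing its C1 at 1.43 Å from the parent
attachment atom (O2/O3/O4/O6, or Nδ2 for the root) with a 116° bond angle,
then enumerating glycosidic torsions: φ ∈ {±70°, ±90°} on the exo-anomeric
side of the child's anomer, ψ over six 60°-spaced values, followed by a
±20° local grid refinement (10° steps) of the best candidate. The fit is
the mean σ-level at the placed atoms; acceptance needs fit ≥ 0.6σ and no
contact under 2.1 Å with any atom other than the parent's attachment
oxygen. The 0.6σ gate is deliberately permissive — the pipeline's density
filters are the real arbiter. Tree extension walks open grammar slots
breadth-first in a fixed order (core positions first, position 4 before 3
before 6, fucoses last), each slot attempted once, so identical inputs give
identical trees.

## Pipeline bookkeeping

"Asparagines of interest" are sequon Asns that do not root a surviving tree
and are not blocked by a chitobiose (CBS) link. Existing trees are extended
before new trees are added, which reduces the risk of building a tree at
the wrong one of two adjacent asparagines. Every residue removed along the
way is either restored (old tree preferred, graft, or non-clashing parked
molecule) or reported as permanently deleted; the tests assert this
conservation and that a second pipeline pass on its own output is a no-op.
New residues are numbered from 401 upward per chain; when a restored
molecule reclaims a number, the new residue is renumbered *before*
restoration so link records stay unambiguous. On flat-B models, built
carbohydrates inherit the flat B value. For grafting, the old child's C1 is
tested against the rebuilt parent's attachment-oxygen position (< 2.5 Å),
and the covalent C1–O pair being formed is exempt from the 2.0 Å clash
test.

## Synthetic fixtures and what the tests show

`make_glycosite` builds an idealized extended peptide (fixed backbone
geometry; no Ramachandran realism claimed) carrying Ala-Gly-Asn-Gly-Thr-
Ala-Gly, attaches an ideal tree using the same templates as the builder,
and synthesizes the observed map at the requested resolution in a P1 box
with an 8 Å solvent margin (protein B = 20 Å², sugar B = 30 Å²). Noise is
white Gaussian on the σ-normalized grid; real crystallographic noise is
correlated, but white noise suffices to exercise the thresholds. Default
study conditions for the recovery experiments: core-5 high-mannose tree,
2.0 Å map at resolution/4 grid spacing, noise 0.1σ; the degraded condition
is 3.5 Å and 0.3σ. Twenty seeded fixtures keep the whole acceptance suite
under a minute on one CPU.

Because the fixture generator and the builder share the template library
and torsion vocabulary, parameter recovery validates the search, scoring
and filtering machinery — not the realism of the templates against
experimental sugars. Conversely, the link-detection tests are independent
of that machinery: expected outcomes come from hand-constructed geometry
and a brute-force filter evaluator.

## Known limitations

* No real-space refinement of the protein: updating the root asparagine
  reduces to persisting the amide flip.
* Link detection works within the asymmetric unit (a genuine N-glycosidic
  bond is intramolecular); symmetry is used for clash checks, not for link
  search.
* The grammar covers the five standard trees only; no sialylated or
  otherwise extended antennae, no O-glycans, and no free-form linkage mode.
* CBS (chitobiose) sites are skipped, not remediated into two NAGs.
* EDIA here is a documented emulation of the published per-atom support
  score, not a numerical replica of any external implementation.
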