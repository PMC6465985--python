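# glycurate

Automated building, rebuilding and validation of **N-glycosylation trees** in
crystallographic protein structure models.

Carbohydrates are the worst-modeled part of the PDB: they sit in weak,
solvent-exposed density, their covalent links to the protein are frequently
missing from the deposited annotation, and their six-membered rings are often
left in impossible conformations. Yet N-glycans are highly predictable — a
common five-residue core NAG(β1–N)Asn · NAG(β1–4) · BMA(β1–4) ·
[MAN(α1–3) + MAN(α1–6)] shared across eukaryotes, decorated according to a
handful of standard tree types — which makes automated curation tractable.
This package is aimed at structural biologists and model-curation pipelines
who want that curation as a library (or a small CLI) rather than an
interactive session.

## What it does

* **Link detection** — for every NAG/NDG whose anomeric carbon C1 is
  unlinked, find asparagines with Nδ2 within 6 Å, flip the side-chain amide
  when Oδ1 faces the sugar, and apply three filters: the Asn must head an
  Asn-X-Ser/Thr sequon (X ≠ Pro); an Nδ2–C1 distance above 4 Å needs another
  sugar atom within 3.5 Å; and more than one surviving candidate means no
  link at all. On success the LINK record is written, the flip persisted and
  the O1/O1L leaving atom removed.
* **Ring validation** — Cremer–Pople puckering (Q, θ, φ) of each pyranose:
  θ ≈ 0° is the ⁴C₁ chair expected for the D-sugars, θ ≈ 180° the ¹C₄ chair
  expected for L-fucoses. A three-tier status (`yes`/`check`/`no`) combines
  the chair test, ring completeness and the geometric anomeric configuration
  at C1.
* **Density scoring** — model maps synthesized as B-smeared Gaussian atoms
  (IT92 X-ray form factors), band-limited to d_min; per-residue RSCC, per-atom
  EDIA aggregated with a power mean of exponent −2 (EDIAm), and the
  sugar/main-chain density ratio. All carbohydrate B factors are overridden
  with 30 Å² during scoring, so good scores cannot be bought with inflated Bs.
* **Tree building** — template-based placement of idealized monosaccharides
  along the five standard tree grammars (high-mannose, hybrid/complex mammal,
  hybrid/complex plant), enumerating glycosidic (φ, ψ) torsion candidates
  against the map with local refinement.
* **The curation pipeline** — crop `check`/`no`/nonstandard residues (and
  their descendants), temporarily clear blocking waters and stray sugars,
  extend existing trees, add whole trees at free sequon sites, accept new
  residues only if RSCC ≥ 0.70 or RSCC + EDIAm > 1.20 (or the borderline
  ratio rule at better than 3.0 Å), reject symmetry clashes < 2.1 Å, keep
  the better of old and new tree per site (most `yes`, then most `check`,
  then largest, ties to new), graft surviving old branches (< 2.5 Å link,
  no < 2.0 Å clash), and restore whatever does not clash (< 2.5 Å,
  symmetry-aware) with the new build.

Everything is testable offline: the `synth` module generates ground-truth
glycosites, synthetic observed maps and degraded working models.

## Worked example

`examples/04_rebuild_glycan_tree.py` deletes an entire five-residue glycan
tree from a synthetic 2.0 Å structure — leaving only the bare sequon — and
lets the pipeline rebuild it from the map:

```
working model: 7 residues, no carbohydrates
tree type used: high-mannose
built 5 residue(s):
  NAG A401: RSCC=1.000 EDIAm=0.996  rmsd to truth=0.00 A
  NAG A402: RSCC=1.000 EDIAm=0.999  rmsd to truth=0.00 A
  BMA A403: RSCC=0.999 EDIAm=1.000  rmsd to truth=0.00 A
  MAN A404: RSCC=0.999 EDIAm=1.000  rmsd to truth=0.00 A
  MAN A405: RSCC=0.999 EDIAm=1.000  rmsd to truth=0.00 A
```

Each line is one rebuilt sugar: its real-space correlation and EDIAm against
the observed map, and the heavy-atom RMSD to the residue that was deleted —
i.e. the tree was recovered at the true position and every residue passed
both the geometric and the density filters. The other examples demonstrate
ring validation (`01`), link generation on a model with a missing LINK
record and a leftover O1 atom (`02`), and density scoring including a
deliberately displaced residue (`03`).

A thin CLI mirrors the library: `glycurate link`, `validate`, `score`,
`trees`, `redo-glycans` and `fixtures` (see `--help`).

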