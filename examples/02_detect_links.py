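"""Generate a missing asparagine-sugar covalent link record.

The working model here has a modeled NAG at a sequon but no LINK record and
a leftover O1 leaving atom — a common deposition problem that makes
refinement push the sugar away from the asparagine. The detector applies
the sequon, distance and ambiguity filters, persists any amide flip, writes
the link and removes the leaving atom.
"""
from glycurate.links import detect_asn_links
from glycurate.synth import GlycositeSpec, make_glycosite

_, _, working = make_glycosite(
    GlycositeSpec(seed=3, strip_link=True, add_leaving_atom=True))

print(f"links before: {len(working.links)}")
new_links, decisions, fixed = detect_asn_links(working)
for d in decisions:
    extra = " (amide flipped)" if d.flipped else ""
    removed = f", removed {','.join(d.removed_atoms)}" if d.removed_atoms else ""
    print(f"NAG {d.carb[0]}{d.carb[1]}: {d.outcome}{extra}{removed}")
for ln in new_links:
    print(f"new link: {ln.atom_a} -- {ln.atom_b}  ({ln.declared_distance} A)")
print(f"links after: {len(fixed.links)}")
print("the bond is now declared, so refinement will restrain it instead of "
      "pushing the atoms apart")
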