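"""Rebuild a whole N-glycan tree from density alone.

The working model is the ground truth with its entire five-residue glycan
tree deleted — only the bare Asn-X-Thr sequon remains, while the observed
map still contains the tree's density. The curation pipeline detects the
free sequon site, grows the tree template-by-template against the map,
filters each new residue on ring geometry and density fit, and reports
what it kept. Built coordinates are compared with the deleted truth.
"""
import numpy as np

from glycurate.geom import rmsd
from glycurate.pipeline import run_pipeline
from glycurate.synth import GlycositeSpec, make_glycosite

truth, map_obs, working = make_glycosite(
    GlycositeSpec(seed=1, resolution=2.0, noise_sd=0.1, crop="all"))

print(f"working model: {len(working.residues)} residues, no carbohydrates")
curated, report = run_pipeline(working, map_obs)

print(f"tree type used: {report.tree_type}")
print(f"built {len(report.built)} residue(s):")
for key in report.built:
    res = curated.residue(key)
    s = report.scores[key]
    best = None
    for t in truth.residues:
        if t.seq_num >= 401 and t.comp_id == res.comp_id:
            names = [a.name for a in res.atoms if t.atom(a.name) is not None]
            d = rmsd(np.array([res.atom(n).pos for n in names]),
                     np.array([t.atom(n).pos for n in names]))
            best = d if best is None else min(best, d)
    print(f"  {res.comp_id} {key[0]}{key[1]}: RSCC={s.rscc:.3f} "
          f"EDIAm={s.ediam:.3f}  rmsd to truth={best:.2f} A")
print("every kept residue passed ring validation and the density filters; "
      "sub-0.5 A agreement means the tree was recovered at the true position")
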