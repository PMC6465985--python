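{
  "comment": "Standard N-glycosylation tree definitions. All five types share the five-residue core NAG(b1-N)Asn, NAG(b1-4), BMA(b1-4), MAN(a1-3)+MAN(a1-6). Node ids are arbitrary labels; 'parent' refers to another node id; position N is the asparagine ND2 link. Fucose decorations sit on the first NAG: a1-6 (mammal) and a1-3 (plant); the default building type is high-mannose with both fucose productions enabled.",
  "core": [
    {"id": "nag1", "parent": null,   "position": "N", "comp": "NAG", "anomer": "beta"},
    {"id": "nag2", "parent": "nag1", "position": 4,   "comp": "NAG", "anomer": "beta"},
    {"id": "bma3", "parent": "nag2", "position": 4,   "comp": "BMA", "anomer": "beta"},
    {"id": "man3", "parent": "bma3", "position": 3,   "comp": "MAN", "anomer": "alpha"},
    {"id": "man6", "parent": "bma3", "position": 6,   "comp": "MAN", "anomer": "alpha"}
  ],
  "types": {
    "high-mannose": {
      "fucoses": ["fuc6", "fuc3"],
      "nodes": [
        {"id": "m3a",  "parent": "man3", "position": 2, "comp": "MAN", "anomer": "alpha"},
        {"id": "m3b",  "parent": "m3a",  "position": 2, "comp": "MAN", "anomer": "alpha"},
        {"id": "m63",  "parent": "man6", "position": 3, "comp": "MAN", "anomer": "alpha"},
        {"id": "m66",  "parent": "man6", "position": 6, "comp": "MAN", "anomer": "alpha"},
        {"id": "m63a", "parent": "m63",  "position": 2, "comp": "MAN", "anomer": "alpha"},
        {"id": "m66a", "parent": "m66",  "position": 2, "comp": "MAN", "anomer": "alpha"},
        {"id": "fuc6", "parent": "nag1", "position": 6, "comp": "FUC", "anomer": "alpha"},
        {"id": "fuc3", "parent": "nag1", "position": 3, "comp": "FUC", "anomer": "alpha"}
      ]
    },
    "hybrid-mammal": {
      "fucoses": ["fuc6"],
      "nodes": [
        {"id": "gn3",  "parent": "man3", "position": 2, "comp": "NAG", "anomer": "beta"},
        {"id": "gal3", "parent": "gn3",  "position": 4, "comp": "GAL", "anomer": "beta"},
        {"id": "m63",  "parent": "man6", "position": 3, "comp": "MAN", "anomer": "alpha"},
        {"id": "m66",  "parent": "man6", "position": 6, "comp": "MAN", "anomer": "alpha"},
        {"id": "bis",  "parent": "bma3", "position": 4, "comp": "NAG", "anomer": "beta"},
        {"id": "fuc6", "parent": "nag1", "position": 6, "comp": "FUC", "anomer": "alpha"}
      ]
    },
    "complex-mammal": {
      "fucoses": ["fuc6"],
      "nodes": [
        {"id": "gn3",  "parent": "man3", "position": 2, "comp": "NAG", "anomer": "beta"},
        {"id": "gal3", "parent": "gn3",  "position": 4, "comp": "GAL", "anomer": "beta"},
        {"id": "gn6",  "parent": "man6", "position": 2, "comp": "NAG", "anomer": "beta"},
        {"id": "gal6", "parent": "gn6",  "position": 4, "comp": "GAL", "anomer": "beta"},
        {"id": "fuc6", "parent": "nag1", "position": 6, "comp": "FUC", "anomer": "alpha"}
      ]
    },
    "hybrid-plant": {
      "fucoses": ["fuc3"],
      "nodes": [
        {"id": "gn3",  "parent": "man3", "position": 2, "comp": "NAG", "anomer": "beta"},
        {"id": "m63",  "parent": "man6", "position": 3, "comp": "MAN", "anomer": "alpha"},
        {"id": "m66",  "parent": "man6", "position": 6, "comp": "MAN", "anomer": "alpha"},
        {"id": "xyl",  "parent": "bma3", "position": 2, "comp": "XYP", "anomer": "beta"},
        {"id": "fuc3", "parent": "nag1", "position": 3, "comp": "FUC", "anomer": "alpha"}
      ]
    },
    "complex-plant": {
      "fucoses": ["fuc3"],
      "nodes": [
        {"id": "gn3",  "parent": "man3", "position": 2, "comp": "NAG", "anomer": "beta"},
        {"id": "gal3", "parent": "gn3",  "position": 4, "comp": "GAL", "anomer": "beta"},
        {"id": "gn6",  "parent": "man6", "position": 2, "comp": "NAG", "anomer": "beta"},
        {"id": "gal6", "parent": "gn6",  "position": 4, "comp": "GAL", "anomer": "beta"},
        {"id": "xyl",  "parent": "bma3", "position": 2, "comp": "XYP", "anomer": "beta"},
        {"id": "fuc3", "parent": "nag1", "position": 3, "comp": "FUC", "anomer": "alpha"}
      ]
    }
  }
}
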