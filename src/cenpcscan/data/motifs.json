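[
  {
    "id": "vertebrate-cenpc-motif",
    "pattern": "NVRRTKRXRLKPLEYWRGERVBY",
    "note": "23-residue vertebrate CENP-C motif consensus derived from a 25-species alignment; X = any, B = Asx."
  },
  {
    "id": "cenpc-motif-identities",
    "pattern": "RxxRxxxxPLxYWxGERxxY",
    "note": "Identity pattern within the vertebrate CENP-C motif, located within about 100 residues upstream of the cupin domain."
  },
  {
    "id": "cenpc-motif-core",
    "pattern": "RxxxxPxxYW",
    "note": "Core of the CENP-C motif; R, Y and W mutations reduce nucleosome binding."
  },
  {
    "id": "central-region-consensus",
    "pattern": "RxSxxPSxWW",
    "note": "Consensus of the CENP-C central (nucleosome-binding) region."
  },
  {
    "id": "central-region-core",
    "pattern": "RxxxxPxxWW",
    "note": "Functionally important core of the central-region consensus; the pattern found twice in putative fish CENP-C."
  }
]
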