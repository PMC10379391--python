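{
  "_comment": "PALB2 protein-domain intervals on 1-based cDNA (NM_024675.4) coordinates. Boundaries are working values consistent with published per-variant domain annotations of this catalog; they are not an authoritative domain definition.",
  "coiled-coil": [25, 132],
  "ETGE": [199, 282],
  "ChAM": [1183, 1338],
  "WD40": [2557, 3558]
}
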