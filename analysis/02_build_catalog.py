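"""Filter and coordinate-map the raw variant table into the working catalog:
keep Pathogenic/Likely pathogenic (PV) and Benign/Likely benign (BV) single-
nucleotide and 1-bp indel variants, map HGVS cDNA anchors to genomic
coordinates, and log every excluded row with its reason.

Reads results/sim/; writes results/catalog.tsv and results/catalog.exclusions.tsv.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from paleovar.catalog import (DomainMap, TranscriptModel, build_catalog,
                              write_catalog_tsv)

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "sim"


def main():
    if not (SIM / "variants.tsv").exists():
        sys.exit("run analysis/01_simulate.py first")
    tm = TranscriptModel.from_json((SIM / "transcript.json").read_text())
    dm = DomainMap.from_mapping(json.loads((SIM / "domains.json").read_text()))
    rows = pd.read_csv(SIM / "variants.tsv", sep="\t", keep_default_na=False)
    kept, excluded = build_catalog(rows, tm, dm)
    write_catalog_tsv(kept, ROOT / "results" / "catalog.tsv")
    pd.DataFrame([{"name": e.name, "reason": e.reason, "detail": e.detail}
                  for e in excluded]).to_csv(
        ROOT / "results" / "catalog.exclusions.tsv", sep="\t", index=False)

    n_pv = sum(v.var_class == "PV" for v in kept)
    n_bv = len(kept) - n_pv
    reasons = pd.Series([e.reason for e in excluded]).value_counts().to_dict()
    print(f"{len(rows)} input rows -> {len(kept)} catalog variants "
          f"({n_pv} PV, {n_bv} BV); {len(excluded)} excluded: {reasons}")
    assert len(kept) + len(excluded) == len(rows)


if __name__ == "__main__":
    main()
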