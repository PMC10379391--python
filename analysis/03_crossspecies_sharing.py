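"""Project the catalog through the MAF alignment: per-species sharing calls
for every variant, then per-species/per-clade summaries, separately for PVs
and BVs. Verifies the sharing matrix against the generator's planted truth.

Reads results/sim/ and results/catalog.tsv; writes results/sharing.*.tsv.
"""

import json
import sys
from pathlib import Path

from paleovar.catalog import read_catalog_tsv
from paleovar.crossspecies import (CladeDef, compute_sharing, sharing_summary,
                                   write_matrix_tsv)
from paleovar.maf import MafIndex, read_maf

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "sim"
RES = ROOT / "results"


def main():
    if not (RES / "catalog.tsv").exists():
        sys.exit("run analysis/02_build_catalog.py first")
    catalog = read_catalog_tsv(RES / "catalog.tsv")
    index = MafIndex(read_maf(str(SIM / "alignment.maf")), "human")
    clades = CladeDef.from_yaml(SIM / "clades.yaml")

    truth = json.loads((SIM / "truth.json").read_text())["sharing"]
    for label in ("PV", "BV"):
        sub = [v for v in catalog if v.var_class == label]
        matrix = compute_sharing(sub, index)
        summ = sharing_summary(matrix, clades)
        write_matrix_tsv(matrix, RES / f"sharing.{label}.matrix.tsv")
        summ.per_species.to_csv(RES / f"sharing.{label}.species.tsv", sep="\t")
        summ.per_clade.to_csv(RES / f"sharing.{label}.clades.tsv", sep="\t")
        mism = sum(matrix.loc[v, sp] != truth[v][sp]
                   for v in matrix.index for sp in matrix.columns)
        print(f"{label}: {summ.n_variants_shared}/{summ.n_variants} variants "
              f"shared with >=1 species "
              f"({100 * summ.variant_sharing_fraction:.1f}%); "
              f"{summ.n_species_sharing} species share >=1 variant; "
              f"{mism} mismatches vs planted truth")


if __name__ == "__main__":
    main()
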