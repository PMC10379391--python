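"""Compare PV and BV per-species sharing-rate distributions with the
two-sided Mann-Whitney U test (exact mode at these group sizes). The planted
conditions make benign variants far more shared than pathogenic ones, so the
test should reject at alpha = 0.05.

Reads results/sharing.*.species.tsv; writes results/pv_bv_test.json.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from paleovar.stats import compare_sharing

ROOT = Path(__file__).resolve().parents[1]
RES = ROOT / "results"


def main():
    try:
        pv = pd.read_csv(RES / "sharing.PV.species.tsv", sep="\t", index_col=0)
        bv = pd.read_csv(RES / "sharing.BV.species.tsv", sep="\t", index_col=0)
    except FileNotFoundError:
        sys.exit("run analysis/03_crossspecies_sharing.py first")
    report = compare_sharing(pv["rate"], bv["rate"])
    with open(RES / "pv_bv_test.json", "w") as fh:
        json.dump(report, fh, indent=2)
    print(f"PV median rate {report['median_rate_pv']:.3f} vs "
          f"BV {report['median_rate_bv']:.3f}: U={report['U']:.1f}, "
          f"p={report['p_value']:.4g} ({report['method']}), "
          f"{'significant' if report['significant'] else 'not significant'} "
          f"at alpha={report['alpha']}")


if __name__ == "__main__":
    main()
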