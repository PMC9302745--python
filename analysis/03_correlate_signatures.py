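"""Correlate observed-data signatures with method accuracy.

For every signature feature of the observed (relative) counts, computes the
Spearman rank correlation with per-cell sensitivity and specificity pooled
over the five rescaling methods.  The headline associations are sparsity
vs sensitivity (proportion of zero counts) and the prevalence of apparent
feature-level change vs specificity (proportion of large fold decreases).

Reads results/records.csv and results/signatures.csv; writes
results/signature_correlations.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from compda.da_tests import ANALOG_METHODS
from compda.metrics import correlate_characteristics

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--records", type=Path,
                    default=ROOT / "results" / "records.csv")
    ap.add_argument("--signatures", type=Path,
                    default=ROOT / "results" / "signatures.csv")
    ap.add_argument("--out", type=Path,
                    default=ROOT / "results" / "signature_correlations.csv")
    args = ap.parse_args()

    records = pd.read_csv(args.records)
    records = records[(records["policy"] == "lenient")
                      & records["method"].isin(ANALOG_METHODS)]
    signatures = pd.read_csv(args.signatures)

    table = correlate_characteristics(records, signatures)
    table = table.sort_values("rho_specificity")
    table.to_csv(args.out, index=False)
    print(f"wrote {args.out} ({len(table)} features)")

    show = table.set_index("feature")
    for feat, target in (("prop_zero", "rho_sensitivity"),
                         ("corr_skew", "rho_sensitivity"),
                         ("prop_large_decrease", "rho_specificity"),
                         ("prop_large_increase", "rho_specificity"),
                         ("sd_delta_log", "rho_specificity")):
        print(f"Spearman rho({feat}, {target.split('_', 1)[1]}) = "
              f"{show.loc[feat, target]:+.2f}")


if __name__ == "__main__":
    main()
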