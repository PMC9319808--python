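"""Collect the experiment reports into one validity table.

Reads every <out>/<experiment>/report.json produced by the earlier
scripts and writes <out>/summary.csv: metrics, metric deltas between
biased and unbiased models, and which operational bias flags fired —
the study's bottom-line table.

Usage: python analysis/04_summary.py [--out results]
"""

import argparse
import glob
import json
import os

import pandas as pd


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=str, default="results")
    args = ap.parse_args()

    rows = []
    for path in sorted(glob.glob(os.path.join(args.out, "*", "report.json"))):
        with open(path) as fh:
            rep = json.load(fh)
        mb = rep["metrics_biased"]
        mu = rep.get("metrics_unbiased") or {}
        row = {
            "experiment": rep["experiment"],
            "bacc_biased": mb["balanced_accuracy"],
            "auc_biased": mb["auc"],
            "bacc_unbiased": mu.get("balanced_accuracy"),
            "auc_unbiased": mu.get("auc"),
            "n_significant": sum(1 for r in rep["tcav"] if r["significant"]),
        }
        row.update({f"flag_{k}": v for k, v in rep["bias_flags"].items()})
        rows.append(row)
    if not rows:
        raise SystemExit(f"no report.json found under {args.out}/*/")
    table = pd.DataFrame(rows)
    dest = os.path.join(args.out, "summary.csv")
    table.to_csv(dest, index=False)
    print(table.to_string(index=False))
    print(f"wrote {dest}")


if __name__ == "__main__":
    main()
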