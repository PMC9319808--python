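"""Generate one synthetic dataset per bias design and summarise what was
planted.

Writes PNG tiles + CSV manifests under <out>/data/<kind>/ and prints a
composition table per dataset: class balance in each split, source
regimes, marker coverage and strata counts — the ground truth that the
explanation methods are later asked to rediscover.

Usage: python analysis/01_simulate_datasets.py [--seed 1] [--tile-size 64]
                                               [--slides 12] [--tiles 8]
                                               [--out results]
"""

import argparse
import os

from xbias import experiments as ex, synthgen as sg

KINDS = ("none", "class_ratio", "measurement", "sampling", "class_correlated")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--tile-size", type=int, default=64)
    ap.add_argument("--slides", type=int, default=12)
    ap.add_argument("--tiles", type=int, default=8)
    ap.add_argument("--out", type=str, default="results")
    args = ap.parse_args()

    seeds = ex.derive_seeds(args.seed)
    params = sg.GenParams(tile_size=args.tile_size)
    for kind in KINDS:
        ds = sg.build_dataset(sg.BiasConfig(kind), args.slides, args.tiles,
                              seeds["data"], params)
        outdir = os.path.join(args.out, "data", kind)
        sg.save_dataset(ds, outdir)
        m = ds.manifest
        print(f"== {kind}: {len(m)} tiles -> {outdir}")
        print(m.groupby(["split", "label"]).size().unstack(fill_value=0))
        if kind == "measurement":
            print("label x source:\n",
                  m.groupby(["label", "source"]).size().unstack(fill_value=0))
        if kind == "class_correlated":
            print("marker coverage by label:\n",
                  m.groupby("label")["has_marker"].mean())
        if kind == "sampling":
            collagen = m.strata.str.contains("collagen")
            print("collagen fraction (train neg / test neg):",
                  round(collagen[(m.split == "train")
                                 & (m.label == "negative")].mean(), 3),
                  round(collagen[(m.split == "test")
                                 & (m.label == "negative")].mean(), 3))


if __name__ == "__main__":
    main()
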