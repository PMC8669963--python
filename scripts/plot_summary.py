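"""Optional plotting extra: bar charts of grand-average PLV (mean +/- SD) and
percent change per block, one figure per protocol/condition panel, from a
summary.csv produced by the package."""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("summary_csv", type=Path)
    ap.add_argument("-o", "--out-dir", type=Path, default=Path("figures"))
    args = ap.parse_args()

    table = pd.read_csv(args.summary_csv)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    groups = table.groupby(["protocol", "condition_label", "n_iterations"], sort=False)
    for i, ((protocol, condition, iters), panel) in enumerate(groups):
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.2))
        x = range(len(panel))
        ax1.bar(x, panel["grand_plv_mean"], yerr=panel["grand_plv_sd"], capsize=3)
        ax1.set_xticks(list(x), panel["block_label"], rotation=30, ha="right")
        ax1.set_ylabel("grand-average PLV")
        ax2.bar(x, panel["percent_change"], color="tab:orange")
        ax2.axhline(100, color="k", lw=0.8, ls="--")
        ax2.set_xticks(list(x), panel["block_label"], rotation=30, ha="right")
        ax2.set_ylabel("% change vs baseline")
        fig.suptitle(f"{protocol} | {condition} | {iters} iters/block", fontsize=10)
        fig.tight_layout()
        name = f"panel{i:02d}_{protocol}.png"
        fig.savefig(args.out_dir / name, dpi=150)
        plt.close(fig)
    print(f"wrote {len(groups)} figures to {args.out_dir}")


if __name__ == "__main__":
    main()
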