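"""Calibration run behind the frozen thresholds of the qualitative pattern suite.

Runs the withdrawal/renewal schedule for the two unbalanced plasticity
conditions and the de novo schedule for the high-potentiation condition, all
with matched replicate seeds at the default network size, and records the
statistics the pattern tests assert on.  The committed output
(``calibration/patterns.json``) documents where the test thresholds come from.

Usage: python scripts/calibrate_patterns.py [--seed 7] [--replicates 20]
"""

import argparse
import json
from pathlib import Path

import numpy as np

from dbskuramoto import (
    condition_bank,
    de_novo_protocol,
    run_experiment,
    withdrawal_renewal_protocol,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--replicates", type=int, default=20)
    ap.add_argument("--out", default="calibration/patterns.json")
    args = ap.parse_args()

    bank = condition_bank()
    kw = dict(n=100, n_replicates=args.replicates, master_seed=(args.seed,))
    protocol = withdrawal_renewal_protocol(2000)
    hi = run_experiment(protocol, bank[1], **kw).per_replicate_block_plv
    lo = run_experiment(protocol, bank[2], **kw).per_replicate_block_plv

    rel_dev = np.abs(hi - hi[:, [0]]) / hi[:, [0]]
    off_wins = int(((lo[:, 1] >= lo[:, 0]) & (lo[:, 3] >= lo[:, 2])).sum())
    off_wins_any = int(((lo[:, 1] >= lo[:, 0]) | (lo[:, 3] >= lo[:, 2])).sum())

    de_novo = {}
    for dur in (500, 1000, 2000):
        res = run_experiment(
            de_novo_protocol(dur), bank[1], n=100,
            n_replicates=args.replicates, master_seed=(args.seed, dur),
        ).per_replicate_block_plv
        de_novo[str(dur)] = {
            "off_mean": float(res[:, 0].mean()),
            "on_mean": float(res[:, 1].mean()),
            "on_over_off": float(res[:, 1].mean() / res[:, 0].mean()),
        }

    report = {
        "seed": args.seed,
        "replicates": args.replicates,
        "withdrawal_renewal": {
            "cond1_block_means": hi.mean(axis=0).tolist(),
            "cond2_block_means": lo.mean(axis=0).tolist(),
            "cond1_replicate_mean_exceeds_cond2": int(
                (hi.mean(axis=1) > lo.mean(axis=1)).sum()
            ),
            "cond1_min_block_exceeds_cond2_max_block": int(
                (hi.min(axis=1) > lo.max(axis=1)).sum()
            ),
            "cond1_max_rel_dev_from_baseline": float(rel_dev.max()),
            "cond2_both_off_blocks_exceed_prior_on": off_wins,
            "cond2_any_off_block_exceeds_prior_on": off_wins_any,
        },
        "de_novo_cond1": de_novo,
        "frozen_thresholds": {
            "cond1_stability_rel_band": 0.10,
            "cond1_vs_cond2_min_wins": 18,
            "de_novo_on_over_off_min_ratio": 0.95,
        },
    }
    out = Path(args.out)
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
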