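{
  "de_novo_cond1": {
    "1000": {
      "off_mean": 0.1769099432342182,
      "on_mean": 0.17679581108374692,
      "on_over_off": 0.9993548573450156
    },
    "2000": {
      "off_mean": 0.17602597921613586,
      "on_mean": 0.176410445713797,
      "on_over_off": 1.0021841463366556
    },
    "500": {
      "off_mean": 0.17895073920400922,
      "on_mean": 0.1770242830864779,
      "on_over_off": 0.9892347127142342
    }
  },
  "frozen_thresholds": {
    "cond1_stability_rel_band": 0.1,
    "cond1_vs_cond2_min_wins": 18,
    "de_novo_on_over_off_min_ratio": 0.95
  },
  "replicates": 20,
  "seed": 7,
  "withdrawal_renewal": {
    "cond1_block_means": [
      0.17646819095420385,
      0.17644486661786024,
      0.17502689751176886,
      0.17585920912476702,
      0.17499729959401478
    ],
    "cond1_max_rel_dev_from_baseline": 0.04092898031370909,
    "cond1_min_block_exceeds_cond2_max_block": 20,
    "cond1_replicate_mean_exceeds_cond2": 20,
    "cond2_any_off_block_exceeds_prior_on": 14,
    "cond2_block_means": [
      0.09001574456495261,
      0.08963326527528068,
      0.0899179641893133,
      0.08962780498370357,
      0.0898330532468182
    ],
    "cond2_both_off_blocks_exceed_prior_on": 2
  }
}
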