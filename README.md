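# dbskuramoto

A reproducible simulator of deep-brain-stimulation (DBS) insertion and
withdrawal in a Kuramoto network of phase oscillators whose pairwise coupling
is fixed by a plasticity signature (potentiation/depotentiation rates with
damping parameters). Synchronization is quantified by the grand-average
phase-locking value (PLV) over block-structured ON/OFF stimulation schedules,
with percentage change reported against a protocol baseline.

## Model

Each of `n` oscillators (default 100) evolves by explicit Euler steps of

```
dphi_i/dt = omega_i + (1/N) * sum_j K_ij * sin(phi_j - phi_i) + I_i
```

with natural frequencies `omega_i ~ U(0, 1)`, static coupling
`K_ij = alpha_p * exp(r1 * tau_p) - alpha_d * exp(r2 * tau_d)` drawn once per
unordered pair (`r1, r2 ~ U(0, 1)`, `r1 != r2`, `tau = 0.5`), and a
rectangular 130 Hz pulse train of amplitude 3.0 as the stimulation drive
(1 ms per iteration, 1-iteration pulses by default). The attractive coupling
convention `sin(phi_j - phi_i)` is the default; the repulsive alternative and
a damped exponential form `exp(-r / tau)` are available via configuration.

Seven built-in plasticity conditions span high/low and balanced/unbalanced
potentiation-depotentiation combinations. Two protocols are provided:

- `withdrawal_renewal`: DBS ON -> OFF -> ON2 -> OFF2 -> ON3, 2,000 iterations
  per block, ON block as the 100% baseline;
- `de_novo`: DBS OFF -> ON with equal block lengths (500/1,000/2,000 in the
  study grid), initial OFF block as the 100% baseline.

## CLI

```bash
# one protocol, one condition
dbskuramoto simulate --protocol withdrawal_renewal --condition 1 \
    --replicates 10 --seed 42 --out results/cond1

# custom plasticity signature
dbskuramoto simulate --protocol de_novo --condition custom \
    --alpha-p 2.0 --alpha-d 0.5 --iterations 1000 --seed 7 --out results/custom

# full study grid (7 withdrawal conditions + de novo durations)
dbskuramoto reproduce-paper --replicates 10 --seed 0 --out results/study

# list built-in conditions
dbskuramoto conditions
```

`simulate` also accepts a JSON/YAML config file (`--config run.yaml`;
command-line options override it) and `--export-trajectories` for
per-iteration phase CSV dumps. Every output directory contains `summary.csv`
(six-significant-digit block summaries), `config_echo.json` (full-precision
per-replicate PLVs plus the resolved parameters), `seeds.json`, and a
`manifest.json`; identical seeds give byte-identical outputs.

## Scripts

```bash
# acceptance report: recomputes the target quantities and writes JSON
python scripts/acceptance.py --seed 1 --out results/acceptance.json

# calibration run behind the frozen pattern-test thresholds
python scripts/calibrate_patterns.py --seed 7 --replicates 20

# quick bar plots from a summary.csv
python scripts/plot_summary.py results/study/summary.csv -o results/study/figures
```

## Library use

```python
import dbskuramoto as dk

bank = dk.condition_bank()
result = dk.run_experiment(
    dk.withdrawal_renewal_protocol(2000), bank[1],
    n=100, n_replicates=10, master_seed=42,
)
print(result.summary.grand_plv_mean, result.summary.percent_change)
```

Determinism contract: replicate `k` of master seed `s` uses
`numpy.random.SeedSequence([s, k])`, so results are bit-reproducible across
runs and platforms, and each replicate is unaffected by how many others run.
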