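"""Result serialization: summary CSV, config echo JSON, seed log, manifest.

CSV numbers are fixed to six significant digits; the JSON sidecar keeps full
precision so every run directory is sufficient to reproduce itself.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path

from ._exceptions import DbsKuramotoError
from .metrics import PhaseTrajectory
from .protocols import ExperimentResult, summary_table

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = (
    "protocol",
    "condition_label",
    "block_label",
    "n_iterations",
    "grand_plv_mean",
    "grand_plv_sd",
    "percent_change",
    "n_replicates",
    "seed",
)

_FLOAT_COLUMNS = ("grand_plv_mean", "grand_plv_sd", "percent_change")


class OutputError(DbsKuramotoError, OSError):
    """Raised when writing results fails; partial files are removed."""


def _fmt(x: float) -> str:
    return format(float(x), ".6g")


def write_results(
    results: ExperimentResult | list[ExperimentResult], out_dir: str | Path
) -> dict:
    """Write summary CSV, full-precision JSON echo, and a seed log.

    Returns a manifest mapping logical names to the written paths; the
    manifest itself is also written as ``manifest.json``.  Output is
    byte-stable for identical results.
    """
    if isinstance(results, ExperimentResult):
        results = [results]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    table = summary_table(results)
    csv_path = out / "summary.csv"
    echo_path = out / "config_echo.json"
    seeds_path = out / "seeds.json"
    manifest_path = out / "manifest.json"
    written: list[Path] = []
    try:
        with open(csv_path, "w", newline="") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(SUMMARY_COLUMNS)
            for _, row in table.iterrows():
                writer.writerow(
                    [
                        _fmt(row[c]) if c in _FLOAT_COLUMNS else row[c]
                        for c in SUMMARY_COLUMNS
                    ]
                )
        written.append(csv_path)

        echo = [
            {
                **res.config_echo,
                "per_replicate_block_plv": res.per_replicate_block_plv.tolist(),
                "block_labels": list(res.summary.block_labels),
                "grand_plv_mean": res.summary.grand_plv_mean.tolist(),
                "grand_plv_sd": res.summary.grand_plv_sd.tolist(),
                "percent_change": res.summary.percent_change.tolist(),
            }
            for res in results
        ]
        echo_path.write_text(json.dumps(echo, indent=2, sort_keys=True) + "\n")
        written.append(echo_path)

        seeds = [
            {
                "protocol": res.protocol.name,
                "condition_label": res.condition.label,
                "replicate_seeds": [list(s) for s in res.seeds],
            }
            for res in results
        ]
        seeds_path.write_text(json.dumps(seeds, indent=2, sort_keys=True) + "\n")
        written.append(seeds_path)

        manifest = {
            "summary_csv": csv_path.name,
            "config_echo_json": echo_path.name,
            "seeds_json": seeds_path.name,
            "n_results": len(results),
            "n_rows": int(len(table)),
        }
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        written.append(manifest_path)
    except OSError as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise OutputError(f"failed writing results under {out}: {exc}") from exc

    logger.info("wrote %d summary rows to %s", len(table), csv_path)
    return {**manifest, "out_dir": str(out)}


def write_trajectory(traj: PhaseTrajectory, path: str | Path) -> Path:
    """Dump one block's phases as long-format CSV (iteration, oscillator_index, phase_rad)."""
    path = Path(path)
    t, n = traj.phases.shape
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["iteration", "oscillator_index", "phase_rad"])
        for k in range(t):
            it = traj.iteration_offset + k
            for i in range(n):
                writer.writerow([it, i, repr(float(traj.phases[k, i]))])
    return path
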