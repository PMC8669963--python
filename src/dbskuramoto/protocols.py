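"""Condition bank, stimulation schedules, and experiment orchestration.

Two protocols are provided: a five-block withdrawal/renewal schedule
(ON, OFF, ON2, OFF2, ON3) for chronic subjects and a two-block de novo
schedule (OFF then ON).  ``run_experiment`` simulates one protocol under one
plasticity condition across independent replicates; ``run_full_study``
enumerates the full condition x protocol grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import ConfigurationError
from .metrics import SyncSummary, grand_plv, summarize_replicates
from .model import (
    PlasticitySignature,
    SimulationState,
    OscillatorEnsemble,
    StimulusSpec,
    build_coupling_matrix,
    draw_natural_frequencies,
    integrate_block,
)

WITHDRAWAL_BLOCK_LABELS = ("DBS ON", "DBS OFF", "DBS ON2", "DBS OFF2", "DBS ON3")
DE_NOVO_BLOCK_LABELS = ("DBS OFF", "DBS ON")

#: de novo ON/OFF block durations explored by default
DE_NOVO_DURATIONS = (500, 1000, 2000)

#: condition ids shown in the de novo arm of the study grid
DE_NOVO_CONDITIONS = (1, 2, 3, 4, 7)


@dataclass(frozen=True)
class ScheduleBlock:
    label: str
    dbs_on: bool
    n_iterations: int

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ConfigurationError(
                f"block '{self.label}' needs n_iterations >= 1, got {self.n_iterations}"
            )


@dataclass(frozen=True)
class Protocol:
    name: str
    blocks: tuple[ScheduleBlock, ...]
    baseline_block_index: int = 0

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ConfigurationError("protocol needs at least one block")
        if not 0 <= self.baseline_block_index < len(self.blocks):
            raise ConfigurationError("baseline_block_index out of range")

    @property
    def block_labels(self) -> tuple[str, ...]:
        return tuple(b.label for b in self.blocks)


@dataclass(frozen=True)
class ExperimentResult:
    """Per-replicate grand PLVs for one protocol/condition plus summary stats."""

    protocol: Protocol
    condition: PlasticitySignature
    per_replicate_block_plv: np.ndarray  # R x B
    summary: SyncSummary
    seeds: tuple[tuple[int, ...], ...]
    config_echo: dict = field(default_factory=dict)
    trajectories: dict | None = None  # replicate index -> list of PhaseTrajectory


def condition_bank() -> dict[int, PlasticitySignature]:
    """The seven built-in plasticity conditions, keyed 1-7."""
    params = {
        1: (8.0, 0.001),
        2: (0.001, 8.0),
        3: (8.0, 8.0),
        4: (4.0, 4.0),
        5: (0.7, 0.7),
        6: (0.1, 0.1),
        7: (0.001, 0.001),
    }
    return {
        cid: PlasticitySignature(
            alpha_p=ap,
            alpha_d=ad,
            label=f"condition {cid} (alpha_p={ap}, alpha_d={ad})",
        )
        for cid, (ap, ad) in params.items()
    }


def withdrawal_renewal_protocol(block_iterations: int = 2000) -> Protocol:
    """Five alternating blocks starting with stimulation ON; baseline is block 0."""
    on_flags = (True, False, True, False, True)
    blocks = tuple(
        ScheduleBlock(label=lab, dbs_on=on, n_iterations=block_iterations)
        for lab, on in zip(WITHDRAWAL_BLOCK_LABELS, on_flags)
    )
    return Protocol(name="withdrawal_renewal", blocks=blocks, baseline_block_index=0)


def de_novo_protocol(block_iterations: int = 2000) -> Protocol:
    """Two equal-length blocks, OFF then ON; the initial OFF block is the baseline."""
    blocks = (
        ScheduleBlock("DBS OFF", False, block_iterations),
        ScheduleBlock("DBS ON", True, block_iterations),
    )
    return Protocol(name="de_novo", blocks=blocks, baseline_block_index=0)


def derive_child_seed(
    master_seed: int | tuple[int, ...], replicate: int
) -> tuple[int, ...]:
    """Deterministic child-seed words for one replicate.

    The returned tuple seeds a ``numpy.random.SeedSequence``, making replicate
    streams independent of each other and stable across platforms.
    """
    master = (master_seed,) if np.isscalar(master_seed) else tuple(master_seed)
    return (*master, replicate)


def _simulate_replicate(
    protocol: Protocol,
    condition: PlasticitySignature,
    n: int,
    spec: StimulusSpec,
    seed_words: tuple[int, ...],
    dt: float,
    sign_convention: str,
    exp_form: str,
    record_trajectories: bool = False,
):
    rng = np.random.default_rng(np.random.SeedSequence(list(seed_words)))
    omega = draw_natural_frequencies(n, rng)
    coupling = build_coupling_matrix(condition, n, rng, exp_form=exp_form)
    phases0 = rng.uniform(0.0, 2.0 * np.pi, size=n)
    state = SimulationState(
        iteration=0,
        ensemble=OscillatorEnsemble(n=n, natural_frequencies=omega, phases=phases0),
        rng_seed=seed_words,
    )
    checksum = coupling.checksum()
    block_plv = np.empty(len(protocol.blocks))
    trajectories = [] if record_trajectories else None
    for b, block in enumerate(protocol.blocks):
        traj, state = integrate_block(
            state,
            coupling,
            spec,
            dbs_on=block.dbs_on,
            n_iterations=block.n_iterations,
            dt=dt,
            sign_convention=sign_convention,
            block_label=block.label,
        )
        block_plv[b] = grand_plv(traj)
        if trajectories is not None:
            trajectories.append(traj)
    if coupling.checksum() != checksum:
        raise ConfigurationError("coupling matrix mutated during run (static plasticity violated)")
    return block_plv, trajectories


def run_experiment(
    protocol: Protocol,
    condition: PlasticitySignature,
    n: int = 100,
    spec: StimulusSpec | None = None,
    n_replicates: int = 10,
    master_seed: int | tuple[int, ...] = 0,
    dt: float = 1.0,
    sign_convention: str = "attractive",
    exp_form: str = "literal",
    record_trajectories: bool = False,
) -> ExperimentResult:
    """Simulate ``n_replicates`` independent subjects through one protocol.

    Each replicate draws its frequencies, coupling matrix, and initial phases
    once from a child seed of ``master_seed``, then integrates the protocol's
    blocks with phases carried across block boundaries.
    """
    if n_replicates < 1:
        raise ConfigurationError(f"n_replicates must be >= 1, got {n_replicates}")
    spec = spec or StimulusSpec()
    seeds = tuple(derive_child_seed(master_seed, k) for k in range(n_replicates))
    plv = np.empty((n_replicates, len(protocol.blocks)))
    all_traj = {}
    for k, seed_words in enumerate(seeds):
        try:
            plv[k], trajs = _simulate_replicate(
                protocol, condition, n, spec, seed_words, dt, sign_convention,
                exp_form, record_trajectories,
            )
        except Exception as exc:
            raise type(exc)(f"replicate {k} ({seed_words}): {exc}") from exc
        if trajs is not None:
            all_traj[k] = trajs
    summary = summarize_replicates(
        plv, protocol.baseline_block_index, protocol.block_labels
    )
    echo = {
        "protocol": protocol.name,
        "block_iterations": [b.n_iterations for b in protocol.blocks],
        "condition_label": condition.label,
        "alpha_p": condition.alpha_p,
        "alpha_d": condition.alpha_d,
        "tau_p": condition.tau_p,
        "tau_d": condition.tau_d,
        "n": n,
        "n_replicates": n_replicates,
        "master_seed": list(master_seed) if not np.isscalar(master_seed) else master_seed,
        "frequency_hz": spec.frequency,
        "amplitude": spec.amplitude,
        "pulse_width_iterations": spec.pulse_width_iterations,
        "iteration_duration_ms": spec.iteration_duration_ms,
        "dt": dt,
        "sign_convention": sign_convention,
        "exp_form": exp_form,
    }
    return ExperimentResult(
        protocol=protocol,
        condition=condition,
        per_replicate_block_plv=plv,
        summary=summary,
        seeds=seeds,
        config_echo=echo,
        trajectories=all_traj if record_trajectories else None,
    )


def run_full_study(
    n_replicates: int = 10,
    master_seed: int = 0,
    n: int = 100,
    spec: StimulusSpec | None = None,
    withdrawal_iterations: int = 2000,
    de_novo_iterations: tuple[int, ...] = DE_NOVO_DURATIONS,
    all_de_novo_conditions: bool = False,
    dt: float = 1.0,
    sign_convention: str = "attractive",
    exp_form: str = "literal",
) -> list[ExperimentResult]:
    """The full study grid: withdrawal/renewal for all seven conditions plus the
    de novo protocol at each duration for the subset of conditions in the study
    figures (all seven with ``all_de_novo_conditions``).

    Conditions within an arm share replicate seeds (matched subjects); each de
    novo duration uses an independent seed stream.
    """
    bank = condition_bank()
    results: list[ExperimentResult] = []
    for cid in sorted(bank):
        results.append(
            run_experiment(
                withdrawal_renewal_protocol(withdrawal_iterations),
                bank[cid],
                n=n,
                spec=spec,
                n_replicates=n_replicates,
                master_seed=(master_seed,),
                dt=dt,
                sign_convention=sign_convention,
                exp_form=exp_form,
            )
        )
    de_novo_ids = sorted(bank) if all_de_novo_conditions else list(DE_NOVO_CONDITIONS)
    for duration in de_novo_iterations:
        for cid in de_novo_ids:
            results.append(
                run_experiment(
                    de_novo_protocol(duration),
                    bank[cid],
                    n=n,
                    spec=spec,
                    n_replicates=n_replicates,
                    master_seed=(master_seed, duration),
                    dt=dt,
                    sign_convention=sign_convention,
                    exp_form=exp_form,
                )
            )
    return results


def summary_table(results: list[ExperimentResult]) -> pd.DataFrame:
    """One row per protocol/condition/block, matching the summary CSV schema."""
    rows = []
    for res in results:
        s = res.summary
        for b, label in enumerate(s.block_labels):
            rows.append(
                {
                    "protocol": res.protocol.name,
                    "condition_label": res.condition.label,
                    "block_label": label,
                    "n_iterations": res.protocol.blocks[b].n_iterations,
                    "grand_plv_mean": s.grand_plv_mean[b],
                    "grand_plv_sd": s.grand_plv_sd[b],
                    "percent_change": s.percent_change[b],
                    "n_replicates": s.n_replicates,
                    "seed": str(res.config_echo.get("master_seed")),
                }
            )
    return pd.DataFrame(rows)
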