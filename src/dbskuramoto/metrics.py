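"""Synchronization metrics: pairwise and grand-average phase-locking value (PLV),
baseline-normalized percentage change, and replicate summaries."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._exceptions import DegenerateBaselineError, InvalidInputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhaseTrajectory:
    """Recorded phases of one schedule block: a T x n matrix of radians."""

    phases: np.ndarray
    block_label: str = ""
    iteration_offset: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.phases, dtype=float)
        if p.ndim != 2 or p.shape[0] < 1 or p.shape[1] < 2:
            raise InvalidInputError(
                f"trajectory must be T x n with T >= 1, n >= 2; got shape {p.shape}"
            )
        if not np.all(np.isfinite(p)):
            raise InvalidInputError("trajectory contains non-finite phases")

    @property
    def n_iterations(self) -> int:
        return self.phases.shape[0]

    @property
    def n_oscillators(self) -> int:
        return self.phases.shape[1]


@dataclass(frozen=True)
class SyncSummary:
    """Per-block replicate statistics of the grand-average PLV."""

    block_labels: tuple[str, ...]
    grand_plv_mean: np.ndarray
    grand_plv_sd: np.ndarray
    percent_change: np.ndarray
    n_replicates: int
    baseline_index: int
    #: mean over replicates of each replicate's own percent-change vector
    percent_change_replicate_mean: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        m = np.asarray(self.grand_plv_mean, dtype=float)
        if np.any((m < 0) | (m > 1)):
            raise InvalidInputError("grand PLV means must lie in [0, 1]")
        if self.percent_change[self.baseline_index] != 100.0:
            raise InvalidInputError("percent change at the baseline block must be 100")


def plv_pair(phases_i, phases_j) -> float:
    """Phase-locking value between two equal-length phase sequences.

    Computed as the modulus of the time average of ``exp(-1j * (phi_i - phi_j))``
    over the recorded iterations; lies in [0, 1], invariant to common offsets
    and to adding multiples of 2*pi to any entry.
    """
    a = np.asarray(phases_i, dtype=float)
    b = np.asarray(phases_j, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or a.shape != b.shape:
        raise InvalidInputError(
            f"phase sequences must be 1-D with equal lengths, got {a.shape} and {b.shape}"
        )
    if a.size == 0:
        raise InvalidInputError("phase sequences must have at least one sample")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise InvalidInputError("phase sequences must be finite")
    v = np.abs(np.mean(np.exp(-1j * (a - b))))
    # |mean of unit vectors| can exceed 1 by an ulp
    return float(min(v, 1.0))


def grand_plv(traj) -> float:
    """Mean pairwise PLV over all n(n-1)/2 unordered oscillator pairs.

    Accepts a :class:`PhaseTrajectory` or a plain T x n array.
    """
    phases = traj.phases if isinstance(traj, PhaseTrajectory) else np.asarray(traj, float)
    if phases.ndim != 2 or phases.shape[1] < 2:
        raise InvalidInputError(f"need a T x n array with n >= 2, got {phases.shape}")
    if not np.all(np.isfinite(phases)):
        raise InvalidInputError("trajectory contains non-finite phases")
    t, n = phases.shape
    z = np.exp(1j * phases)  # T x n
    # pairwise mean of exp(-i (phi_i - phi_j)) for all i, j at once
    m = np.conj(z).T @ z / t
    iu = np.triu_indices(n, k=1)
    return float(min(np.mean(np.abs(m[iu])), 1.0))


def percent_change(block_values, baseline_index: int) -> np.ndarray:
    """Per-block values as percentages of the baseline block (baseline = 100)."""
    values = np.asarray(block_values, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise InvalidInputError("block_values must be a non-empty 1-D sequence")
    if not 0 <= baseline_index < values.size:
        raise InvalidInputError(
            f"baseline_index {baseline_index} out of range for {values.size} blocks"
        )
    base = values[baseline_index]
    if base <= 0:
        raise DegenerateBaselineError(
            f"baseline block value is {base}; percent change undefined"
        )
    out = 100.0 * values / base
    out[baseline_index] = 100.0
    return out


def summarize_replicates(
    per_replicate_block_values,
    baseline_index: int,
    block_labels: tuple[str, ...] | None = None,
) -> SyncSummary:
    """Per-block mean and sample SD across replicates, plus percent change.

    Percent change is computed on the per-block replicate means; the mean of
    per-replicate percent-change vectors is also reported for transparency.
    A single replicate yields SD = 0 with a logged warning.
    """
    values = np.atleast_2d(np.asarray(per_replicate_block_values, dtype=float))
    r, b = values.shape
    if r < 1 or b < 1:
        raise InvalidInputError("need at least one replicate and one block")
    if block_labels is None:
        block_labels = tuple(f"block_{i}" for i in range(b))
    if len(block_labels) != b:
        raise InvalidInputError("block_labels length must match block count")

    means = values.mean(axis=0)
    if r == 1:
        logger.warning("single replicate: reporting SD = 0 for all blocks")
        sds = np.zeros(b)
    else:
        sds = values.std(axis=0, ddof=1)
    pct = percent_change(means, baseline_index)
    per_rep_pct = np.vstack(
        [percent_change(values[k], baseline_index) for k in range(r)]
    ).mean(axis=0)
    return SyncSummary(
        block_labels=tuple(block_labels),
        grand_plv_mean=means,
        grand_plv_sd=sds,
        percent_change=pct,
        n_replicates=r,
        baseline_index=baseline_index,
        percent_change_replicate_mean=per_rep_pct,
    )
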