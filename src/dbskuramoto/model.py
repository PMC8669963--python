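"""Oscillator ensemble, plasticity-determined coupling, pulse drive, and integrator.

The network is a Kuramoto system of ``n`` phase oscillators whose pairwise
coupling strengths are drawn once at construction time from a plasticity
signature (potentiation/depotentiation rates and damping parameters) and then
held fixed for the whole run.  A rectangular pulse train models the external
stimulation drive; integration is explicit Euler with unwrapped phases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._exceptions import (
    ConfigurationError,
    InvalidNetworkError,
    NumericalOverflowError,
)
from .metrics import PhaseTrajectory

#: abort threshold for |phase|; anything this large signals an unstable dt/K combination
PHASE_OVERFLOW_BOUND = 1e9

#: accepted coupling-term sign conventions
SIGN_CONVENTIONS = ("attractive", "repulsive")

#: accepted plasticity exponential forms
EXP_FORMS = ("literal", "damped")


@dataclass(frozen=True)
class PlasticitySignature:
    """Plasticity makeup of a simulated subject.

    Parameters
    ----------
    alpha_p : float
        Potentiation rate (dimensionless, >= 0).
    alpha_d : float
        Depotentiation rate (dimensionless, >= 0).
    tau_p, tau_d : float
        Damping parameters (> 0), both defaulting to 0.5.
    label : str
        Free-text condition name.
    """

    alpha_p: float
    alpha_d: float
    tau_p: float = 0.5
    tau_d: float = 0.5
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.alpha_p >= 0 and math.isfinite(self.alpha_p)):
            raise ConfigurationError(f"alpha_p must be finite and >= 0, got {self.alpha_p}")
        if not (self.alpha_d >= 0 and math.isfinite(self.alpha_d)):
            raise ConfigurationError(f"alpha_d must be finite and >= 0, got {self.alpha_d}")
        if not (self.tau_p > 0 and math.isfinite(self.tau_p)):
            raise ConfigurationError(f"tau_p must be finite and > 0, got {self.tau_p}")
        if not (self.tau_d > 0 and math.isfinite(self.tau_d)):
            raise ConfigurationError(f"tau_d must be finite and > 0, got {self.tau_d}")


@dataclass(frozen=True)
class CouplingMatrix:
    """Static pairwise coupling strengths plus the random draws behind them."""

    n: int
    strengths: np.ndarray
    draws_r1: np.ndarray
    draws_r2: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.strengths, dtype=float)
        if s.shape != (self.n, self.n):
            raise ConfigurationError(
                f"strengths must be {self.n}x{self.n}, got {s.shape}"
            )
        if not np.allclose(s, s.T, rtol=0, atol=0):
            raise ConfigurationError("coupling matrix must be exactly symmetric")
        if np.any(np.diag(s) != 0):
            raise ConfigurationError("coupling matrix diagonal must be zero")

    def checksum(self) -> bytes:
        """Byte digest of the strength matrix, for static-plasticity assertions."""
        import hashlib

        return hashlib.sha256(np.ascontiguousarray(self.strengths).tobytes()).digest()


@dataclass(frozen=True)
class OscillatorEnsemble:
    """Natural frequencies and current (unwrapped) phases of the network."""

    n: int
    natural_frequencies: np.ndarray
    phases: np.ndarray

    def __post_init__(self) -> None:
        if len(self.natural_frequencies) != self.n or len(self.phases) != self.n:
            raise ConfigurationError(
                "natural_frequencies and phases must both have length n"
            )


@dataclass(frozen=True)
class StimulusSpec:
    """Rectangular pulse-train stimulation parameters.

    ``targets`` is either ``None`` (every oscillator receives the drive) or a
    sequence of oscillator indices.
    """

    frequency: float = 130.0
    amplitude: float = 3.0
    pulse_width_iterations: int = 1
    iteration_duration_ms: float = 1.0
    targets: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not (self.frequency > 0 and math.isfinite(self.frequency)):
            raise ConfigurationError(f"frequency must be > 0, got {self.frequency}")
        if not math.isfinite(self.amplitude):
            raise ConfigurationError("amplitude must be finite")
        if self.pulse_width_iterations < 1:
            raise ConfigurationError("pulse_width_iterations must be >= 1")
        if not (self.iteration_duration_ms > 0):
            raise ConfigurationError("iteration_duration_ms must be > 0")
        duty = (
            self.pulse_width_iterations
            * self.frequency
            * self.iteration_duration_ms
            / 1000.0
        )
        if duty >= 1:
            raise ConfigurationError(
                f"pulse onsets overlap: width*frequency*duration = {duty} >= 1"
            )


@dataclass(frozen=True)
class SimulationState:
    """One snapshot of the evolving system; advanced by :func:`euler_step`."""

    iteration: int
    ensemble: OscillatorEnsemble
    rng_seed: int | tuple[int, ...] | None = None


def _open_unit_uniform(rng: np.random.Generator, size: int) -> np.ndarray:
    """U(0,1) draws guaranteed to lie strictly inside the open interval."""
    x = rng.uniform(size=size)
    bad = (x <= 0.0) | (x >= 1.0)
    while bad.any():  # probability ~0, guards the documented open-interval contract
        x[bad] = rng.uniform(size=int(bad.sum()))
        bad = (x <= 0.0) | (x >= 1.0)
    return x


def draw_natural_frequencies(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` natural frequencies, each uniform on the open interval (0, 1)."""
    if n < 2:
        raise InvalidNetworkError(f"network needs at least 2 oscillators, got n={n}")
    return _open_unit_uniform(rng, n)


def _plasticity_exponential(r, tau: float, exp_form: str):
    if exp_form == "literal":
        return np.exp(np.asarray(r) * tau)
    if exp_form == "damped":
        return np.exp(-np.asarray(r) / tau)
    raise ConfigurationError(
        f"exp_form must be one of {EXP_FORMS}, got {exp_form!r}"
    )


def coupling_strength(
    sig: PlasticitySignature, r1, r2, exp_form: str = "literal"
):
    """Pairwise coupling ``alpha_p * E(r1, tau_p) - alpha_d * E(r2, tau_d)``.

    ``E`` is ``exp(r * tau)`` in the default ``literal`` form or ``exp(-r / tau)``
    in the alternative ``damped`` form.  Accepts scalars or arrays for r1/r2.
    May be negative when the depotentiation term dominates.
    """
    pot = sig.alpha_p * _plasticity_exponential(r1, sig.tau_p, exp_form)
    dep = sig.alpha_d * _plasticity_exponential(r2, sig.tau_d, exp_form)
    out = pot - dep
    if np.ndim(out) == 0:
        return float(out)
    return out


def build_coupling_matrix(
    sig: PlasticitySignature,
    n: int,
    rng: np.random.Generator,
    exp_form: str = "literal",
) -> CouplingMatrix:
    """Draw one (r1, r2) pair per unordered oscillator pair and build K.

    The matrix is symmetric with zero diagonal; r2 is redrawn on the
    (probability-zero) event that it collides with r1.
    """
    if n < 2:
        raise InvalidNetworkError(f"network needs at least 2 oscillators, got n={n}")
    m = n * (n - 1) // 2
    r1 = _open_unit_uniform(rng, m)
    r2 = _open_unit_uniform(rng, m)
    clash = r2 == r1
    while clash.any():
        r2[clash] = _open_unit_uniform(rng, int(clash.sum()))
        clash = r2 == r1
    k = np.asarray(coupling_strength(sig, r1, r2, exp_form), dtype=float)

    iu = np.triu_indices(n, k=1)
    strengths = np.zeros((n, n))
    m_r1 = np.zeros((n, n))
    m_r2 = np.zeros((n, n))
    strengths[iu] = k
    m_r1[iu] = r1
    m_r2[iu] = r2
    strengths += strengths.T
    m_r1 += m_r1.T
    m_r2 += m_r2.T
    return CouplingMatrix(n=n, strengths=strengths, draws_r1=m_r1, draws_r2=m_r2)


def _pulse_onset(spec: StimulusSpec, iteration: int) -> bool:
    delta = spec.iteration_duration_ms / 1000.0
    f = spec.frequency
    return math.floor(iteration * delta * f) > math.floor((iteration - 1) * delta * f)


def dbs_waveform(spec: StimulusSpec, iteration: int, dbs_on: bool) -> float:
    """Instantaneous drive value at a global iteration index.

    Returns 0 when stimulation is off; during ON blocks a pulse of
    ``pulse_width_iterations`` begins at every iteration where the pulse clock
    ``floor(t * dt_seconds * frequency)`` advances (onset at t = 0 included).
    """
    if iteration < 0:
        raise ConfigurationError(f"iteration must be >= 0, got {iteration}")
    if not dbs_on:
        return 0.0
    lo = max(0, iteration - spec.pulse_width_iterations + 1)
    for onset in range(lo, iteration + 1):
        if _pulse_onset(spec, onset):
            return spec.amplitude
    return 0.0


def drive_series(
    spec: StimulusSpec, start_iteration: int, n_iterations: int, dbs_on: bool
) -> np.ndarray:
    """Vectorized drive values for iterations [start, start + n_iterations).

    Matches :func:`dbs_waveform` evaluated pointwise on the global iteration
    counter (the pulse clock never resets between blocks).
    """
    if not dbs_on:
        return np.zeros(n_iterations)
    delta = spec.iteration_duration_ms / 1000.0
    w = spec.pulse_width_iterations
    # look back w-1 iterations so pulses straddling the block start are kept
    lo = max(0, start_iteration - (w - 1))
    t = np.arange(lo - 1, start_iteration + n_iterations)
    clock = np.floor(t * delta * spec.frequency)
    onsets = clock[1:] > clock[:-1]  # onset flag for iterations lo .. end-1
    active = onsets.copy()
    for k in range(1, w):
        active[k:] |= onsets[:-k]
    active = active[start_iteration - lo :]
    return np.where(active, spec.amplitude, 0.0)


def _step_kernel(
    phases: np.ndarray,
    omega: np.ndarray,
    strengths: np.ndarray,
    drive: np.ndarray | float,
    dt: float,
    sign_convention: str,
) -> np.ndarray:
    # sum_j K_ij sin(phi_j - phi_i) = Im( exp(-i phi_i) * sum_j K_ij exp(i phi_j) )
    z = np.exp(1j * phases)
    interaction = np.imag(np.conj(z) * (strengths @ z)) / len(phases)
    if sign_convention == "repulsive":
        interaction = -interaction
    elif sign_convention != "attractive":
        raise ConfigurationError(
            f"sign_convention must be one of {SIGN_CONVENTIONS}, got {sign_convention!r}"
        )
    return phases + dt * (omega + interaction + drive)


def _check_phases(phases: np.ndarray, iteration: int) -> None:
    if not np.all(np.isfinite(phases)):
        raise NumericalOverflowError(
            f"non-finite phase at iteration {iteration}; unstable dt/coupling combination"
        )
    peak = np.max(np.abs(phases))
    if peak > PHASE_OVERFLOW_BOUND:
        raise NumericalOverflowError(
            f"|phase| = {peak:.3e} exceeds {PHASE_OVERFLOW_BOUND:.0e} "
            f"at iteration {iteration}; unstable dt/coupling combination"
        )


def euler_step(
    state: SimulationState,
    coupling: CouplingMatrix,
    drive: np.ndarray | float,
    dt: float = 1.0,
    sign_convention: str = "attractive",
) -> SimulationState:
    """Advance the state one explicit-Euler step; phases stay unwrapped."""
    ens = state.ensemble
    if coupling.n != ens.n:
        raise ConfigurationError(
            f"coupling is for n={coupling.n} but ensemble has n={ens.n}"
        )
    if dt <= 0:
        raise ConfigurationError(f"dt must be > 0, got {dt}")
    drive_arr = np.asarray(drive, dtype=float)
    if drive_arr.ndim == 1 and len(drive_arr) != ens.n:
        raise ConfigurationError(
            f"drive vector has length {len(drive_arr)}, expected {ens.n}"
        )
    new_phases = _step_kernel(
        ens.phases, ens.natural_frequencies, coupling.strengths, drive_arr, dt,
        sign_convention,
    )
    _check_phases(new_phases, state.iteration + 1)
    return replace(
        state,
        iteration=state.iteration + 1,
        ensemble=replace(ens, phases=new_phases),
    )


def _target_mask(spec: StimulusSpec, n: int) -> np.ndarray:
    if spec.targets is None:
        return np.ones(n)
    mask = np.zeros(n)
    idx = np.asarray(spec.targets, dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= n):
        raise ConfigurationError("stimulus targets out of range for network size")
    mask[idx] = 1.0
    return mask


def integrate_block(
    state: SimulationState,
    coupling: CouplingMatrix,
    spec: StimulusSpec,
    dbs_on: bool,
    n_iterations: int,
    dt: float = 1.0,
    sign_convention: str = "attractive",
    block_label: str = "",
) -> tuple[PhaseTrajectory, SimulationState]:
    """Run one schedule block, recording the phase vector after every step.

    The pulse clock is driven by the *global* iteration counter carried in
    ``state``, so chaining blocks is bit-identical to one long run.
    """
    if n_iterations < 1:
        raise ConfigurationError(f"n_iterations must be >= 1, got {n_iterations}")
    ens = state.ensemble
    if coupling.n != ens.n:
        raise ConfigurationError(
            f"coupling is for n={coupling.n} but ensemble has n={ens.n}"
        )
    if sign_convention not in SIGN_CONVENTIONS:
        raise ConfigurationError(
            f"sign_convention must be one of {SIGN_CONVENTIONS}, got {sign_convention!r}"
        )

    mask = _target_mask(spec, ens.n)
    drives = drive_series(spec, state.iteration, n_iterations, dbs_on)
    omega = ens.natural_frequencies
    strengths = coupling.strengths
    phases = ens.phases
    out = np.empty((n_iterations, ens.n))
    start = state.iteration
    for k in range(n_iterations):
        phases = _step_kernel(
            phases, omega, strengths, drives[k] * mask, dt, sign_convention
        )
        out[k] = phases
    _check_phases(phases, start + n_iterations)

    traj = PhaseTrajectory(
        phases=out, block_label=block_label, iteration_offset=start
    )
    new_state = replace(
        state,
        iteration=start + n_iterations,
        ensemble=replace(ens, phases=phases),
    )
    return traj, new_state
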