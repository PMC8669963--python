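"""Run configuration: schema, defaults, validation, (de)serialization.

Configs are plain JSON/YAML mappings with four sections (``network``,
``plasticity``, ``stimulus``, ``protocol``) plus ``replicates`` and
``output``.  Unknown keys are an error: this is a reproducibility tool and a
silently ignored typo would corrupt parameter provenance.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from ._exceptions import ConfigurationError
from .model import EXP_FORMS, SIGN_CONVENTIONS, PlasticitySignature, StimulusSpec
from .protocols import (
    Protocol,
    condition_bank,
    de_novo_protocol,
    withdrawal_renewal_protocol,
)

PROTOCOL_NAMES = ("withdrawal_renewal", "de_novo")


@dataclass(frozen=True)
class NetworkConfig:
    n: int = 100
    master_seed: int = 0


@dataclass(frozen=True)
class PlasticityConfig:
    condition: int | None = None
    alpha_p: float | None = None
    alpha_d: float | None = None
    tau_p: float = 0.5
    tau_d: float = 0.5
    label: str = ""
    exp_form: str = "literal"


@dataclass(frozen=True)
class StimulusConfig:
    frequency_hz: float = 130.0
    amplitude: float = 3.0
    pulse_width_iterations: int = 1
    iteration_duration_ms: float = 1.0
    coupling_sign_convention: str = "attractive"


@dataclass(frozen=True)
class ProtocolConfig:
    name: str = "withdrawal_renewal"
    block_iterations: int = 2000


@dataclass(frozen=True)
class OutputConfig:
    dir: str = "results"
    export_trajectories: bool = False


@dataclass(frozen=True)
class RunConfig:
    network: NetworkConfig = field(default_factory=NetworkConfig)
    plasticity: PlasticityConfig = field(default_factory=PlasticityConfig)
    stimulus: StimulusConfig = field(default_factory=StimulusConfig)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    replicates: int = 10
    output: OutputConfig = field(default_factory=OutputConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    def serialize(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    # --- resolution to simulator objects -------------------------------------

    def signature(self) -> PlasticitySignature:
        p = self.plasticity
        if p.condition is not None:
            if p.alpha_p is not None or p.alpha_d is not None:
                raise ConfigurationError(
                    "plasticity: give either 'condition' or explicit alpha values, not both"
                )
            bank = condition_bank()
            if p.condition not in bank:
                raise ConfigurationError(
                    f"plasticity.condition must be in 1..7, got {p.condition}"
                )
            return bank[p.condition]
        if p.alpha_p is None or p.alpha_d is None:
            raise ConfigurationError(
                "plasticity: need 'condition' or both 'alpha_p' and 'alpha_d'"
            )
        label = p.label or f"custom (alpha_p={p.alpha_p}, alpha_d={p.alpha_d})"
        return PlasticitySignature(
            alpha_p=p.alpha_p, alpha_d=p.alpha_d, tau_p=p.tau_p, tau_d=p.tau_d,
            label=label,
        )

    def stimulus_spec(self) -> StimulusSpec:
        s = self.stimulus
        return StimulusSpec(
            frequency=s.frequency_hz,
            amplitude=s.amplitude,
            pulse_width_iterations=s.pulse_width_iterations,
            iteration_duration_ms=s.iteration_duration_ms,
        )

    def resolved_protocol(self) -> Protocol:
        if self.protocol.name == "withdrawal_renewal":
            return withdrawal_renewal_protocol(self.protocol.block_iterations)
        return de_novo_protocol(self.protocol.block_iterations)


_SECTION_TYPES = {
    "network": NetworkConfig,
    "plasticity": PlasticityConfig,
    "stimulus": StimulusConfig,
    "protocol": ProtocolConfig,
    "output": OutputConfig,
}


def _build_section(name: str, cls, doc: dict):
    if not isinstance(doc, dict):
        raise ConfigurationError(f"section '{name}' must be a mapping")
    known = {f for f in cls.__dataclass_fields__}
    unknown = set(doc) - known
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) in '{name}': {sorted(unknown)} (known: {sorted(known)})"
        )
    return cls(**doc)


def _validate(cfg: RunConfig) -> RunConfig:
    if cfg.network.n < 2:
        raise ConfigurationError(f"network.n must be >= 2, got {cfg.network.n}")
    p = cfg.plasticity
    for key in ("alpha_p", "alpha_d"):
        v = getattr(p, key)
        if v is not None and v < 0:
            raise ConfigurationError(f"plasticity.{key} must be >= 0, got {v}")
    for key in ("tau_p", "tau_d"):
        if getattr(p, key) <= 0:
            raise ConfigurationError(f"plasticity.{key} must be > 0")
    if p.exp_form not in EXP_FORMS:
        raise ConfigurationError(
            f"plasticity.exp_form must be one of {EXP_FORMS}, got {p.exp_form!r}"
        )
    if cfg.stimulus.coupling_sign_convention not in SIGN_CONVENTIONS:
        raise ConfigurationError(
            "stimulus.coupling_sign_convention must be one of "
            f"{SIGN_CONVENTIONS}, got {cfg.stimulus.coupling_sign_convention!r}"
        )
    if cfg.protocol.name not in PROTOCOL_NAMES:
        raise ConfigurationError(
            f"protocol.name must be one of {PROTOCOL_NAMES}, got {cfg.protocol.name!r}"
        )
    if cfg.protocol.block_iterations < 1:
        raise ConfigurationError("protocol.block_iterations must be >= 1")
    if cfg.replicates < 1:
        raise ConfigurationError("replicates must be >= 1")
    # exercise the stricter constructor-level checks (frequency, amplitude, ...)
    cfg.stimulus_spec()
    return cfg


def load_config(source: str | Path | dict | None = None) -> RunConfig:
    """Build a validated, default-filled :class:`RunConfig`.

    ``source`` may be a path to a JSON/YAML file, a document string, a mapping,
    or None/empty for all-defaults.  Unknown keys fail loudly, naming the key.
    """
    if source is None:
        doc: dict = {}
    elif isinstance(source, dict):
        doc = source
    else:
        text = Path(source).read_text() if Path(str(source)).is_file() else str(source)
        parsed = yaml.safe_load(text)
        if parsed is None:
            parsed = {}
        if not isinstance(parsed, dict):
            raise ConfigurationError("config document must be a mapping")
        doc = parsed

    unknown = set(doc) - set(_SECTION_TYPES) - {"replicates"}
    if unknown:
        raise ConfigurationError(
            f"unknown top-level key(s): {sorted(unknown)} "
            f"(known: {sorted(set(_SECTION_TYPES) | {'replicates'})})"
        )
    sections = {
        name: _build_section(name, cls, doc.get(name, {}))
        for name, cls in _SECTION_TYPES.items()
    }
    replicates = doc.get("replicates", 10)
    if not isinstance(replicates, int):
        raise ConfigurationError(f"replicates must be an integer, got {replicates!r}")
    cfg = RunConfig(replicates=replicates, **sections)
    return _validate(cfg)
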