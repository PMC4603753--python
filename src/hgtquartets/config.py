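"""Configuration files, run manifests and the seeding convention.

Configs are TOML: flat keys matching :class:`SimulationConfig` and
:class:`ExperimentConfig` field names (GTR parameters as ``gtr_rates``,
``gtr_freqs``, ``gtr_alpha``).  Unknown keys are rejected by name.  One
global seed spawns per-stage/per-replicate/per-locus substreams through a
documented counter scheme (see :func:`hgtquartets.evaluation.rng_for`), so
adding methods or conditions never perturbs simulation draws.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .evaluation import ExperimentConfig, rng_for  # re-exported convention
from .simulate import GTRParams, SimulationConfig

__all__ = ["load_config", "dump_config", "RunManifest", "rng_for"]

_SIM_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)} - {"gtr"}
_EXP_FIELDS = {f.name for f in dataclasses.fields(ExperimentConfig)} - {"sim"}
_GTR_KEYS = {"gtr_rates", "gtr_freqs", "gtr_alpha"}


def _num(key: str, value):
    """Accept TOML numbers or numeric strings like \"2e-9\"."""
    if isinstance(value, bool):
        raise ValueError(f"config key {key!r}: expected a number, got a boolean")
    if isinstance(value, (int, float)):
        return value
    if isinstance(value, str):
        try:
            return float(value)
        except ValueError:
            raise ValueError(f"config key {key!r}: {value!r} is not a number")
    raise ValueError(f"config key {key!r}: {value!r} is not a number")


def load_config(path) -> ExperimentConfig:
    """Parse a TOML config into an :class:`ExperimentConfig`.

    An empty file yields the all-defaults configuration (the zero-HGT
    condition at full 51-taxon scale).  Invalid values raise ValueError
    naming the key and constraint.
    """
    text = Path(path).read_text()
    try:
        data = tomllib.loads(text)
    except tomllib.TOMLDecodeError as exc:
        raise ValueError(f"{path}: not valid TOML: {exc}") from exc

    sim_kwargs: dict = {}
    exp_kwargs: dict = {}
    gtr_kwargs: dict = {}
    for key, value in data.items():
        if key in _GTR_KEYS:
            gtr_kwargs[key.removeprefix("gtr_")] = value
        elif key in _SIM_FIELDS:
            sim_kwargs[key] = value
        elif key in _EXP_FIELDS:
            exp_kwargs[key] = value
        else:
            known = sorted(_SIM_FIELDS | _EXP_FIELDS | _GTR_KEYS)
            raise ValueError(f"unknown config key {key!r}; known keys: {known}")

    for k in ("birth_rate", "tree_height", "hgt_rate", "subst_rate"):
        if k in sim_kwargs:
            sim_kwargs[k] = _num(k, sim_kwargs[k])
    if "pop_size" in sim_kwargs:
        v = sim_kwargs["pop_size"]
        if isinstance(v, list):
            sim_kwargs["pop_size"] = tuple(_num("pop_size", x) for x in v)
        else:
            sim_kwargs["pop_size"] = _num("pop_size", v)
    if gtr_kwargs:
        if "rates" in gtr_kwargs:
            gtr_kwargs["rates"] = tuple(_num("gtr_rates", x) for x in gtr_kwargs["rates"])
        if "freqs" in gtr_kwargs:
            gtr_kwargs["freqs"] = tuple(_num("gtr_freqs", x) for x in gtr_kwargs["freqs"])
        if "alpha" in gtr_kwargs:
            gtr_kwargs["alpha"] = _num("gtr_alpha", gtr_kwargs["alpha"])
        sim_kwargs["gtr"] = GTRParams(**gtr_kwargs)
    for k in ("hgt_rates", "expected_events"):
        if k in exp_kwargs:
            exp_kwargs[k] = tuple(_num(k, x) for x in exp_kwargs[k])
    for k in ("gene_counts", "methods"):
        if k in exp_kwargs:
            exp_kwargs[k] = tuple(exp_kwargs[k])

    try:
        sim = SimulationConfig(**sim_kwargs)
        return ExperimentConfig(sim=sim, **exp_kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid configuration: {exc}") from exc


def dump_config(config: ExperimentConfig) -> dict:
    """Flatten a config back to the TOML key space (for manifests/logs)."""
    out: dict = {}
    for f in dataclasses.fields(SimulationConfig):
        v = getattr(config.sim, f.name)
        if f.name == "gtr":
            out["gtr_rates"] = list(v.rates)
            out["gtr_freqs"] = list(v.freqs)
            out["gtr_alpha"] = v.alpha
        elif v is not None:
            out[f.name] = list(v) if isinstance(v, tuple) else v
    for f in dataclasses.fields(ExperimentConfig):
        if f.name == "sim":
            continue
        v = getattr(config, f.name)
        if v is not None:
            out[f.name] = list(v) if isinstance(v, tuple) else v
    return out


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Everything needed to re-execute a pipeline stage bit-identically:
    config snapshot, global seed, package version, per-stage output paths
    and checksums of the stage inputs."""

    config: dict
    seed: int
    version: str
    outputs: dict[str, str] = field(default_factory=dict)
    input_checksums: dict[str, str] = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         sort_keys=True) + "\n")

    @staticmethod
    def from_json(path) -> "RunManifest":
        return RunManifest(**json.loads(Path(path).read_text()))

    @staticmethod
    def for_run(config: ExperimentConfig) -> "RunManifest":
        from . import __version__

        return RunManifest(config=dump_config(config), seed=config.seed,
                           version=__version__)
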