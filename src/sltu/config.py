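"""Experiment configuration: YAML loading, validation, provenance.

Config keys carry their unit in the name (``gNa_mS_per_cm2``, ``Ra_ohm_cm``,
``gmax_nS`` ...) so a file can never be mis-read in the wrong unit.  Unknown
keys are rejected with a list of offenders; an empty file yields the package
defaults.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .biophys import MembraneParams, Morphology

__all__ = ["ExperimentConfig", "ConfigError", "load_config", "provenance"]

_EXPERIMENTS = ("sweep", "rate-table", "spike-table", "enumerate", "min-weights")

_PARAM_KEYS = {
    "Cm_uF_per_cm2",
    "gL_mS_per_cm2",
    "gNa_mS_per_cm2",
    "gK_mS_per_cm2",
    "EL_mV",
    "ENa_mV",
    "EK_mV",
    "Es_mV",
    "VT_mV",
    "tau_s_ms",
    "Ra_ohm_cm",
}
_MORPH_KEYS = {
    "soma_diameter_um",
    "dendrite_length_um",
    "dendrite_diameter_um",
    "n_dendrites",
    "compartments_per_dendrite",
}
_TOP_KEYS = {
    "experiment",
    "seed",
    "dt_ms",
    "n_bins",
    "n_inputs",
    "gmax_nS",
    "distance_um",
    "totals_nS",
    "membrane",
    "morphology",
    "outdir",
}

_NONNEGATIVE = {
    "Cm_uF_per_cm2", "gL_mS_per_cm2", "gNa_mS_per_cm2", "gK_mS_per_cm2",
    "tau_s_ms", "Ra_ohm_cm", "gmax_nS", "dt_ms",
}


class ConfigError(ValueError):
    """Invalid experiment configuration."""


@dataclass(frozen=True)
class ExperimentConfig:
    """A fully resolved experiment description."""

    experiment: str = "sweep"
    seed: int = 0
    dt_ms: float = 0.025
    n_bins: int = 20
    n_inputs: int = 3
    gmax_nS: float = 20.0
    distance_um: float = 350.0
    totals_nS: tuple[float, ...] = (10, 20, 30, 40, 50, 60, 70, 80, 90, 100)
    membrane: MembraneParams = field(default_factory=MembraneParams)
    morphology: Morphology = field(default_factory=Morphology)
    outdir: str = "results"

    def canonical(self) -> dict:
        d = asdict(self)
        d["membrane"] = asdict(self.membrane)
        d["morphology"] = asdict(self.morphology)
        d["totals_nS"] = list(self.totals_nS)
        return d


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> ExperimentConfig:
    """Load a YAML config, merge with defaults, and validate.

    ``overrides`` (e.g. from CLI flags) take precedence over the file.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config root must be a mapping, got {type(loaded).__name__}")
        raw = loaded
    if overrides:
        for k, v in overrides.items():
            if v is None:
                continue
            if k in _PARAM_KEYS:
                raw.setdefault("membrane", {})
                raw["membrane"] = dict(raw["membrane"], **{k: v})
            else:
                raw[k] = v
    return _validate(raw)


def _validate(raw: dict) -> ExperimentConfig:
    problems: list[str] = []
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        problems.append(f"unknown keys: {sorted(unknown)}")

    membrane = raw.get("membrane", {}) or {}
    morph = raw.get("morphology", {}) or {}
    if not isinstance(membrane, dict):
        problems.append("membrane must be a mapping")
        membrane = {}
    if not isinstance(morph, dict):
        problems.append("morphology must be a mapping")
        morph = {}
    bad_mem = set(membrane) - _PARAM_KEYS
    if bad_mem:
        problems.append(
            f"unknown membrane keys (every quantity carries its unit suffix): {sorted(bad_mem)}"
        )
    bad_morph = set(morph) - _MORPH_KEYS
    if bad_morph:
        problems.append(f"unknown morphology keys: {sorted(bad_morph)}")

    for key, val in list(membrane.items()) + [
        (k, raw[k]) for k in ("gmax_nS", "dt_ms") if k in raw
    ]:
        if key in _NONNEGATIVE and isinstance(val, (int, float)) and val < 0:
            problems.append(f"{key} must be non-negative, got {val}")

    exp = raw.get("experiment", "sweep")
    if exp not in _EXPERIMENTS:
        problems.append(f"experiment must be one of {_EXPERIMENTS}, got {exp!r}")

    if problems:
        raise ConfigError("; ".join(problems))

    try:
        mp = MembraneParams(**membrane)
        mo = Morphology(**morph)
        cfg = ExperimentConfig(
            experiment=exp,
            seed=int(raw.get("seed", 0)),
            dt_ms=float(raw.get("dt_ms", 0.025)),
            n_bins=int(raw.get("n_bins", 20)),
            n_inputs=int(raw.get("n_inputs", 3)),
            gmax_nS=float(raw.get("gmax_nS", 20.0)),
            distance_um=float(raw.get("distance_um", 350.0)),
            totals_nS=tuple(raw.get("totals_nS", (10, 20, 30, 40, 50, 60, 70, 80, 90, 100))),
            membrane=mp,
            morphology=mo,
            outdir=str(raw.get("outdir", "results")),
        )
    except (TypeError, ValueError) as err:
        raise ConfigError(str(err)) from err
    return cfg


def provenance(config: ExperimentConfig, version: str) -> dict:
    """Reproducibility stamp: canonical config, its hash, seed and version."""
    canon = json.dumps(config.canonical(), sort_keys=True)
    return {
        "config": config.canonical(),
        "config_sha256": hashlib.sha256(canon.encode()).hexdigest(),
        "seed": config.seed,
        "package_version": version,
    }
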