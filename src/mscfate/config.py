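"""Run configuration: YAML loading, defaults, validation, JSON sidecars.

A :class:`RunConfig` resolves everything a command needs: the parameter set
(Table-style defaults plus overrides or a parameter file), the model
variant, the kPa-to-internal unit constant, per-command option blocks and
the output directory.  Loading fills defaults, rejects unknown keys by
name, and validates values; every command writes the fully resolved config
back out as a JSON sidecar next to its outputs so results are traceable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import yaml

from .model import PA_PER_KPA, ModelVariant, STATE_VARS
from .params import GENES, PARAM_NAMES, ParameterSet

__all__ = ["RunConfig", "load_config", "resolve_params", "resolve_variant"]

_SWEEP_DEFAULTS = {"s_min_kpa": 0.1, "s_max_kpa": 60.0, "n_points": 500,
                   "theta_on": 0.5, "resolution_kpa": 0.01}
_DOSE_DEFAULTS = {"first_s_kpa": 30.0, "first_duration": 50.0,
                  "second_s_kpa": 0.4, "total_time": None, "sample_dt": 0.2}
_ROBUSTNESS_DEFAULTS = {"s_min_kpa": 0.2, "s_max_kpa": 42.0,
                        "n_stiffness": 1000, "n_perturbations": 1000,
                        "cv": 0.05, "tol": 4.0, "per_gene": False}
_LANDSCAPE_DEFAULTS = {"s_kpa": [0.4, 0.8, 12.0, 20.0], "n_starts": 10000,
                       "noise_d": 0.01, "diffusion": "state",
                       "grid_shape": [200, 200]}
_SDE_DEFAULTS = {"eta": 0.223606797749979, "dt": 0.01, "n_replicates": 10,
                 "shared_wiener": True, "noise_on": "all", "sample_dt": 0.2}
_VARIANT_DEFAULTS = {"mode": "noncooperative", "blocked": [],
                     "submodel_gene": None}

_TOP_KEYS = {"params", "params_file", "variant", "seed", "output_dir",
             "sweep", "dose", "robustness", "landscape", "sde"}


@dataclass
class RunConfig:
    """Fully resolved run configuration."""

    params: ParameterSet = field(default_factory=ParameterSet)
    variant: ModelVariant = field(default_factory=ModelVariant)
    seed: int = 0
    output_dir: Path = Path("out")
    sweep: Dict = field(default_factory=lambda: dict(_SWEEP_DEFAULTS))
    dose: Dict = field(default_factory=lambda: dict(_DOSE_DEFAULTS))
    robustness: Dict = field(default_factory=lambda: dict(_ROBUSTNESS_DEFAULTS))
    landscape: Dict = field(default_factory=lambda: dict(_LANDSCAPE_DEFAULTS))
    sde: Dict = field(default_factory=lambda: dict(_SDE_DEFAULTS))
    #: stiffness unit conversion (printed kPa -> internal units)
    pa_per_kpa: float = PA_PER_KPA

    def to_dict(self) -> Dict:
        return {
            "params": self.params.to_dict(),
            "variant": {"mode": self.variant.mode,
                        "blocked": sorted(self.variant.blocked),
                        "submodel_gene": self.variant.submodel_gene},
            "seed": self.seed,
            "output_dir": str(self.output_dir),
            "pa_per_kpa": self.pa_per_kpa,
            "sweep": self.sweep, "dose": self.dose,
            "robustness": self.robustness, "landscape": self.landscape,
            "sde": self.sde,
        }

    def write_sidecar(self, path) -> None:
        """Write the resolved config as a JSON sidecar."""
        Path(path).write_text(json.dumps(self.to_dict(), indent=2,
                                         sort_keys=True) + "\n")


def _merge_block(name: str, defaults: Dict, overrides: Dict) -> Dict:
    merged = dict(defaults)
    for key, value in overrides.items():
        if key not in defaults:
            raise ValueError(f"unknown key {name}.{key!r}; "
                             f"known keys: {sorted(defaults)}")
        merged[key] = value
    return merged


def resolve_params(overrides: Optional[Dict] = None,
                   params_file=None) -> ParameterSet:
    """Default parameters with named overrides applied (and validated)."""
    base = ParameterSet.read_yaml(params_file) if params_file \
        else ParameterSet()
    if not overrides:
        return base
    values = base.to_dict()
    for key, value in overrides.items():
        if key not in values:
            raise ValueError(f"unknown parameter {key!r}; known names: "
                             f"{PARAM_NAMES[:6]}... (41 kinetic constants "
                             "k1..k9, K1..K16, n1..n16, plus d1..d6)")
        values[key] = value
    return ParameterSet.from_dict(values)   # re-validates positivity etc.


def resolve_variant(spec: Optional[Dict] = None) -> ModelVariant:
    spec = _merge_block("variant", _VARIANT_DEFAULTS, spec or {})
    blocked = spec["blocked"]
    if blocked == "all":
        blocked = list(GENES)
    for gene in blocked:
        if gene not in GENES:
            raise ValueError(f"variant.blocked entry {gene!r} is not a "
                             f"lineage gene (one of {list(GENES)})")
    return ModelVariant(mode=spec["mode"], blocked=frozenset(blocked),
                        submodel_gene=spec["submodel_gene"])


def load_config(path=None) -> RunConfig:
    """Load a YAML config file; an empty or missing-path file gives defaults.

    Unknown keys at any level are rejected with the offending key named.
    """
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config root must be a mapping, got "
                             f"{type(loaded).__name__}")
        raw = loaded
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)}; "
                         f"known keys: {sorted(_TOP_KEYS)}")
    params = resolve_params(raw.get("params"), raw.get("params_file"))
    variant = resolve_variant(raw.get("variant"))
    seed = int(raw.get("seed", 0))
    if not 0 <= seed < 2**31:
        raise ValueError("seed must be in [0, 2**31)")
    cfg = RunConfig(
        params=params, variant=variant, seed=seed,
        output_dir=Path(raw.get("output_dir", "out")),
        sweep=_merge_block("sweep", _SWEEP_DEFAULTS, raw.get("sweep") or {}),
        dose=_merge_block("dose", _DOSE_DEFAULTS, raw.get("dose") or {}),
        robustness=_merge_block("robustness", _ROBUSTNESS_DEFAULTS,
                                raw.get("robustness") or {}),
        landscape=_merge_block("landscape", _LANDSCAPE_DEFAULTS,
                               raw.get("landscape") or {}),
        sde=_merge_block("sde", _SDE_DEFAULTS, raw.get("sde") or {}),
    )
    return cfg
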