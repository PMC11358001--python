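"""Run configuration: one structured YAML file driving the whole pipeline.

A ``RunConfig`` holds components, couplings, protocols, the noise model,
normalization rules, regime strains and the global seed.  ``load`` rejects
unknown keys by name, and ``load(save(c)) == c`` holds losslessly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .components import ComponentSpec, CouplingSpec, NoiseModel, StretchProtocol

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config", "config_hash"]


class ConfigError(ValueError):
    """Raised for malformed or unknown configuration content."""


@dataclass
class RunConfig:
    components: list[ComponentSpec] = field(default_factory=list)
    couplings: list[CouplingSpec] = field(default_factory=list)
    protocols: dict[str, StretchProtocol] = field(default_factory=dict)
    noise: NoiseModel = field(default_factory=NoiseModel)
    norm_rules: dict[str, str] = field(default_factory=dict)
    regime_strains: dict[str, float] = field(default_factory=lambda: {"low": 0.10, "high": 0.20})
    output_dir: str = "."
    seed: int = 0


def _component_to_dict(c: ComponentSpec) -> dict:
    vf = c.viscous_fraction
    if isinstance(vf, dict):
        vf = {float(k): float(v) for k, v in vf.items()}
    return {
        "name": c.name,
        "elastic_poly": [float(v) for v in c.elastic_poly],
        "viscous_fraction": vf,
        "tau": float(c.tau),
        "preparations": sorted(c.preparations),
    }


def _component_from_dict(d: dict) -> ComponentSpec:
    _check_keys(d, {"name", "elastic_poly", "viscous_fraction", "tau", "preparations"}, "component")
    vf = d.get("viscous_fraction", 0.0)
    if isinstance(vf, dict):
        vf = {float(k): float(v) for k, v in vf.items()}
    return ComponentSpec(
        name=d["name"],
        elastic_poly=tuple(d["elastic_poly"]),
        viscous_fraction=vf,
        tau=d.get("tau", 1.0),
        preparations=frozenset(d.get("preparations", [])),
    )


def _check_keys(d, allowed, context):
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {context}: {sorted(unknown)}")


_TOP_KEYS = {
    "components",
    "couplings",
    "protocols",
    "noise",
    "norm_rules",
    "regime_strains",
    "output_dir",
    "seed",
}


def save_config(cfg: RunConfig, path) -> None:
    doc = {
        "components": [_component_to_dict(c) for c in cfg.components],
        "couplings": [
            {
                "source": c.source,
                "target": c.target,
                "loss_fraction": float(c.loss_fraction),
                "gating": c.gating,
                "applies_to": c.applies_to,
            }
            for c in cfg.couplings
        ],
        "protocols": {
            name: {
                "steps": [[float(s), float(h)] for s, h in p.steps],
                "ramp_rate": float(p.ramp_rate),
                "rest_s": float(p.rest_s),
                "fs": float(p.fs),
                "replicates": int(p.replicates),
            }
            for name, p in cfg.protocols.items()
        },
        "noise": {
            "sigma_rel": float(cfg.noise.sigma_rel),
            "replicate_cv": float(cfg.noise.replicate_cv),
            "seed": int(cfg.noise.seed),
        },
        "norm_rules": dict(cfg.norm_rules),
        "regime_strains": {k: float(v) for k, v in cfg.regime_strains.items()},
        "output_dir": cfg.output_dir,
        "seed": int(cfg.seed),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    _check_keys(doc, _TOP_KEYS, "config")
    couplings = []
    for d in doc.get("couplings", []):
        _check_keys(d, {"source", "target", "loss_fraction", "gating", "applies_to"}, "coupling")
        couplings.append(
            CouplingSpec(
                source=d["source"],
                target=d["target"],
                loss_fraction=d.get("loss_fraction", 0.0),
                gating=d.get("gating", "none"),
                applies_to=d.get("applies_to", "both"),
            )
        )
    protocols = {}
    for name, d in doc.get("protocols", {}).items():
        _check_keys(d, {"steps", "ramp_rate", "rest_s", "fs", "replicates"}, f"protocol {name}")
        protocols[name] = StretchProtocol(
            steps=tuple((float(s), float(h)) for s, h in d["steps"]),
            ramp_rate=d.get("ramp_rate", 1.0),
            rest_s=d.get("rest_s", 1.0),
            fs=d.get("fs", 1000.0),
            replicates=d.get("replicates", 1),
        )
    nd = doc.get("noise", {})
    _check_keys(nd, {"sigma_rel", "replicate_cv", "seed"}, "noise")
    return RunConfig(
        components=[_component_from_dict(d) for d in doc.get("components", [])],
        couplings=couplings,
        protocols=protocols,
        noise=NoiseModel(
            sigma_rel=nd.get("sigma_rel", 0.0),
            replicate_cv=nd.get("replicate_cv", 0.0),
            seed=nd.get("seed", 0),
        ),
        norm_rules=doc.get("norm_rules", {}),
        regime_strains=doc.get("regime_strains", {"low": 0.10, "high": 0.20}),
        output_dir=doc.get("output_dir", "."),
        seed=doc.get("seed", 0),
    )


def config_hash(obj) -> str:
    """Short stable hash of a configuration object (for output headers)."""
    return hashlib.sha1(repr(obj).encode()).hexdigest()[:12]
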