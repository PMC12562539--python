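"""YAML configuration parsing with named profiles.

Two packaged profiles exist: ``fullscale`` (80
epochs, batch 8, alpha=0.01, eta=0.001, sigma2=0.001, the 1024-feature
residual backbone with AdamW) and ``desk`` (16^3 volumes, tiny CNN with 32
features, 10 epochs — the CPU-minutes scale every test runs at).  A YAML
file may override any field; unknown keys are rejected with the offending
name.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .fed_engine import FederatedConfig
from .synthetic import SyntheticSpec

__all__ = ["PROFILES", "parse_config", "dump_config", "ConfigError"]


class ConfigError(ValueError):
    pass


PROFILES: dict[str, dict] = {
    "desk": {},
    "fullscale": {
        "epochs": 80,
        "batch_size": 8,
        "alpha": 0.01,
        "eta": 0.001,
        "sigma2": 0.001,
        "d_feat": 1024,
        "encoder_variant": "resnet10_3d",
        "optimizer": "adamw",
        "weight_decay": 0.95,
    },
}


def _build(cls, overrides: dict, section: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(overrides) - fields
    if unknown:
        raise ConfigError(
            f"unknown key(s) in section {section!r}: {sorted(unknown)}")
    # normalize YAML lists to the tuple types the dataclasses expect
    clean = {k: tuple(v) if isinstance(v, list) else v
             for k, v in overrides.items()}
    try:
        return cls(**clean)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid value in section {section!r}: {exc}")


def parse_config(path: str | Path | None = None, profile: str = "desk",
                 ) -> tuple[FederatedConfig, SyntheticSpec]:
    """Parse a YAML config into (FederatedConfig, SyntheticSpec).

    Layout: top-level ``federated:`` and ``synthetic:`` mappings, both
    optional.  Profile defaults are applied first, file values win.
    """
    if profile not in PROFILES:
        raise ConfigError(f"unknown profile {profile!r}; "
                          f"expected one of {sorted(PROFILES)}")
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
    unknown = set(raw) - {"federated", "synthetic"}
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    fed = dict(PROFILES[profile])
    fed.update(raw.get("federated") or {})
    syn = dict(raw.get("synthetic") or {})
    if "site_params" in syn and syn["site_params"] is not None:
        syn["site_params"] = tuple(tuple(p) for p in syn["site_params"])
    return (_build(FederatedConfig, fed, "federated"),
            _build(SyntheticSpec, syn, "synthetic"))


def dump_config(fed: FederatedConfig, syn: SyntheticSpec) -> str:
    """Serialize configs back to YAML (semantic round-trip with parse)."""
    def plain(obj):
        d = dataclasses.asdict(obj)
        return {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in d.items()}
    syn_d = plain(syn)
    if syn_d.get("site_params"):
        syn_d["site_params"] = [list(p) for p in syn_d["site_params"]]
    return yaml.safe_dump({"federated": plain(fed), "synthetic": syn_d},
                          sort_keys=False)
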