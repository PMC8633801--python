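"""Run configuration: strict YAML/JSON schema for domains, stages and inlets.

Unknown keys are rejected so that typos fail loudly, and every run can emit
the resolved configuration next to its outputs for bit-identical replay.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .dcco_growth import CostFunctional, StageConfig
from .domain_geometry import BoxDomain, DomainPartition, MeshDomain, PerfusionDomain

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    pass


def _check_keys(block: dict, allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")


def _domain_from_dict(block: dict) -> PerfusionDomain:
    _check_keys(block, {"type", "corners", "file", "seed"}, "domain")
    kind = block.get("type")
    seed = block.get("seed")
    if kind == "box":
        lo, hi = block["corners"]
        return BoxDomain(lo, hi, seed=seed)
    if kind == "mesh":
        return MeshDomain.from_file(block["file"], seed=seed)
    raise ConfigError(f"domain type must be box or mesh, got {kind!r}")


def _cost_from_dict(block: dict | None) -> CostFunctional:
    if block is None:
        return CostFunctional.volumetric()
    _check_keys(block, {"kind", "c_v", "c_p", "c_d", "V_ref", "l_ref",
                        "r_ref", "gamma"}, "cost")
    kind = block.get("kind", "volumetric")
    if kind == "volumetric":
        return CostFunctional.volumetric()
    return CostFunctional.sprouting(
        c_v=block.get("c_v", 1.0), c_p=block.get("c_p", 0.0),
        c_d=block.get("c_d", 0.0), V_ref=block.get("V_ref", 1.0),
        l_ref=block.get("l_ref", 1.0), r_ref=block.get("r_ref", 1.0),
        gamma=block.get("gamma", 3.0),
    )


_STAGE_KEYS = {
    "name", "N", "cost", "gamma", "delta", "f_r", "f_n", "n_bif",
    "theta_min", "phi_min", "seed", "k_d", "opt_v",
}


def _stage_from_dict(block: dict, default_seed: int) -> StageConfig:
    _check_keys(block, _STAGE_KEYS, f"stage {block.get('name', '?')!r}")
    return StageConfig(
        N=int(block["N"]),
        cost=_cost_from_dict(block.get("cost")),
        name=block.get("name", "stage"),
        gamma=block.get("gamma", 3.0),
        delta=block.get("delta", 0.0),
        f_r=block.get("f_r", 0.9),
        f_n=block.get("f_n", 1.0),
        n_bif=block.get("n_bif", 7),
        theta_min=block.get("theta_min", 30.0),
        phi_min=block.get("phi_min", 0.0),
        seed=int(block.get("seed", default_seed)),
        k_d=block.get("k_d", 0.25),
        opt_v=block.get("opt_v", 1.0),
    )


@dataclasses.dataclass
class RunConfig:
    """Everything needed to (re)run a growth experiment."""

    domain: PerfusionDomain
    inlet: dict
    stages: list[StageConfig]
    subdomain_stages: list[StageConfig]
    partition_counts: tuple[int, int, int] | None
    seed: int
    output_dir: Path
    raw: dict

    def partition(self) -> DomainPartition:
        if self.partition_counts is None:
            raise ConfigError("config has no partition block")
        return DomainPartition(self.domain, self.partition_counts)

    def dump_resolved(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.raw, fh, indent=2, sort_keys=True)


_TOP_KEYS = {"domain", "inlet", "stages", "subdomain_stages", "partition",
             "seed", "output_dir"}
_INLET_KEYS = {"x_p", "x_d", "r0", "Q_in", "gamma", "tree_csv"}


def load_config(path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        raw = (json.load(fh) if path.suffix == ".json"
               else yaml.safe_load(fh))
    if not isinstance(raw, dict):
        raise ConfigError("top-level config must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")
    if "domain" not in raw:
        raise ConfigError("config requires a domain block")
    seed = int(raw.get("seed", 0))
    inlet = dict(raw.get("inlet", {}))
    if inlet:
        _check_keys(inlet, _INLET_KEYS, "inlet")
    counts = raw.get("partition", {}).get("counts") if raw.get("partition") else None
    if raw.get("partition"):
        _check_keys(raw["partition"], {"counts"}, "partition")
    return RunConfig(
        domain=_domain_from_dict(raw["domain"]),
        inlet=inlet,
        stages=[_stage_from_dict(b, seed) for b in raw.get("stages", [])],
        subdomain_stages=[_stage_from_dict(b, seed)
                          for b in raw.get("subdomain_stages", [])],
        partition_counts=tuple(counts) if counts else None,
        seed=seed,
        output_dir=Path(raw.get("output_dir", "out")),
        raw=raw,
    )
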