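"""Structured-text (YAML) run configurations.

A run configuration bundles everything one interim decision analysis needs:
the trial design, per-arm priors, observed stage-one means, both candidate
stage-two plans, the utility kind and indifference band, and optional grid
and simulation blocks.  Configurations round-trip losslessly through
:func:`to_dict` / :func:`from_dict`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .bayes import NormalPrior
from .designs import ADD, NO_ADD, Stage2Plan, TrialDesign, make_plan
from .simulate import SimulationSettings
from .testing import Stage1Observation
from .utilities import UTILITY_KINDS

__all__ = ["ConfigError", "RunConfig", "load_config", "from_dict", "to_dict", "dump_config"]


class ConfigError(ValueError):
    """A configuration block is missing, malformed or inconsistent."""


@dataclass(frozen=True)
class RunConfig:
    """Parsed run configuration."""

    design: TrialDesign
    priors: Mapping[int, NormalPrior]
    stage1: Stage1Observation | None
    plan_add: Stage2Plan
    plan_noadd: Stage2Plan
    utility: str = "count"
    epsilon: float = 0.01
    grids: Mapping[str, Any] = field(default_factory=dict)
    simulation: SimulationSettings | None = None


def _require(block: Mapping[str, Any], key: str, where: str) -> Any:
    if key not in block:
        raise ConfigError(f"missing '{key}' in the {where} block")
    return block[key]


def _int_keys(mapping: Mapping[Any, Any], where: str) -> dict[int, Any]:
    try:
        return {int(k): v for k, v in mapping.items()}
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"arm indices in the {where} block must be integers") from exc


def from_dict(raw: Mapping[str, Any]) -> RunConfig:
    """Build a validated :class:`RunConfig` from a plain mapping."""
    if not isinstance(raw, Mapping):
        raise ConfigError("configuration root must be a mapping")
    try:
        d = _require(raw, "design", "root")
        design = TrialDesign(
            K=int(_require(d, "K", "design")),
            n1=_int_keys(_require(d, "n1", "design"), "design.n1"),
            sigma2={
                k: float(v)
                for k, v in _int_keys(_require(d, "sigma2", "design"), "design.sigma2").items()
            },
            alpha=float(_require(d, "alpha", "design")),
            N2=int(_require(d, "N2", "design")),
        )
        priors = {
            k: NormalPrior(float(v["mean"]), float(v["variance"]))
            for k, v in _int_keys(_require(raw, "priors", "root"), "priors").items()
        }
        stage1 = None
        if raw.get("stage1") is not None:
            stage1 = Stage1Observation(
                xbar1={
                    k: float(v) for k, v in _int_keys(raw["stage1"], "stage1").items()
                }
            )
        plans = _require(raw, "plans", "root")
        plan_noadd = make_plan(
            design, NO_ADD, _int_keys(_require(plans, "no_add", "plans"), "plans.no_add")
        )
        add_total = plans.get("add_total")
        plan_add = make_plan(
            design,
            ADD,
            _int_keys(_require(plans, "add", "plans"), "plans.add"),
            total=None if add_total is None else int(add_total),
        )
        utility = raw.get("utility", "count")
        if utility not in UTILITY_KINDS:
            raise ConfigError(f"utility must be one of {UTILITY_KINDS}, got {utility!r}")
        epsilon = float(raw.get("epsilon", 0.01))
        simulation = None
        if raw.get("simulation") is not None:
            s = raw["simulation"]
            tm = s.get("true_means")
            simulation = SimulationSettings(
                n_sims=int(_require(s, "n_sims", "simulation")),
                seed=int(_require(s, "seed", "simulation")),
                policy=s.get("policy", "never_add"),
                true_means=None
                if tm is None
                else {k: float(v) for k, v in _int_keys(tm, "simulation.true_means").items()},
            )
        return RunConfig(
            design=design,
            priors=priors,
            stage1=stage1,
            plan_add=plan_add,
            plan_noadd=plan_noadd,
            utility=utility,
            epsilon=epsilon,
            grids=dict(raw.get("grids") or {}),
            simulation=simulation,
        )
    except ConfigError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc


def to_dict(cfg: RunConfig) -> dict[str, Any]:
    """Serialise a :class:`RunConfig` back to a plain mapping."""
    out: dict[str, Any] = {
        "design": {
            "K": cfg.design.K,
            "n1": dict(cfg.design.n1),
            "sigma2": dict(cfg.design.sigma2),
            "alpha": cfg.design.alpha,
            "N2": cfg.design.N2,
        },
        "priors": {
            k: {"mean": p.mean, "variance": p.variance} for k, p in cfg.priors.items()
        },
        "plans": {
            "no_add": dict(cfg.plan_noadd.n2),
            "add": dict(cfg.plan_add.n2),
        },
        "utility": cfg.utility,
        "epsilon": cfg.epsilon,
    }
    if cfg.plan_add.total != cfg.design.N2:
        out["plans"]["add_total"] = cfg.plan_add.total
    if cfg.stage1 is not None:
        out["stage1"] = dict(cfg.stage1.xbar1)
    if cfg.grids:
        out["grids"] = dict(cfg.grids)
    if cfg.simulation is not None:
        out["simulation"] = {
            "n_sims": cfg.simulation.n_sims,
            "seed": cfg.simulation.seed,
            "policy": cfg.simulation.policy,
        }
        if cfg.simulation.true_means is not None:
            out["simulation"]["true_means"] = dict(cfg.simulation.true_means)
    return out


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run configuration."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raise ConfigError(f"{path} is empty")
    return from_dict(raw)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a run configuration as YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(cfg), fh, sort_keys=True)
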