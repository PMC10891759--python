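"""Scenario configuration schema and end-to-end runner.

A scenario bundles one or more (population, regimen) groups with shared
simulation settings and a list of requested outputs.  Scenarios are JSON
documents validated by a pydantic schema (violations are reported with
field paths); a set of packaged scenarios covers the source study arms,
the renal-failure box-plot comparison and the pediatric age-band sweep.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, ValidationError, field_validator

from . import __version__, engine, nca
from .drug import nadolol_parameters
from .physiology import PopulationSpec, sample_population
from .validation import load_study_arms

__all__ = [
    "PopulationConfig",
    "RegimenConfig",
    "SettingsConfig",
    "GroupConfig",
    "ScenarioConfig",
    "load_scenario",
    "list_scenarios",
    "validate_config",
    "run_scenario",
]


class PopulationConfig(BaseModel):
    n: int = Field(100, ge=1)
    age_range: tuple[float, float]
    female_fraction: float = Field(0.0, ge=0.0, le=1.0)
    health_state: Literal["healthy", "moderate_rf", "severe_rf", "pediatric"] = "healthy"
    weight_range: tuple[float, float] | None = None
    iiv_cv: float = Field(0.16, ge=0.0)

    @field_validator("age_range", "weight_range")
    @classmethod
    def _ordered(cls, v):
        if v is not None and v[0] > v[1]:
            raise ValueError("range must be (low, high)")
        return v


class RegimenConfig(BaseModel):
    route: Literal["iv_bolus", "oral"]
    dose_mg: float = Field(gt=0)
    per_kg: bool = False
    n_doses: int = Field(1, ge=1)
    interval_h: float = Field(24.0, gt=0)
    duration_h: float = Field(48.0, gt=0)

    def build(self) -> engine.Regimen:
        events = tuple(
            engine.DoseEvent(self.route, self.dose_mg, i * self.interval_h, self.per_kg)
            for i in range(self.n_doses)
        )
        return engine.Regimen(events, self.duration_h, self.interval_h if self.n_doses > 1 else None)


class SettingsConfig(BaseModel):
    output_step_h: float = Field(0.1, gt=0)
    rtol: float = Field(1e-6, gt=0)
    atol: float = Field(1e-8, gt=0)
    method: Literal["expm", "lsoda"] = "expm"

    def build(self, seed: int) -> engine.SimulationSettings:
        return engine.SimulationSettings(
            output_step_h=self.output_step_h,
            rtol=self.rtol,
            atol=self.atol,
            method=self.method,
            seed=seed,
        )


class GroupConfig(BaseModel):
    name: str
    population: PopulationConfig
    regimen: RegimenConfig


class ScenarioConfig(BaseModel):
    name: str
    groups: list[GroupConfig] = Field(min_length=1)
    settings: SettingsConfig = SettingsConfig()
    outputs: list[Literal["profiles", "nca", "vpc", "boxstats"]] = [
        "profiles",
        "nca",
        "vpc",
        "boxstats",
    ]

    @field_validator("groups")
    @classmethod
    def _unique_names(cls, v):
        names = [g.name for g in v]
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")
        return v


def _packaged_scenario_files() -> dict[str, str]:
    root = resources.files("nadolol_pbpk.data.scenarios")
    return {p.name.removesuffix(".json"): p.name for p in root.iterdir() if p.name.endswith(".json")}


def _study_arm_scenarios() -> dict[str, ScenarioConfig]:
    """One scenario per packaged clinical study arm."""
    out = {}
    for arm in load_study_arms().itertuples():
        route = "iv" if arm.route == "iv_bolus" else "oral"
        name = f"study_{arm.block}_{int(arm.row):02d}_{route}_{arm.dose_mg:g}mg"
        weight_range = None
        if np.isfinite(arm.wt_lo) and np.isfinite(arm.wt_hi):
            weight_range = (float(arm.wt_lo), float(arm.wt_hi))
        pop = PopulationConfig(
            n=100,
            age_range=(float(arm.age_lo), float(arm.age_hi)),
            female_fraction=float(arm.female_fraction),
            weight_range=weight_range,
        )
        reg = RegimenConfig(
            route=arm.route,
            dose_mg=float(arm.dose_mg),
            n_doses=7 if arm.steady_state else 1,
            duration_h=float(arm.duration_h),
        )
        out[name] = ScenarioConfig(name=name, groups=[GroupConfig(name="study", population=pop, regimen=reg)])
    return out


@lru_cache(maxsize=1)
def _registry() -> dict[str, ScenarioConfig]:
    reg = {}
    for name, fname in _packaged_scenario_files().items():
        with resources.files("nadolol_pbpk.data.scenarios").joinpath(fname).open() as fh:
            reg[name] = ScenarioConfig.model_validate(json.load(fh))
    reg.update(_study_arm_scenarios())
    return reg


def list_scenarios() -> list[str]:
    """Names of all packaged scenarios (named workflows + every study arm)."""
    return sorted(_registry())


def load_scenario(name: str) -> ScenarioConfig:
    try:
        return _registry()[name]
    except KeyError:
        raise KeyError(f"unknown scenario {name!r}; see list_scenarios()") from None


def validate_config(document: dict) -> ScenarioConfig:
    """Validate a scenario document; raises pydantic.ValidationError with
    field paths on schema violations."""
    return ScenarioConfig.model_validate(document)


def _mass_balance_error(model: engine.ModelSystem, traj: pd.DataFrame) -> float:
    amounts = traj[list(model.state_names)].to_numpy().sum(axis=1)
    administered = traj["administered_mg"].to_numpy()
    ok = administered > 0
    if not ok.any():
        return 0.0
    return float(np.max(np.abs(amounts[ok] - administered[ok]) / administered[ok]))


def run_scenario(
    config: ScenarioConfig,
    seed: int = 1,
    out_dir: str | Path | None = None,
    n_override: int | None = None,
) -> dict:
    """Run a scenario end to end; deterministic given the seed.

    Returns a bundle with per-group NCA tables, VPC/box summaries and a run
    log (inputs, seed, version, mass-balance check); writes CSV/JSON files
    when ``out_dir`` is given.
    """
    drug = nadolol_parameters()
    settings = config.settings.build(seed)
    bundle: dict = {"name": config.name, "seed": seed, "groups": {}}
    boxstat_rows = []
    mass_balance_max = 0.0

    for g_idx, group in enumerate(config.groups):
        pop_cfg = group.population
        spec = PopulationSpec(
            n=n_override or pop_cfg.n,
            age_range=pop_cfg.age_range,
            female_fraction=pop_cfg.female_fraction,
            health_state=pop_cfg.health_state,
            weight_range=pop_cfg.weight_range,
            seed=seed * 1000 + g_idx,
            iiv_cv=pop_cfg.iiv_cv,
        )
        population = sample_population(spec)
        regimen = group.regimen.build()
        profiles = engine.simulate_population(population, drug, regimen, settings)

        # mass-balance audit on the first subject of each group
        model0 = engine.build_model(population[0], drug)
        _, traj = engine.simulate(model0, regimen, settings, full_output=True)
        mass_balance_max = max(mass_balance_max, _mass_balance_error(model0, traj))

        route = "iv" if group.regimen.route == "iv_bolus" else "oral"
        nca_rows = []
        for indiv, p in zip(population, profiles):
            dose = group.regimen.dose_mg * (indiv.body_weight_kg if group.regimen.per_kg else 1.0)
            pk = nca.run_nca(p, dose, route=route)
            nca_rows.append(
                {
                    "scenario": config.name,
                    "group": group.name,
                    "subject_id": p.subject_id,
                    "cmax_ng_ml": pk.cmax,
                    "tmax_h": pk.tmax_h,
                    "auc_0_t": pk.auc_0_t,
                    "auc_0_inf": pk.auc_0_inf,
                    "cl_ml_min": pk.cl_ml_min,
                    "t_half_h": pk.t_half_h,
                }
            )
        nca_df = pd.DataFrame(nca_rows)
        group_bundle = {"nca": nca_df, "profiles": profiles}
        if "vpc" in config.outputs:
            group_bundle["vpc"] = nca.vpc_summary(profiles) if len(profiles) > 1 else None
        if "boxstats" in config.outputs:
            box = nca.box_summary(nca_df["auc_0_t"])
            boxstat_rows.append(
                {
                    "scenario": config.name,
                    "group": group.name,
                    "quantity": "auc_0_t",
                    "median": box.median,
                    "q25": box.q25,
                    "q75": box.q75,
                    "whisker_low": box.whisker_low,
                    "whisker_high": box.whisker_high,
                    "mean": float(nca_df["auc_0_t"].mean()),
                }
            )
        bundle["groups"][group.name] = group_bundle

    bundle["boxstats"] = pd.DataFrame(boxstat_rows)
    bundle["mass_balance_max_rel_error"] = mass_balance_max

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for gname, gb in bundle["groups"].items():
            if "profiles" in config.outputs:
                pd.concat([p.to_frame() for p in gb["profiles"]], ignore_index=True).to_csv(
                    out / f"{gname}_profiles.csv", index=False
                )
            if "nca" in config.outputs:
                gb["nca"].to_csv(out / f"{gname}_nca.csv", index=False)
            if "vpc" in config.outputs and gb.get("vpc") is not None:
                gb["vpc"].to_frame().to_csv(out / f"{gname}_vpc.csv", index=False)
        if "boxstats" in config.outputs and len(bundle["boxstats"]):
            bundle["boxstats"].to_csv(out / "boxstats.csv", index=False)
        log = {
            "scenario": config.name,
            "seed": seed,
            "version": __version__,
            "n_override": n_override,
            "config": config.model_dump(),
            "mass_balance_max_rel_error": mass_balance_max,
            "mass_balance_ok": mass_balance_max <= 1e-6,
        }
        (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return bundle
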