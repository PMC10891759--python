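"""Virtual human physiology for whole-body PBPK simulation.

Provides a reference adult, chronic-kidney-disease (renal failure) scaling,
pediatric age scaling with renal maturation, and seeded virtual-population
sampling.  Organ volumes, regional blood flows and tissue composition are
shipped as a packaged reference table (ICRP-style adult, ~70 kg); all values
are overridable by constructing :class:`PhysiologyState` directly.

Units: volumes L, blood flows L/h, GFR mL/min, gastric emptying time min,
age years, body weight kg, height cm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OrganSpec",
    "PhysiologyState",
    "PopulationSpec",
    "reference_adult",
    "apply_renal_failure",
    "scale_to_age",
    "scale_to_weight",
    "sample_population",
    "gfr_maturation",
    "default_weight_for_age",
    "GFR_REFERENCE_ML_MIN",
    "REFERENCE_BODY_WEIGHT_KG",
    "BLOOD_COMPARTMENTS",
    "RenalFailureSeverity",
]

#: Healthy adult reference GFR used to normalise renal clearance scaling.
GFR_REFERENCE_ML_MIN = 120.0
#: Body weight of the packaged reference adult.
REFERENCE_BODY_WEIGHT_KG = 70.0
#: Compartments that hold blood rather than perfused tissue (flow field is 0;
#: they are excluded from the regional-flow balance).
BLOOD_COMPARTMENTS = frozenset({"arterial_blood", "venous_blood"})

#: Allometric exponent for blood flows, clearances and GFR size scaling.
ALLOMETRIC_EXPONENT = 0.75

# Hill-type renal maturation of GFR versus postmenstrual age (weeks).
GFR_MATURATION_TM50_WEEKS = 47.7
GFR_MATURATION_HILL = 3.4
TERM_GESTATION_WEEKS = 40.0
WEEKS_PER_YEAR = 52.1775

_FLOW_BALANCE_RTOL = 1e-6


class RenalFailureSeverity:
    MODERATE = "moderate"
    SEVERE = "severe"


#: Pathophysiology of chronic renal failure: GFR (mL/min), hematocrit,
#: gastric emptying time (min) for moderate and severe impairment.
RENAL_FAILURE_VALUES = {
    RenalFailureSeverity.MODERATE: {
        "gfr": 45.0,
        "hematocrit": 0.42,
        "gastric_emptying_min": 20.4,
    },
    RenalFailureSeverity.SEVERE: {
        "gfr": 18.0,
        "hematocrit": 0.39,
        "gastric_emptying_min": 24.6,
    },
}


@dataclass(frozen=True)
class OrganSpec:
    """One perfused compartment: volume, regional blood flow and composition.

    ``water``, ``lipid`` and ``protein`` are volume fractions used by the
    tissue-composition partition-coefficient calculation.
    """

    name: str
    volume_L: float
    flow_L_per_h: float
    water: float
    lipid: float
    protein: float

    def __post_init__(self) -> None:
        if self.volume_L <= 0:
            raise ValueError(f"organ {self.name!r}: volume must be > 0")
        if self.flow_L_per_h < 0:
            raise ValueError(f"organ {self.name!r}: flow must be >= 0")
        for frac_name in ("water", "lipid", "protein"):
            f = getattr(self, frac_name)
            if not 0.0 <= f <= 1.0:
                raise ValueError(
                    f"organ {self.name!r}: {frac_name} fraction must be in [0, 1]"
                )
        if self.water + self.lipid + self.protein > 1.0 + 1e-9:
            raise ValueError(
                f"organ {self.name!r}: composition fractions sum to more than 1"
            )


@dataclass(frozen=True)
class PhysiologyState:
    """One virtual individual.

    The regional flows of all systemic organs must sum to the cardiac output
    (carried by the lung compartment, which receives the entire venous
    return) to within 1e-6 relative.
    """

    organs: tuple[OrganSpec, ...]
    gfr: float  # mL/min
    hematocrit: float
    gastric_emptying_min: float
    age_y: float
    body_weight_kg: float
    height_cm: float
    sex: str = "male"

    def __post_init__(self) -> None:
        if self.gfr < 0:
            raise ValueError("gfr must be >= 0")
        if not 0.0 < self.hematocrit < 1.0:
            raise ValueError("hematocrit must be in (0, 1)")
        if self.gastric_emptying_min <= 0:
            raise ValueError("gastric emptying time must be > 0")
        names = [o.name for o in self.organs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate organ names")
        if "lung" not in names:
            raise ValueError("physiology requires a lung compartment")
        co = self.cardiac_output_L_per_h
        systemic = self.systemic_flow_L_per_h
        if co > 0 and abs(systemic - co) > _FLOW_BALANCE_RTOL * co:
            raise ValueError(
                "flow balance violated: systemic flows "
                f"{systemic:.6f} L/h vs cardiac output {co:.6f} L/h"
            )

    def organ(self, name: str) -> OrganSpec:
        for o in self.organs:
            if o.name == name:
                return o
        raise KeyError(name)

    @property
    def cardiac_output_L_per_h(self) -> float:
        return self.organ("lung").flow_L_per_h

    @property
    def systemic_flow_L_per_h(self) -> float:
        return sum(
            o.flow_L_per_h
            for o in self.organs
            if o.name != "lung" and o.name not in BLOOD_COMPARTMENTS
        )


@dataclass(frozen=True)
class PopulationSpec:
    """Specification of a virtual population for seeded sampling."""

    n: int
    age_range: tuple[float, float]
    female_fraction: float
    health_state: str = "healthy"  # healthy | moderate_rf | severe_rf | pediatric
    weight_range: tuple[float, float] | None = None
    seed: int = 0
    iiv_cv: float = 0.16  # log-normal CV on organ volumes, flows and GFR

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("population size n must be >= 1")
        lo, hi = self.age_range
        if not lo <= hi:
            raise ValueError("age_range must be non-empty")
        if self.weight_range is not None and not (
            self.weight_range[0] <= self.weight_range[1]
        ):
            raise ValueError("weight_range must be non-empty")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must be in [0, 1]")
        if self.health_state not in {"healthy", "moderate_rf", "severe_rf", "pediatric"}:
            raise ValueError(f"unknown health_state {self.health_state!r}")
        if self.iiv_cv < 0:
            raise ValueError("iiv_cv must be >= 0")


@lru_cache(maxsize=1)
def _organ_table() -> pd.DataFrame:
    with resources.files("nadolol_pbpk.data").joinpath("organs_reference.csv").open() as fh:
        return pd.read_csv(fh)


@lru_cache(maxsize=1)
def _pediatric_table() -> pd.DataFrame:
    with resources.files("nadolol_pbpk.data").joinpath("pediatric_reference.csv").open() as fh:
        return pd.read_csv(fh)


def reference_adult() -> PhysiologyState:
    """The packaged healthy adult reference (70 kg, 170 cm, 30 y, male).

    GFR 120 mL/min, hematocrit 0.45, gastric emptying 15 min; organ volumes,
    flows and composition from the packaged reference table.  Deterministic.
    """
    tbl = _organ_table()
    organs = tuple(
        OrganSpec(
            name=r.organ,
            volume_L=float(r.volume_L),
            flow_L_per_h=float(r.flow_L_per_h),
            water=float(r.water),
            lipid=float(r.lipid),
            protein=float(r.protein),
        )
        for r in tbl.itertuples()
    )
    return PhysiologyState(
        organs=organs,
        gfr=GFR_REFERENCE_ML_MIN,
        hematocrit=0.45,
        gastric_emptying_min=15.0,
        age_y=30.0,
        body_weight_kg=REFERENCE_BODY_WEIGHT_KG,
        height_cm=170.0,
    )


def apply_renal_failure(state: PhysiologyState, severity: str) -> PhysiologyState:
    """Impose chronic renal failure pathophysiology on an individual.

    Only GFR, hematocrit and gastric emptying time change (moderate: 45
    mL/min, 0.42, 20.4 min; severe: 18 mL/min, 0.39, 24.6 min); organs and
    demographics are untouched and the input is not mutated.
    """
    try:
        values = RENAL_FAILURE_VALUES[severity]
    except KeyError:
        raise ValueError(
            f"unknown renal failure severity {severity!r}; "
            f"expected one of {sorted(RENAL_FAILURE_VALUES)}"
        ) from None
    return replace(
        state,
        gfr=values["gfr"],
        hematocrit=values["hematocrit"],
        gastric_emptying_min=values["gastric_emptying_min"],
    )


def gfr_maturation(postmenstrual_age_weeks: float) -> float:
    """Fraction of size-normalised adult GFR reached at a postmenstrual age.

    Hill sigmoid with TM50 47.7 weeks and Hill coefficient 3.4 — the
    standard published renal maturation function.
    """
    pma = float(postmenstrual_age_weeks)
    if pma <= 0:
        return 0.0
    return pma**GFR_MATURATION_HILL / (
        GFR_MATURATION_TM50_WEEKS**GFR_MATURATION_HILL + pma**GFR_MATURATION_HILL
    )


def default_weight_for_age(age_y: float) -> float:
    """Median body weight (kg) for an age, interpolated from the packaged table."""
    tbl = _pediatric_table()
    return float(np.interp(age_y, tbl["age_y"], tbl["weight_kg"]))


def _hematocrit_for_age(age_y: float) -> float:
    tbl = _pediatric_table()
    return float(np.interp(age_y, tbl["age_y"], tbl["hematocrit"]))


def _volume_rel_fraction(organ: str, age_y: float) -> float:
    """Age multiplier on the weight-proportional organ volume fraction."""
    tbl = _pediatric_table()
    col = {"brain": "brain_rel", "muscle": "muscle_rel", "adipose": "adipose_rel"}.get(organ)
    if col is None:
        return 1.0
    return float(np.interp(age_y, tbl["age_y"], tbl[col]))


def scale_to_weight(state: PhysiologyState, body_weight_kg: float) -> PhysiologyState:
    """Rescale an adult template to a body weight.

    Volumes scale linearly with weight; flows and GFR allometrically with
    exponent 0.75.  Cardiac output is kept equal to the sum of systemic
    flows.
    """
    if body_weight_kg <= 0:
        raise ValueError("body weight must be > 0")
    frac = body_weight_kg / REFERENCE_BODY_WEIGHT_KG
    flow_frac = frac**ALLOMETRIC_EXPONENT
    systemic = [o for o in state.organs if o.name != "lung"]
    new_organs = []
    co = 0.0
    for o in systemic:
        q = o.flow_L_per_h * flow_frac
        if o.name not in BLOOD_COMPARTMENTS:
            co += q
        new_organs.append(replace(o, volume_L=o.volume_L * frac, flow_L_per_h=q))
    lung = state.organ("lung")
    new_organs.insert(0, replace(lung, volume_L=lung.volume_L * frac, flow_L_per_h=co))
    return replace(
        state,
        organs=tuple(new_organs),
        gfr=state.gfr * flow_frac,
        body_weight_kg=body_weight_kg,
    )


def scale_to_age(
    age_y: float, body_weight_kg: float, height_cm: float | None = None
) -> PhysiologyState:
    """Pediatric (or young-adult) physiology for a given age and weight.

    Organ volumes scale with the weight fraction of the adult reference,
    multiplied by age-band relative-fraction tables (brain proportionally
    larger in infants, muscle smaller, adipose larger); flows scale
    allometrically (weight^0.75).  GFR combines allometric size scaling with
    a Hill maturation sigmoid of postmenstrual age (postnatal age + 40
    weeks); hematocrit comes from a packaged age table.
    """
    if not 0 < age_y <= 18:
        raise ValueError("age must be in (0, 18] years")
    if body_weight_kg <= 0:
        raise ValueError("body weight must be > 0")
    ref = reference_adult()
    frac = body_weight_kg / REFERENCE_BODY_WEIGHT_KG
    flow_frac = frac**ALLOMETRIC_EXPONENT

    new_organs = []
    co = 0.0
    for o in ref.organs:
        if o.name == "lung":
            continue
        vol = o.volume_L * frac * _volume_rel_fraction(o.name, age_y)
        q = o.flow_L_per_h * flow_frac
        if o.name not in BLOOD_COMPARTMENTS:
            co += q
        new_organs.append(replace(o, volume_L=vol, flow_L_per_h=q))
    lung = ref.organ("lung")
    new_organs.insert(
        0,
        replace(
            lung,
            volume_L=lung.volume_L * frac * _volume_rel_fraction("lung", age_y),
            flow_L_per_h=co,
        ),
    )

    pma_weeks = age_y * WEEKS_PER_YEAR + TERM_GESTATION_WEEKS
    gfr = GFR_REFERENCE_ML_MIN * flow_frac * gfr_maturation(pma_weeks)

    if height_cm is None:
        # crude length-for-weight stand-in; height is not used by the engine
        height_cm = 170.0 * frac ** (1.0 / 3.0) * 1.15 if age_y < 18 else 170.0
        height_cm = min(height_cm, 180.0)

    return replace(
        ref,
        organs=tuple(new_organs),
        gfr=gfr,
        hematocrit=_hematocrit_for_age(age_y),
        age_y=age_y,
        body_weight_kg=body_weight_kg,
        height_cm=height_cm,
    )


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Median-preserving log-normal multiplier, truncated at +/-3 SD."""
    if cv == 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    z = float(np.clip(rng.standard_normal(), -3.0, 3.0))
    return math.exp(sigma * z)


def _perturb(state: PhysiologyState, rng: np.random.Generator, cv: float) -> PhysiologyState:
    """Apply log-normal inter-individual variability to volumes, flows, GFR."""
    new_organs = []
    co = 0.0
    for o in state.organs:
        if o.name == "lung":
            continue
        vol = o.volume_L * _lognormal_factor(rng, cv)
        q = o.flow_L_per_h * _lognormal_factor(rng, cv)
        if o.name not in BLOOD_COMPARTMENTS:
            co += q
        new_organs.append(replace(o, volume_L=vol, flow_L_per_h=q))
    lung = state.organ("lung")
    new_organs.insert(
        0,
        replace(
            lung,
            volume_L=lung.volume_L * _lognormal_factor(rng, cv),
            flow_L_per_h=co if co > 0 else lung.flow_L_per_h,
        ),
    )
    return replace(state, organs=tuple(new_organs), gfr=state.gfr * _lognormal_factor(rng, cv))


def sample_population(spec: PopulationSpec) -> list[PhysiologyState]:
    """Sample a seeded virtual population.

    Ages and weights are uniform within their ranges (weight defaults to the
    packaged weight-for-age +/- 20 % when no range is given), sex is
    Bernoulli(female_fraction), and log-normal inter-individual variability
    (CV ``spec.iiv_cv``, truncated at +/-3 SD) is applied to organ volumes,
    flows and GFR.  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    out: list[PhysiologyState] = []
    for _ in range(spec.n):
        age = float(rng.uniform(*spec.age_range))
        if spec.weight_range is not None:
            weight = float(rng.uniform(*spec.weight_range))
        else:
            weight = default_weight_for_age(age) * float(rng.uniform(0.8, 1.2))
        female = bool(rng.random() < spec.female_fraction)
        if age < 18.0:
            indiv = scale_to_age(age, weight)
        else:
            indiv = replace(scale_to_weight(reference_adult(), weight), age_y=age)
        if spec.health_state == "moderate_rf":
            indiv = apply_renal_failure(indiv, RenalFailureSeverity.MODERATE)
        elif spec.health_state == "severe_rf":
            indiv = apply_renal_failure(indiv, RenalFailureSeverity.SEVERE)
        indiv = _perturb(indiv, rng, spec.iiv_cv)
        indiv = replace(indiv, sex="female" if female else "male")
        out.append(indiv)
    return out
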