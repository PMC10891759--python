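"""Model qualification: predicted/observed ratios, average fold error,
twofold acceptance, and the packaged observed PK parameter tables.

The package ships the printed predicted and observed Cmax, AUC_0-t and CL
cells of the source clinical studies (healthy adults IV/oral, pediatrics
IV/oral) together with the study demographics needed to re-simulate the
adult arms.  Observed CL values are carried opaquely: the printed oral and
pediatric CL columns are not dimensionally consistent with Dose/AUC in the
stated units, so CL never enters unit conversions here.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import engine, nca
from .drug import nadolol_parameters
from .physiology import PopulationSpec, sample_population

__all__ = [
    "ratio",
    "afe",
    "twofold_check",
    "TwofoldSummary",
    "qualification_report",
    "load_observed_table",
    "load_afe_table",
    "load_study_arms",
    "printed_ratio_report",
    "afe_by_group",
    "simulate_study_arm",
    "simulated_qualification",
    "KNOWN_PRINT_DISCREPANCIES",
]

#: Cells of the packaged observed table whose printed ratio deviates by more
#: than +/-0.011 from predicted/observed recomputed at full precision
#: (apparent truncation or typographical errors in the source; the largest,
#: pediatric IV row 2 CL, prints 0.25 for 0.07/2.7 = 0.026).
KNOWN_PRINT_DISCREPANCIES = frozenset(
    {
        ("iv_healthy", 4, "cmax"),
        ("oral_healthy", 6, "cmax"),
        ("oral_healthy", 6, "auc"),
        ("iv_pediatric", 1, "cl"),
        ("iv_pediatric", 2, "cl"),
        ("oral_pediatric", 3, "cmax"),
    }
)


#: Arms whose printed observations reflect unreported dosing/sampling
#: schedules and are therefore flagged, not scored, in simulation-based
#: twofold checks.  Evidence from the printed numbers alone: the B39 30 mg
#: arm's observed AUC (1830.7) is 2.2-2.6x the four other single-dose 30 mg
#: arms (716-840), and the source's own prediction for that arm (1583) is
#: likewise ~2.2x its predictions for the identical regimen elsewhere.
SIM_TWOFOLD_FLAGGED_ARMS = frozenset({("oral_healthy", 6)})


def ratio(predicted: float, observed: float) -> float:
    """Predicted-to-observed ratio R; rejects non-positive observations."""
    if observed <= 0:
        raise ValueError("observed value must be > 0")
    return predicted / observed


def afe(ratios: Iterable[float]) -> float:
    """Average fold error: 10**(mean log10 ratio) = geometric mean of ratios."""
    arr = np.asarray(list(ratios), dtype=float)
    if arr.size == 0:
        raise ValueError("AFE of empty ratio list")
    if np.any(arr <= 0):
        raise ValueError("AFE requires strictly positive ratios")
    return float(10.0 ** np.mean(np.log10(arr)))


@dataclass(frozen=True)
class TwofoldSummary:
    ratios: tuple[float, ...]
    within: tuple[bool, ...]
    pass_fraction: float
    max_symmetric_fold_error: float


def twofold_check(ratios: Iterable[float]) -> TwofoldSummary:
    """Flag each ratio against the closed twofold interval [0.5, 2]."""
    arr = np.asarray(list(ratios), dtype=float)
    if arr.size == 0 or np.any(arr <= 0):
        raise ValueError("twofold check requires positive ratios")
    within = (arr >= 0.5) & (arr <= 2.0)
    sym = np.maximum(arr, 1.0 / arr)
    return TwofoldSummary(
        ratios=tuple(arr.tolist()),
        within=tuple(bool(w) for w in within),
        pass_fraction=float(within.mean()),
        max_symmetric_fold_error=float(sym.max()),
    )


def qualification_report(predicted: pd.DataFrame, observed: pd.DataFrame) -> pd.DataFrame:
    """Join predicted and observed parameter tables and compute R + twofold.

    Both frames are keyed by (block, row, parameter) with a ``value``
    column.  Keys present on one side only raise, listing the offenders.
    """
    keys = ["block", "row", "parameter"]
    for name, df in (("predicted", predicted), ("observed", observed)):
        missing_cols = set(keys + ["value"]) - set(df.columns)
        if missing_cols:
            raise ValueError(f"{name} table lacks columns {sorted(missing_cols)}")
    merged = predicted.merge(observed, on=keys, how="outer", suffixes=("_pred", "_obs"), indicator=True)
    bad = merged[merged["_merge"] != "both"]
    if len(bad):
        labels = [tuple(r) for r in bad[keys].itertuples(index=False)]
        raise ValueError(f"unmatched qualification keys: {labels}")
    out = merged.drop(columns="_merge").rename(
        columns={"value_pred": "predicted", "value_obs": "observed"}
    )
    out["ratio"] = out.apply(lambda r: ratio(r.predicted, r.observed), axis=1)
    out["within_twofold"] = (out["ratio"] >= 0.5) & (out["ratio"] <= 2.0)
    return out


@lru_cache(maxsize=1)
def load_observed_table() -> pd.DataFrame:
    with resources.files("nadolol_pbpk.data").joinpath("observed_pk.csv").open() as fh:
        return pd.read_csv(fh)


@lru_cache(maxsize=1)
def load_afe_table() -> pd.DataFrame:
    with resources.files("nadolol_pbpk.data").joinpath("afe_reference.csv").open() as fh:
        return pd.read_csv(fh)


@lru_cache(maxsize=1)
def load_study_arms() -> pd.DataFrame:
    with resources.files("nadolol_pbpk.data").joinpath("study_arms.csv").open() as fh:
        return pd.read_csv(fh)


def printed_ratio_report(tolerance: float = 0.0105) -> pd.DataFrame:
    """Recompute R for every packaged predicted/observed cell.

    Returns one row per (block, row, parameter) with the recomputed ratio,
    the printed ratio, and a ``consistent`` flag at the given tolerance
    (default covers truncation-vs-rounding of two printed decimals).
    """
    tbl = load_observed_table()
    rows = []
    for r in tbl.itertuples():
        for param in ("cmax", "auc", "cl"):
            pred = getattr(r, f"{param}_pred")
            obs = getattr(r, f"{param}_obs")
            printed = getattr(r, f"ratio_{param}")
            recomputed = ratio(pred, obs)
            rows.append(
                {
                    "block": r.block,
                    "row": r.row,
                    "parameter": param,
                    "predicted": pred,
                    "observed": obs,
                    "ratio": recomputed,
                    "ratio_printed": printed,
                    "consistent": abs(recomputed - printed) <= tolerance,
                    "known_discrepancy": (r.block, r.row, param) in KNOWN_PRINT_DISCREPANCIES,
                    "within_twofold": 0.5 <= recomputed <= 2.0,
                }
            )
    return pd.DataFrame(rows)


def afe_by_group(report: pd.DataFrame, use_printed: bool = True) -> pd.DataFrame:
    """AFE per {block} x {parameter} group from a ratio report."""
    col = "ratio_printed" if use_printed and "ratio_printed" in report.columns else "ratio"
    out = (
        report.groupby(["block", "parameter"])[col]
        .apply(lambda s: afe(s.values))
        .rename("afe")
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# simulation-based qualification of the adult healthy arms
# ---------------------------------------------------------------------------

def _arm_population(arm, n_subjects: int, seed: int) -> list:
    wt_lo, wt_hi = arm.wt_lo, arm.wt_hi
    weight_range = None
    if np.isfinite(wt_lo) and np.isfinite(wt_hi):
        weight_range = (float(wt_lo), float(wt_hi))
    spec = PopulationSpec(
        n=n_subjects,
        age_range=(float(arm.age_lo), float(arm.age_hi)),
        female_fraction=float(arm.female_fraction),
        weight_range=weight_range,
        seed=seed,
    )
    return sample_population(spec)


def simulate_study_arm(
    arm,
    n_subjects: int = 100,
    seed: int = 1,
    settings: engine.SimulationSettings = engine.SimulationSettings(),
) -> dict:
    """Simulate one packaged study arm and summarise predicted Cmax/AUC.

    Single-dose arms report AUC_0-t over the arm's sampling window; the
    steady-state arm simulates 7 once-daily doses and analyses the last
    interval.  Predictions are arithmetic means over the virtual population,
    matching how the observed study means are reported.
    """
    drug = nadolol_parameters()
    population = _arm_population(arm, n_subjects, seed)
    steady_state = bool(arm.steady_state)
    duration = float(arm.duration_h)
    if steady_state:
        regimen = engine.Regimen.once_daily_oral(float(arm.dose_mg), n_doses=7, duration_h=duration)
    elif arm.route == "iv_bolus":
        regimen = engine.Regimen.single_iv(float(arm.dose_mg), duration_h=duration)
    else:
        regimen = engine.Regimen.single_oral(float(arm.dose_mg), duration_h=duration)

    profiles = engine.simulate_population(population, drug, regimen, settings)
    cmaxes, aucs = [], []
    for p in profiles:
        if steady_state:
            # last dosing interval, re-referenced to the interval start
            mask = p.times_h >= duration - 24.0 - 1e-9
            p = engine.ConcentrationProfile(
                times_h=p.times_h[mask] - (duration - 24.0),
                conc_ng_ml=p.conc_ng_ml[mask],
                subject_id=p.subject_id,
            )
        pk = nca.run_nca(p, float(arm.dose_mg), route="iv" if arm.route == "iv_bolus" else "oral")
        cmaxes.append(pk.cmax)
        aucs.append(pk.auc_0_t)
    return {
        "block": arm.block,
        "row": int(arm.row),
        "cmax_sim": float(np.mean(cmaxes)),
        "auc_sim": float(np.mean(aucs)),
    }


def simulated_qualification(n_subjects: int = 100, seed: int = 1) -> pd.DataFrame:
    """Re-simulate every packaged adult arm and qualify against observations.

    Returns one row per (arm, parameter in {cmax, auc}) with the simulated
    prediction, the printed observation, R, and the twofold flag.  CL is
    excluded (opaque printed units); pediatric arms are not packaged here
    because their dosing/sampling schedules are not reconstructible.
    """
    arms = load_study_arms()
    obs = load_observed_table()
    rows = []
    for arm in arms.itertuples():
        sim = simulate_study_arm(arm, n_subjects=n_subjects, seed=seed + int(arm.row))
        o = obs[(obs.block == arm.block) & (obs.row == arm.row)].iloc[0]
        for param, sim_key in (("cmax", "cmax_sim"), ("auc", "auc_sim")):
            r = ratio(sim[sim_key], float(o[f"{param}_obs"]))
            rows.append(
                {
                    "block": arm.block,
                    "row": int(arm.row),
                    "parameter": param,
                    "predicted": sim[sim_key],
                    "observed": float(o[f"{param}_obs"]),
                    "ratio": r,
                    "within_twofold": 0.5 <= r <= 2.0,
                }
            )
    return pd.DataFrame(rows)
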