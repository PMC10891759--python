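"""Synthetic "observed" concentration-time studies.

The source clinical curves exist only as digitized figures, so end-to-end
testing of the NCA/VPC/qualification pipeline uses synthetic studies:
noise-free closed-form one- or two-compartment profiles (the analytic
oracle), plus seeded inter-individual variability on CL and V and a
proportional + additive measurement-noise model.  Ground-truth parameters
are returned alongside the data for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .engine import ConcentrationProfile

__all__ = ["SyntheticStudySpec", "closed_form_profile", "generate_observed_study"]

_EPS = 1e-12


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Target kinetics, regimen, sampling and noise for a synthetic study."""

    cl_ml_min: float
    v_central_l: float
    dose_mg: float
    route: str = "iv"  # iv | oral
    v_peripheral_l: float = 0.0
    q_inter_l_h: float = 0.0
    ka_per_h: float = 1.0
    f_oral: float = 1.0
    sampling_times_h: tuple[float, ...] = tuple(np.round(np.arange(0.0, 48.1, 0.5), 6))
    n_subjects: int = 1
    iiv_cv: float = 0.20  # log-normal CV on CL and V
    prop_cv: float = 0.10  # proportional measurement noise
    additive_floor_ng_ml: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.route not in ("iv", "oral"):
            raise ValueError(f"unknown route {self.route!r}")
        for name in ("cl_ml_min", "v_central_l", "dose_mg", "ka_per_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.v_peripheral_l < 0 or self.q_inter_l_h < 0:
            raise ValueError("peripheral parameters must be >= 0")
        if not 0.0 < self.f_oral <= 1.0:
            raise ValueError("f_oral must be in (0, 1]")
        if self.iiv_cv < 0 or self.prop_cv < 0 or self.additive_floor_ng_ml < 0:
            raise ValueError("variability/noise terms must be >= 0")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


def _macro_rates(cl_l_h: float, vc: float, vp: float, q: float) -> tuple[float, float, float]:
    """Hybrid rate constants (alpha, beta) and k21 of the two-compartment model."""
    k10 = cl_l_h / vc
    if vp <= 0 or q <= 0:
        return k10, 0.0, 0.0
    k12 = q / vc
    k21 = q / vp
    s = k10 + k12 + k21
    disc = math.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    return alpha, beta, k21


def closed_form_profile(
    spec: SyntheticStudySpec,
    cl_ml_min: float | None = None,
    v_central_l: float | None = None,
    subject_id: str = "subject-0",
) -> ConcentrationProfile:
    """Noise-free analytic profile for one subject.

    IV bolus: mono-/bi-exponential disposition.  Oral: first-order input at
    ka on top of the same disposition.  Near-degenerate rate constants fall
    back to the limiting (t·exp) form.
    """
    cl = spec.cl_ml_min if cl_ml_min is None else cl_ml_min
    vc = spec.v_central_l if v_central_l is None else v_central_l
    cl_l_h = cl * 0.06
    t = np.asarray(spec.sampling_times_h, dtype=float)
    dose_ng = spec.dose_mg * 1e6
    vc_ml = vc * 1000.0

    alpha, beta, k21 = _macro_rates(cl_l_h, vc, spec.v_peripheral_l, spec.q_inter_l_h)
    one_compartment = beta == 0.0 and k21 == 0.0

    if spec.route == "iv":
        if one_compartment:
            c = dose_ng / vc_ml * np.exp(-alpha * t)
        elif alpha - beta < _EPS * alpha:
            # degenerate eigenvalues: limiting form of the bi-exponential
            c = dose_ng / vc_ml * np.exp(-alpha * t) * (1.0 + (alpha - k21) * t)
        else:
            a = (alpha - k21) / (alpha - beta)
            b = (k21 - beta) / (alpha - beta)
            c = dose_ng / vc_ml * (a * np.exp(-alpha * t) + b * np.exp(-beta * t))
    else:
        ka = spec.ka_per_h
        scale = spec.f_oral * dose_ng / vc_ml
        if one_compartment:
            ke = alpha
            if abs(ka - ke) < _EPS * max(ka, ke):
                c = scale * ka * t * np.exp(-ka * t)
            else:
                c = scale * ka / (ka - ke) * (np.exp(-ke * t) - np.exp(-ka * t))
        else:
            # nudge ka off a resonance with either hybrid rate constant
            for lam in (alpha, beta):
                if abs(ka - lam) < 1e-9 * max(ka, lam):
                    ka *= 1.0 + 1e-9
            c = (
                scale
                * ka
                * (
                    (k21 - alpha) / ((ka - alpha) * (beta - alpha)) * np.exp(-alpha * t)
                    + (k21 - beta) / ((ka - beta) * (alpha - beta)) * np.exp(-beta * t)
                    + (k21 - ka) / ((alpha - ka) * (beta - ka)) * np.exp(-ka * t)
                )
            )
    return ConcentrationProfile(
        times_h=t, conc_ng_ml=np.maximum(c, 0.0), subject_id=subject_id
    )


def generate_observed_study(
    spec: SyntheticStudySpec,
) -> tuple[list[ConcentrationProfile], pd.DataFrame]:
    """Seeded synthetic study: noisy profiles plus per-subject ground truth.

    CL and V_central receive median-preserving log-normal perturbations
    (CV ``iiv_cv``); measurements get proportional Gaussian noise
    (CV ``prop_cv``) plus additive noise at the quantification floor, and
    are clipped at zero.
    """
    rng = np.random.default_rng(spec.seed)
    sigma = math.sqrt(math.log(1.0 + spec.iiv_cv**2)) if spec.iiv_cv > 0 else 0.0
    profiles: list[ConcentrationProfile] = []
    truth_rows = []
    for i in range(spec.n_subjects):
        cl_i = spec.cl_ml_min * math.exp(sigma * rng.standard_normal()) if sigma else spec.cl_ml_min
        v_i = spec.v_central_l * math.exp(sigma * rng.standard_normal()) if sigma else spec.v_central_l
        clean = closed_form_profile(spec, cl_i, v_i, subject_id=f"subject-{i}")
        c = clean.conc_ng_ml.copy()
        if spec.prop_cv > 0:
            c = c * (1.0 + spec.prop_cv * rng.standard_normal(c.shape))
        if spec.additive_floor_ng_ml > 0:
            c = c + spec.additive_floor_ng_ml * rng.standard_normal(c.shape)
        profiles.append(
            ConcentrationProfile(
                times_h=clean.times_h,
                conc_ng_ml=np.maximum(c, 0.0),
                subject_id=clean.subject_id,
            )
        )
        truth_rows.append({"subject_id": clean.subject_id, "cl_ml_min": cl_i, "v_central_l": v_i})
    return profiles, pd.DataFrame(truth_rows)
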