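import math
from dataclasses import replace

import numpy as np
import pytest

from nadolol_pbpk.physiology import (
    GFR_REFERENCE_ML_MIN,
    OrganSpec,
    PopulationSpec,
    apply_renal_failure,
    default_weight_for_age,
    gfr_maturation,
    reference_adult,
    sample_population,
    scale_to_age,
    scale_to_weight,
)


def flow_balance_ok(state):
    return math.isclose(
        state.systemic_flow_L_per_h, state.cardiac_output_L_per_h, rel_tol=1e-6
    )


class TestReferenceAdult:
    def test_packaged_reference_values(self, ref_adult):
        assert ref_adult.gfr == 120.0
        assert 0.0 < ref_adult.hematocrit < 1.0
        assert ref_adult.gastric_emptying_min == 15.0
        assert len(ref_adult.organs) >= 14
        assert flow_balance_ok(ref_adult)

    def test_deterministic(self):
        a, b = reference_adult(), reference_adult()
        assert a == b


class TestOrganSpec:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(volume_L=-1.0),
            dict(flow_L_per_h=-1.0),
            dict(water=1.2),
            dict(water=0.7, lipid=0.3, protein=0.2),  # fractions sum > 1
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        base = dict(name="x", volume_L=1.0, flow_L_per_h=1.0, water=0.7, lipid=0.1, protein=0.1)
        with pytest.raises(ValueError):
            OrganSpec(**{**base, **kwargs})


class TestRenalFailure:
    @pytest.mark.parametrize(
        "severity,gfr,hct,get",
        [("moderate", 45.0, 0.42, 20.4), ("severe", 18.0, 0.39, 24.6)],
    )
    def test_pathophysiology_values(self, ref_adult, severity, gfr, hct, get):
        rf = apply_renal_failure(ref_adult, severity)
        assert rf.gfr == gfr
        assert rf.hematocrit == hct
        assert rf.gastric_emptying_min == get

    def test_only_three_fields_change(self, ref_adult):
        rf = apply_renal_failure(ref_adult, "moderate")
        assert rf.organs == ref_adult.organs
        assert rf.body_weight_kg == ref_adult.body_weight_kg
        assert ref_adult.gfr == 120.0  # input not mutated

    def test_idempotent_per_severity(self, ref_adult):
        once = apply_renal_failure(ref_adult, "severe")
        twice = apply_renal_failure(once, "severe")
        assert once == twice

    def test_unknown_severity_rejected(self, ref_adult):
        with pytest.raises(ValueError, match="severity"):
            apply_renal_failure(ref_adult, "mild")


class TestPediatricScaling:
    def test_adult_age_recovers_reference_gfr(self):
        state = scale_to_age(18.0, 70.0, 170.0)
        assert state.gfr == pytest.approx(GFR_REFERENCE_ML_MIN, rel=0.02)

    def test_infant_gfr_below_adult(self):
        infant = scale_to_age(0.25, 6.4)
        assert infant.gfr < GFR_REFERENCE_ML_MIN
        assert flow_balance_ok(infant)

    def test_ten_year_old_gfr_matches_documented_formula(self):
        # independent evaluation of the maturation model: allometric size
        # scaling times the Hill sigmoid of postmenstrual age
        age, weight = 10.0, 32.0
        pma = age * 52.1775 + 40.0
        expected = 120.0 * (weight / 70.0) ** 0.75 * pma**3.4 / (47.7**3.4 + pma**3.4)
        assert scale_to_age(age, weight).gfr == pytest.approx(expected, rel=1e-12)

    def test_gfr_monotone_in_age_at_default_weights(self):
        ages = np.linspace(0.05, 18.0, 60)
        gfrs = [scale_to_age(a, default_weight_for_age(a)).gfr for a in ages]
        assert all(g2 >= g1 for g1, g2 in zip(gfrs, gfrs[1:]))

    def test_maturation_saturates(self):
        assert gfr_maturation(18 * 52.1775 + 40) > 0.999
        assert gfr_maturation(0.0) == 0.0

    @pytest.mark.parametrize("age,weight", [(0.0, 10.0), (-1.0, 10.0), (5.0, -3.0), (19.0, 70.0)])
    def test_invalid_inputs_rejected(self, age, weight):
        with pytest.raises(ValueError):
            scale_to_age(age, weight)

    def test_flow_balance_across_ages(self):
        for age in (0.25, 1.0, 4.0, 9.0, 14.0, 17.5):
            assert flow_balance_ok(scale_to_age(age, default_weight_for_age(age)))


class TestPopulationSampling:
    SPEC = PopulationSpec(n=100, age_range=(18, 74), female_fraction=0.25, seed=42)

    def test_seeded_determinism(self):
        assert sample_population(self.SPEC) == sample_population(self.SPEC)

    def test_different_seeds_differ(self):
        other = replace(self.SPEC, seed=43)
        assert sample_population(self.SPEC) != sample_population(other)

    def test_demographics(self):
        pop = sample_population(PopulationSpec(n=100, age_range=(18, 74), female_fraction=0.25, seed=1))
        ages = [p.age_y for p in pop]
        assert min(ages) >= 18 and max(ages) <= 74
        n_female = sum(p.sex == "female" for p in pop)
        # binomial(100, 0.25) central 99% interval
        assert 14 <= n_female <= 37

    def test_zero_variance_limit_equals_template(self):
        spec = PopulationSpec(
            n=1, age_range=(30, 30), weight_range=(70, 70), female_fraction=0.0, seed=5, iiv_cv=0.0
        )
        indiv = sample_population(spec)[0]
        template = scale_to_weight(reference_adult(), 70.0)
        assert indiv.gfr == template.gfr
        assert indiv.organs == template.organs

    def test_sampled_individuals_keep_flow_balance(self):
        pop = sample_population(PopulationSpec(n=20, age_range=(18, 74), female_fraction=0.5, seed=7))
        assert all(flow_balance_ok(p) for p in pop)

    def test_rf_population_gets_scaled_gfr(self):
        pop = sample_population(
            PopulationSpec(n=30, age_range=(18, 74), female_fraction=0.25, health_state="severe_rf", seed=2)
        )
        gfrs = np.array([p.gfr for p in pop])
        assert np.median(gfrs) == pytest.approx(18.0, rel=0.2)
        assert all(p.hematocrit == 0.39 for p in pop)

    def test_invalid_population_rejected(self):
        with pytest.raises(ValueError):
            PopulationSpec(n=0, age_range=(18, 74), female_fraction=0.25)
        with pytest.raises(ValueError):
            PopulationSpec(n=5, age_range=(18, 74), female_fraction=1.5)
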