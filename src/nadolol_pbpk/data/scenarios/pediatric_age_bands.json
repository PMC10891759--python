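{
  "name": "pediatric_age_bands",
  "groups": [
    {
      "name": "infants_iv",
      "population": {"n": 100, "age_range": [0.1, 1], "female_fraction": 0.5, "health_state": "pediatric"},
      "regimen": {"route": "iv_bolus", "dose_mg": 0.32, "duration_h": 96}
    },
    {
      "name": "toddlers_iv",
      "population": {"n": 100, "age_range": [2, 4], "female_fraction": 0.5, "health_state": "pediatric"},
      "regimen": {"route": "iv_bolus", "dose_mg": 0.32, "duration_h": 96}
    },
    {
      "name": "middle_childhood_iv",
      "population": {"n": 100, "age_range": [6, 11], "female_fraction": 0.5, "health_state": "pediatric"},
      "regimen": {"route": "iv_bolus", "dose_mg": 0.32, "duration_h": 96}
    },
    {
      "name": "young_teens_iv",
      "population": {"n": 100, "age_range": [12, 14], "female_fraction": 0.5, "health_state": "pediatric"},
      "regimen": {"route": "iv_bolus", "dose_mg": 0.32, "duration_h": 96}
    },
    {
      "name": "teenagers_iv",
      "population": {"n": 100, "age_range": [15, 17], "female_fraction": 0.5, "health_state": "pediatric"},
      "regimen": {"route": "iv_bolus", "dose_mg": 0.32, "duration_h": 96}
    },
    {
      "name": "infants_oral",
      "population": {"n": 100, "age_range": [0.1, 1], "female_fraction": 0.5, "health_state": "pediatric"},
      "regimen": {"route": "oral", "dose_mg": 5, "duration_h": 96}
    },
    {
      "name": "toddlers_oral",
      "population": {"n": 100, "age_range": [2, 4], "female_fraction": 0.5, "health_state": "pediatric"},
      "regimen": {"route": "oral", "dose_mg": 5, "duration_h": 96}
    },
    {
      "name": "middle_childhood_oral",
      "population": {"n": 100, "age_range": [6, 11], "female_fraction": 0.5, "health_state": "pediatric"},
      "regimen": {"route": "oral", "dose_mg": 5, "duration_h": 96}
    },
    {
      "name": "young_teens_oral",
      "population": {"n": 100, "age_range": [12, 14], "female_fraction": 0.5, "health_state": "pediatric"},
      "regimen": {"route": "oral", "dose_mg": 5, "duration_h": 96}
    },
    {
      "name": "teenagers_oral",
      "population": {"n": 100, "age_range": [15, 17], "female_fraction": 0.5, "health_state": "pediatric"},
      "regimen": {"route": "oral", "dose_mg": 5, "duration_h": 96}
    }
  ]
}
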