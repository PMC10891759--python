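{
  "name": "rf_boxplot_80mg",
  "groups": [
    {
      "name": "healthy",
      "population": {"n": 100, "age_range": [18, 74], "female_fraction": 0.25, "health_state": "healthy"},
      "regimen": {"route": "oral", "dose_mg": 80, "duration_h": 96}
    },
    {
      "name": "moderate_rf",
      "population": {"n": 100, "age_range": [18, 74], "female_fraction": 0.25, "health_state": "moderate_rf"},
      "regimen": {"route": "oral", "dose_mg": 80, "duration_h": 96}
    },
    {
      "name": "severe_rf",
      "population": {"n": 100, "age_range": [18, 74], "female_fraction": 0.25, "health_state": "severe_rf"},
      "regimen": {"route": "oral", "dose_mg": 80, "duration_h": 96}
    }
  ]
}
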