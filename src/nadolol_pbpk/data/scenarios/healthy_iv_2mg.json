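{
  "name": "healthy_iv_2mg",
  "groups": [
    {
      "name": "healthy",
      "population": {
        "n": 100,
        "age_range": [20, 27],
        "weight_range": [63.6, 96.6],
        "female_fraction": 0.0,
        "health_state": "healthy"
      },
      "regimen": {"route": "iv_bolus", "dose_mg": 2, "duration_h": 48}
    }
  ]
}
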