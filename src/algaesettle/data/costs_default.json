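{
  "centrifugation": {
    "energy_kwh_per_m3": 5.8,
    "energy_rate_usd_per_kwh": 0.33,
    "consumables_usd_per_m3": 0.0,
    "recovery_pct": 90.0
  },
  "sedimentation": {
    "energy_kwh_per_m3": 0.0,
    "energy_rate_usd_per_kwh": 0.0,
    "consumables_usd_per_m3": 0.42761,
    "recovery_pct": {"chlorella_sorokiniana": 96.14, "monoraphidium_convolutum": 88.7}
  },
  "dry_weight_mg_per_l": {
    "chlorella_sorokiniana": 439.33,
    "monoraphidium_convolutum": 682.0
  }
}
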