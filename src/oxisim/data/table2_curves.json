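{
  "description": "Linear pulse-oximeter calibration curves SaO2 = a - b*R for simulated finger transmittance and reflectance geometry at three skin pigmentation levels, plus a typical commercial transmittance algorithm. Intercepts in % SaO2, slopes in % per unit ratio-of-ratios.",
  "curves": [
    {"skin_type": "light", "mode": "transmittance", "intercept": 109.0, "slope": 25.44},
    {"skin_type": "light", "mode": "reflectance", "intercept": 110.8, "slope": 29.98},
    {"skin_type": "moderate", "mode": "transmittance", "intercept": 109.2, "slope": 32.05},
    {"skin_type": "moderate", "mode": "reflectance", "intercept": 108.4, "slope": 32.3},
    {"skin_type": "dark", "mode": "transmittance", "intercept": 110.6, "slope": 49.33},
    {"skin_type": "dark", "mode": "reflectance", "intercept": 114.9, "slope": 76.99},
    {"skin_type": "commercial", "mode": "commercial", "intercept": 110.0, "slope": 25.0}
  ]
}
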