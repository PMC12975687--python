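{
  "name": "CIB",
  "diameter_mm": 20.2,
  "notch": "iris",
  "point_spacing_mm": 3.37,
  "film_radius_mm": 16.0,
  "certified_ratio_pct": 55.3,
  "notch_start_radius_mm": 8.0,
  "notch_half_angle_deg": 25.0,
  "certified_cax": null
}
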