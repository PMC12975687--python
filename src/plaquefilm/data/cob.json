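{
  "name": "COB",
  "diameter_mm": 19.8,
  "notch": "optic",
  "point_spacing_mm": 3.3,
  "film_radius_mm": 16.0,
  "certified_ratio_pct": 58.1,
  "notch_start_radius_mm": 10.5,
  "notch_half_angle_deg": 25.0,
  "certified_cax": null
}
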