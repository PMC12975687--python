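{
  "name": "CCA",
  "diameter_mm": 15.3,
  "notch": "none",
  "point_spacing_mm": 2.55,
  "film_radius_mm": 14.0,
  "certified_ratio_pct": 57.0,
  "certified_cax": [
    [0.83, 1.35],
    [1.0, 1.3],
    [2.0, 1.0],
    [3.0, 0.74],
    [4.0, 0.52],
    [5.0, 0.36],
    [6.0, 0.23],
    [7.0, 0.15],
    [8.0, 0.09],
    [9.0, 0.05],
    [10.0, 0.03]
  ]
}
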