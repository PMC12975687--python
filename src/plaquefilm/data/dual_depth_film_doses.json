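{
  "_comment": "Film-measured central-axis doses (Gy) at 1 mm (first film) and 3 mm (second film) depth after 15-min irradiation, with the manufacturer-certified dual-depth ratio (%), per plaque model.",
  "CCA": {"dose_1mm_Gy": 179.5, "sd_1mm_Gy": 3.2, "dose_3mm_Gy": 103.0, "sd_3mm_Gy": 2.3, "certified_ratio_pct": 57.0},
  "COB": {"dose_1mm_Gy": 157.4, "sd_1mm_Gy": 1.1, "dose_3mm_Gy": 91.2, "sd_3mm_Gy": 1.4, "certified_ratio_pct": 58.1},
  "CIB": {"dose_1mm_Gy": 201.7, "sd_1mm_Gy": 2.3, "dose_3mm_Gy": 112.5, "sd_3mm_Gy": 2.0, "certified_ratio_pct": 55.3}
}
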