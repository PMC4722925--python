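{
  "description": "Published LQ parameters for F10B16 skin melanoma and 4T1 breast adenocarcinoma cells, derived from MTT survival assays under Co-60 irradiation at 0.81 Gy/min. t_half uncertainties are the reported standard errors.",
  "cell_lines": {
    "F10B16": {"name": "F10B16", "alpha": 0.0956, "beta": 0.0177, "t_half_h": 0.524, "t_half_se_h": 0.035},
    "4T1": {"name": "4T1", "alpha": 0.0424, "beta": 0.0399, "t_half_h": 0.344, "t_half_se_h": 0.015}
  }
}
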