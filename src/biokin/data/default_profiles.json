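{
  "_comment": "Whole-body masses are cohort means. Organ masses and blood volumes are literature ASSUMPTIONS (ICRP-style adult values; standard laboratory rodent and juvenile pig values) shipped only so that relative mass scaling (Method 2) can run; they are not measured study values. Mouse blood volume is deliberately absent: without it per-mL blood TIACs cannot be converted to whole-blood coefficients, so mass-based scaling of mouse blood is refused.",
  "mouse": {
    "m_wb": 0.026,
    "organ_masses": {"kidneys": 0.0004, "liver": 0.0014},
    "blood_volume_ml": null
  },
  "pig": {
    "m_wb": 28.0,
    "organ_masses": {"kidneys": 0.13, "liver": 0.7},
    "blood_volume_ml": 1800
  },
  "human": {
    "m_wb": 61.0,
    "organ_masses": {"kidneys": 0.31, "liver": 1.8},
    "blood_volume_ml": 4500
  }
}
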