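cohort:
  n_subjects: 127
  seed: 0
reference: {}
devices:
- name: tricorder
  vitals:
  - SBP
  - HR
  - SPO2
  bias:
    SBP: 2.0
    HR: 0.5
    SPO2: 1.0
  noise_sd:
    SBP: 4.0
    HR: 2.0
    SPO2: 2.5
  failure_prob: 0.37
  requires_calibration: true
  calibration_coupling: 0.5
- name: watch
  vitals:
  - SBP
  - DBP
  - HR
  slope:
    SBP: -0.5
    DBP: -0.4
  anchor:
    SBP: 125.0
    DBP: 76.0
  bias:
    HR: -2.0
  noise_sd:
    SBP: 12.0
    DBP: 7.0
    HR: 8.0
  failure_prob: 0.67
analysis: {}
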