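# Mean air-conduction profile used by the synthetic cohort generator: a
# moderately sloping loss close to the standard N3 audiogram shape, in
# dB HL at the 11 audiometric frequencies.
version: 1
thresholds_db_hl:
  125: 30.0
  250: 35.0
  500: 40.0
  750: 45.0
  1000: 50.0
  1500: 55.0
  2000: 60.0
  3000: 65.0
  4000: 70.0
  6000: 75.0
  8000: 80.0
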