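# Reference equivalent threshold sound pressure levels (RETSPL-style) used
# for the packaged dB HL <-> dB SPL conversion at the 11 audiometric
# frequencies.  Values follow the familiar supra-aural headphone dialect;
# exact per-site calibration is out of scope, so a single table is packaged
# and declared here.
dialect: supra-aural-generic
retspl_db:
  125: 45.0
  250: 25.5
  500: 13.5
  750: 9.0
  1000: 7.5
  1500: 7.5
  2000: 9.0
  3000: 10.0
  4000: 12.0
  6000: 16.0
  8000: 15.5
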