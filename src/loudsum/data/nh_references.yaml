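# Normal-hearing reference loudness-function parameters (versioned fixture).
#
# Narrowband (critical-band noise) references are defined by a two-anchor
# construction shared with the audiogram-based estimation of impaired
# functions: a "very soft" anchor (2.5 CU) at `very_soft_hl` dB HL and a
# "too loud" anchor (50 CU) at `top_anchor_hl` dB HL, both converted to
# dB SPL with the packaged transducer table.  The pivot (25 CU) sits at
# fraction `pivot_fraction` of the way from the low to the top anchor.
#
# Broadband binaural references are given directly as two-branch parameters
# in dB SPL.  The IFnoise reference is anchored so that it reaches 40 CU at
# exactly 82.3 dB SPL (l_cut + 15 / m_hi).
version: 1
narrowband:
  very_soft_hl: 2.0
  pivot_fraction: 0.55
  top_anchor_hl:
    125: 97.0
    250: 98.0
    500: 99.0
    750: 99.5
    1000: 100.0
    1500: 100.0
    2000: 100.5
    3000: 101.0
    4000: 101.0
    6000: 102.0
    8000: 102.0
broadband_binaural:
  IFnoise:
    l_cut: 67.3
    m_lo: 0.40
    m_hi: 1.00
  UEN17:
    l_cut: 70.0
    m_lo: 0.38
    m_hi: 0.95
  UEN5:
    l_cut: 75.0
    m_lo: 0.35
    m_hi: 0.85
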