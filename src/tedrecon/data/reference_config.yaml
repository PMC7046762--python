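# Reference dosimetry configuration.
#
# Ventilation volumes are the standard age-specific daily breathing volumes
# (m3/day).  Thyroid equivalent dose coefficients (Sv/Bq) are transcribed
# from the published age-dependent committed-equivalent-dose tables for
# iodine-131: inhalation by chemical form (particulate aerosol type F,
# elemental vapour, methyl iodide) and ingestion in drinking water.
# Verify against the primary ICRP tabulations before any production use;
# the test-suite uses synthetic round-number coefficients instead.
ventilation_m3_per_day:
  1y: 5.16
  5y: 8.72
  10y: 15.3
  adult: 22.2

dose_coefficients_sv_per_bq:
  inhalation:
    1y:    {particulate: 1.4e-6, elemental: 2.6e-6, methyl: 2.0e-6}
    5y:    {particulate: 7.3e-7, elemental: 1.4e-6, methyl: 1.1e-6}
    10y:   {particulate: 3.7e-7, elemental: 7.3e-7, methyl: 5.6e-7}
    adult: {particulate: 1.5e-7, elemental: 3.9e-7, methyl: 3.0e-7}
  ingestion:
    1y: 3.6e-6
    5y: 2.1e-6
    10y: 1.0e-6
    adult: 4.3e-7

correction_factors:
  fc_central: 0.62          # 18.5/30 uptake-rate correction
  fc_sd: 0.20               # 6.0/30
  df_shelter_central: 0.5   # construction-year-averaged sheltering factor
  df_triangular: [0.1, 0.5, 0.95]
  sf_central: 0.7           # 1 - 0.3 well-water share
  sf_binomial: [100, 0.3]
  sf_windows:
    - {start: 2011-03-12, end: 2011-03-13, multiplier: 1.59}
    - {start: 2011-03-15, end: 2011-03-16, multiplier: 1.08}
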