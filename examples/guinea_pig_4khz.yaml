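# Reference scenario: 40 um outer hair cell at the 4 kHz place of the
# guinea-pig cochlea.  All values are plain SI floats; see ohcamp.params.UNITS
# for the unit of each key.
physical:
  q: -1.28e-19        # motile charge per motor, C (-0.8 e)
  a: 6.7e-14          # length change per motor, m (0.67e-4 nm)
  N: 3.0e+7           # motor count
  C0: 3.0e-11         # structural capacitance, F (30 pF)
  sigma: 1.0e-8       # steady conductance, S (10 nS)
  i0: 3.0e-10         # standing transducer current, A (0.3 nA)
  ko: 0.017           # cell-body stiffness, N/m (17 mN/m)
  Ke: 0.020           # basilar-membrane stiffness per cell, N/m (20 mN/m)
  gx: 4.0e+7          # bundle sensitivity magnitude, 1/m (1/(25 nm))
  eta: 8.0e-8         # subtectorial drag, N s/m
  fr: 4000.0          # mechanical resonance frequency, Hz
  connectivity: series
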