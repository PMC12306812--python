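# Dimensionless figure-mode scenario: the reference-cell groups with the
# viscoelastic roll-off pinned at omega_eta/omega_r = 10, as used by the
# standard frequency-response plots.
dimensionless:
  ua: 0.13818143408981173
  Kbar_e: 0.5405405405405405
  alpha_c: 1.0
  omega_bar_eta: 10.0
  omega_bar_m: 0.013262911924324614
  g: -36.94054054054055
  ah1: 0.11355421781774185
  bh2: 0.9888942539835828
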