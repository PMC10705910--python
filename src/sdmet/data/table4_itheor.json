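{
  "description": "Theoretical MS intensities I_SD^Theor = 2.6388e-17 * sqrt(D_QC) for the common product ions of the silylated 4-desoxy-glucose structures (arbitrary instrument-independent units).",
  "itheor": {
    "45": 1.11e-07,
    "73": 4.72e-12,
    "103": 1.91e-07,
    "147": 3.22e-08,
    "205": 1.33e-07,
    "361": 1.24e-08
  }
}
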