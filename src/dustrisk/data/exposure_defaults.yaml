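# Receptor exposure parameters, standards-derived (HJ 25.3-2019 / USEPA
# conventions commonly used for Chinese urban road-dust assessments).
# Fuzzy parameters (IngR, InhR, BW) are triangular fuzzy numbers
# [minimum, most-expected, maximum]; all others are crisp.
# Units: IngR mg/day; InhR m3/day; BW kg; ED yr; EF days/yr; AT days;
# SA cm2; SSAR mg/(cm2 day); ABS unitless; PEF m3/kg.
receptors:
  adult:
    IngR: [50.0, 100.0, 150.0]
    InhR: [12.0, 14.5, 17.0]
    BW: [54.4, 61.8, 70.0]
    ED: 24.0
    EF: 350.0
    AT_nc: 8760.0      # ED * 365
    AT_ca: 25550.0     # 70-yr lifetime
    SA: 5373.0
    SSAR: 0.07
    ABS: 0.001
    PEF: 1.36e9
  child:
    IngR: [100.0, 200.0, 300.0]
    InhR: [5.0, 7.5, 10.0]
    BW: [15.0, 19.2, 24.0]
    ED: 6.0
    EF: 350.0
    AT_nc: 2190.0      # ED * 365
    AT_ca: 25550.0     # 70-yr lifetime
    SA: 2848.0
    SSAR: 0.2
    ABS: 0.001
    PEF: 1.36e9
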