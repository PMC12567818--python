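# Carcinogenic-risk classification scheme: ordered lower-closed,
# upper-open intervals from negligible (I, below 1e-6) to very high
# (V, 1e-4 and above). 'lower: -.inf' marks an open lower end.
levels:
  - {label: I, lower: -.inf, upper: 1.0e-6}
  - {label: II, lower: 1.0e-6, upper: 1.0e-5}
  - {label: III, lower: 1.0e-5, upper: 5.0e-5}
  - {label: IV, lower: 5.0e-5, upper: 1.0e-4}
  - {label: V, lower: 1.0e-4, upper: 1.0}
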