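# Toxicity parameters per metal x pathway, standards-derived (USEPA
# IRIS/RAIS values as conventionally used in road-dust risk studies).
# rfd: reference dose, mg/(kg d); sf: carcinogenic slope factor, kg d/mg.
# Metals without an entry are excluded from the corresponding endpoint
# (no HQ for Pb; CR only for Cd, Ni, As, Pb).
rfd:
  Cd: {ingestion: 1.0e-3, inhalation: 1.0e-3, dermal: 1.0e-5}
  Ni: {ingestion: 2.0e-2, inhalation: 2.06e-2, dermal: 5.4e-3}
  As: {ingestion: 3.0e-4, inhalation: 3.01e-4, dermal: 1.23e-4}
  Zn: {ingestion: 3.0e-1, inhalation: 3.0e-1, dermal: 6.0e-2}
  Cu: {ingestion: 4.0e-2, inhalation: 4.02e-2, dermal: 1.2e-2}
  Cr: {ingestion: 3.0e-3, inhalation: 2.86e-5, dermal: 6.0e-5}
sf:
  Cd: {ingestion: 6.1, inhalation: 6.3}
  Ni: {inhalation: 0.84}
  As: {ingestion: 1.5, inhalation: 15.1, dermal: 3.66}
  Pb: {ingestion: 8.5e-3}
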