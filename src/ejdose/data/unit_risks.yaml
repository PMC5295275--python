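# Inhalation unit risks (per ug/m^3) for the three-chemical mixture,
# with benzene as the index chemical.  Benzene's published risk is a
# range; its point value is taken as the range midpoint (5.0e-6),
# giving RPFs of 6 for 1,3-butadiene and 0.44 for acetaldehyde.
index_chemical: benzene
unit_risk:
  benzene: [2.2e-6, 7.8e-6]
  butadiene: 3.0e-5
  acetaldehyde: 2.2e-6
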