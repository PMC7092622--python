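provenance: >
  Standard transformed Gibbs energies of formation (pH 7, 25 C, 1 M / 1 atm)
  from the compilation of Thauer, Jungermann & Decker (1977), Bacteriol. Rev.
  41:100-180.  Midpoint potentials: CO2/CO and H+/H2 from the same
  compilation; clostridial ferredoxin set to -450 mV, the value consistent
  with the printed CO/ferredoxin and ferredoxin/H2 conversion energies.
  Each net mole of H+ produced contributes -7 * RT ln10 = -39.96 kJ.
delta_gf_prime:
  co: -137.2
  co2: -394.4
  h2: 0.0
  h2o: -237.2
  acetate: -369.4
  ethanol: -181.8
  butanediol: -322.0
  formate: -351.0
  lactate: -517.8
couples:
  co2_co: -520.0
  h_h2: -414.0
  fd: -450.0
  nad: -320.0
  nadp: -320.0
faraday: 96.485
rt_ln10: 5.708
reference_delta_g:
  net_r1: -175.0
  net_r2: -95.0
  net_r3: -224.0
  net_r4: -105.0
  net_r5: -388.0
  net_r6: -14.0
  net_r7: -7.0
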