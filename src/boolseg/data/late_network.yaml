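# Late (segment-polarity-resolving) network, analysed in simplified mode
# (all delays 0, opa frozen ON).  Assembled from the regulatory constraints
# the expression data support:
#   * slp and odd mutually repress (their co-expression is unstable);
#   * prd expression requires prior prd (autoactivation only);
#   * eve is maintained, never initiated (no secondary eve stripes);
#   * slp represses odd and ftz (their domains persist where slp is absent);
#   * opa gates the whole late regime.
# wg/en output logic: en where eve or ftz persist (excluded by slp and wg),
# wg where slp persists (excluded by en and odd).
genes: [eve, runt, odd, ftz, slp, prd, wg, en]
inputs: [opa]
delays:
  preset: simplified
rules:
  eve: "input(opa) AND protein(eve) AND NOT protein(slp) AND NOT protein(runt)"
  runt: "input(opa) AND NOT protein(eve) AND NOT protein(odd) AND NOT protein(ftz)"
  odd: "input(opa) AND NOT protein(slp) AND NOT protein(eve) AND NOT protein(en)"
  ftz: "input(opa) AND protein(ftz) AND NOT protein(slp) AND NOT protein(eve)"
  slp: "input(opa) AND NOT protein(odd) AND NOT protein(eve) AND NOT protein(ftz)"
  prd: "input(opa) AND protein(prd) AND NOT protein(odd)"
  wg: "input(opa) AND protein(slp) AND NOT protein(en) AND NOT protein(odd)"
  en: "input(opa) AND (protein(eve) OR protein(ftz)) AND NOT protein(slp) AND NOT protein(wg)"
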