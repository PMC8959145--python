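# Early pair-rule oscillator: the unique four-gene repression ring found by
# the exhaustive topology screen (each gene repressed by its two successors
# in the hairy -> eve -> runt -> odd cycle), with constitutive activation.
# The early regime runs while cad is on and opa off; once opa switches on,
# each gene latches its own protein state (the late, pattern-freezing regime).
genes: [hairy, eve, runt, odd]
inputs: [cad, D, opa]
delays:
  preset: framework
rules:
  hairy: "(input(cad) AND NOT input(opa) AND NOT protein(eve) AND NOT protein(runt)) OR (input(opa) AND protein(hairy))"
  eve: "(input(cad) AND NOT input(opa) AND NOT protein(runt) AND NOT protein(odd)) OR (input(opa) AND protein(eve))"
  runt: "(input(cad) AND NOT input(opa) AND NOT protein(odd) AND NOT protein(hairy)) OR (input(opa) AND protein(runt))"
  odd: "(input(cad) AND NOT input(opa) AND NOT protein(hairy) AND NOT protein(eve)) OR (input(opa) AND protein(odd))"
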