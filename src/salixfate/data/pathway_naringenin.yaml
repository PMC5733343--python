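# Gut-microbial degradation of naringenin glycosides: deglycosylation to the
# aglycone, C-ring fission to 3-(4-hydroxyphenyl)propionic acid plus
# phloroglucinol, then dehydroxylation / alpha-oxidation.  Phloroglucinol is
# further fermented to short-chain acids and 3-(4-hydroxyphenyl)propionic
# acid ionizes weakly in negative electrospray, so both carry
# expected_undetectable.  phenylpropionic acid is shared with the catechin
# route (same name and peak_id).
name: naringenin
nodes:
  - {name: naringenin-7-glucoside, peak_id: 47, formula: C21H22O10}
  - {name: "(+)-naringenin-5-glucoside", peak_id: 37, formula: C21H22O10}
  - {name: "(-)-naringenin-5-glucoside", peak_id: 41, formula: C21H22O10}
  - {name: naringenin, peak_id: 56, formula: C15H12O5}
  - {name: 3-(4-hydroxyphenyl)propionic acid, formula: C9H10O3, expected_undetectable: true}
  - {name: phloroglucinol, formula: C6H6O3, expected_undetectable: true}
  - {name: phenylpropionic acid, peak_id: 49, formula: C9H10O2}
  - {name: 4-hydroxybenzoic acid, peak_id: 15, formula: C7H6O3}
edges:
  - {from: naringenin-7-glucoside, to: naringenin, type: DEGLYCOSYLATION}
  - {from: "(+)-naringenin-5-glucoside", to: naringenin, type: DEGLYCOSYLATION}
  - {from: "(-)-naringenin-5-glucoside", to: naringenin, type: DEGLYCOSYLATION}
  - {from: naringenin, to: 3-(4-hydroxyphenyl)propionic acid, type: C_RING_CLEAVAGE}
  - {from: naringenin, to: phloroglucinol, type: C_RING_CLEAVAGE}
  - {from: 3-(4-hydroxyphenyl)propionic acid, to: phenylpropionic acid, type: DEHYDROXYLATION}
  - {from: 3-(4-hydroxyphenyl)propionic acid, to: 4-hydroxybenzoic acid, type: ALPHA_OXIDATION}
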