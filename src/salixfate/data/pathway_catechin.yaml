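# Gut-microbial degradation of catechin / flavan-3-ols: ring fission of the
# flavan C-ring yields phenyl-gamma-valerolactones and phenylvaleric acids,
# which are shortened and dehydroxylated to phenylpropionic acids and small
# phenolic acids.  peak_id refers to the bundled willow-bark compound
# library where the node was detected in that extract.
name: catechin
nodes:
  - {name: catechin, peak_id: 19, formula: C15H14O6}
  - {name: "(epi)gallocatechin", peak_id: 7, formula: C15H14O7}
  - {name: "5-(3',4',5'-trihydroxyphenyl)-gamma-valerolactone", peak_id: 13, formula: C11H12O5}
  - {name: "5-(dihydroxyphenyl)-gamma-valerolactone", peak_id: 28, formula: C11H12O4}
  - {name: 4-hydroxy-5-(dihydroxyphenyl)valeric acid, peak_id: 16, formula: C11H14O5}
  - {name: 4-oxo-5-(dihydroxyphenyl)valeric acid, peak_id: 20, formula: C11H12O5}
  - {name: 5-(dihydroxyphenyl)valeric acid, peak_id: 42, formula: C11H14O4}
  - {name: 4-hydroxy-5-(hydroxyphenyl)valeric acid, peak_id: 35, formula: C11H14O4}
  - {name: hydroxyphenylvaleric acid, peak_id: 54, formula: C11H14O3}
  - {name: dihydrocaffeic acid, peak_id: 17, formula: C9H10O4}
  - {name: 3-(3-hydroxyphenyl)propionic acid, peak_id: 34, formula: C9H10O3}
  - {name: phenylpropionic acid, peak_id: 49, formula: C9H10O2}
  - {name: protocatechuic acid, peak_id: 6, formula: C7H6O4}
edges:
  - {from: catechin, to: "5-(dihydroxyphenyl)-gamma-valerolactone", type: C_RING_CLEAVAGE}
  - {from: catechin, to: 4-hydroxy-5-(dihydroxyphenyl)valeric acid, type: C_RING_CLEAVAGE}
  - {from: "(epi)gallocatechin", to: "5-(3',4',5'-trihydroxyphenyl)-gamma-valerolactone", type: C_RING_CLEAVAGE}
  - {from: "5-(dihydroxyphenyl)-gamma-valerolactone", to: 4-oxo-5-(dihydroxyphenyl)valeric acid, type: OXIDATION}
  - {from: 4-oxo-5-(dihydroxyphenyl)valeric acid, to: 5-(dihydroxyphenyl)valeric acid, type: REDUCTION}
  - {from: 5-(dihydroxyphenyl)valeric acid, to: hydroxyphenylvaleric acid, type: DEHYDROXYLATION}
  - {from: 4-hydroxy-5-(hydroxyphenyl)valeric acid, to: hydroxyphenylvaleric acid, type: REDUCTION}
  - {from: 5-(dihydroxyphenyl)valeric acid, to: dihydrocaffeic acid, type: BETA_OXIDATION}
  - {from: dihydrocaffeic acid, to: 3-(3-hydroxyphenyl)propionic acid, type: DEHYDROXYLATION}
  - {from: hydroxyphenylvaleric acid, to: 3-(3-hydroxyphenyl)propionic acid, type: BETA_OXIDATION}
  - {from: dihydrocaffeic acid, to: protocatechuic acid, type: BETA_OXIDATION}
  - {from: 3-(3-hydroxyphenyl)propionic acid, to: phenylpropionic acid, type: DEHYDROXYLATION}
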