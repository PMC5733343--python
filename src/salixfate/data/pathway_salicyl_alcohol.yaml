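# Degradation of salicylic alcohol derivatives: hydrolytic cleavage of the
# glucoside releases saligenin (salicyl alcohol), which is oxidized to
# salicylic acid and further hydroxylated to gentisic acid.
name: salicyl_alcohol
nodes:
  - {name: salicin, peak_id: 10, formula: C13H18O7}
  - {name: saligenin, peak_id: 12, formula: C7H8O2}
  - {name: salicylic acid, peak_id: 38, formula: C7H6O3}
  - {name: gentisic acid, peak_id: 14, formula: C7H6O4}
edges:
  - {from: salicin, to: saligenin, type: DEGLYCOSYLATION}
  - {from: saligenin, to: salicylic acid, type: OXIDATION}
  - {from: salicylic acid, to: gentisic acid, type: OXIDATION}
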