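# Drug-likeness rule bound tables, from the rules' original publications.
# Each bound is inclusive: a property passes at the boundary value.
# policy: max_violations allowed while still passing the rule.
lipinski:
  policy: {max_violations: 1}
  bounds:
    MW: {max: 500}
    logP: {max: 5}
    HBD: {max: 5}
    HBA: {max: 10}
ghose:
  policy: {max_violations: 0}
  bounds:
    MW: {min: 160, max: 480}
    logP: {min: -0.4, max: 5.6}
    MR: {min: 40, max: 130}
    atoms: {min: 20, max: 70}
veber:
  policy: {max_violations: 0}
  bounds:
    RotB: {max: 10}
    TPSA: {max: 140}
egan:
  policy: {max_violations: 0}
  bounds:
    logP: {max: 5.88}
    TPSA: {max: 131.6}
muegge:
  policy: {max_violations: 0}
  bounds:
    MW: {min: 200, max: 600}
    logP: {min: -2, max: 5}
    TPSA: {max: 150}
    rings: {max: 7}
    carbons: {min: 5}
    heteroatoms: {min: 2}
    RotB: {max: 15}
    HBD: {max: 5}
    HBA: {max: 10}
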