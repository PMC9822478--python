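# Default physico-chemical descriptor panel (96 names) for the
# RDKit MolecularDescriptorCalculator. The list is configuration, not
# code: swap it by pointing --descriptors at another YAML list.
descriptors:
- MolWt
- HeavyAtomMolWt
- ExactMolWt
- NumValenceElectrons
- FractionCSP3
- TPSA
- LabuteASA
- MolLogP
- MolMR
- HeavyAtomCount
- NHOHCount
- NOCount
- NumHAcceptors
- NumHDonors
- NumHeteroatoms
- NumRotatableBonds
- NumAromaticRings
- NumSaturatedRings
- NumAliphaticRings
- NumAromaticCarbocycles
- NumAromaticHeterocycles
- NumSaturatedCarbocycles
- NumSaturatedHeterocycles
- NumAliphaticCarbocycles
- NumAliphaticHeterocycles
- RingCount
- BalabanJ
- BertzCT
- HallKierAlpha
- Kappa1
- Kappa2
- Kappa3
- Chi0
- Chi1
- Chi0n
- Chi1n
- Chi2n
- Chi3n
- Chi4n
- Chi0v
- Chi1v
- Chi2v
- Chi3v
- Chi4v
- MaxEStateIndex
- MinEStateIndex
- MaxAbsEStateIndex
- MinAbsEStateIndex
- AvgIpc
- SlogP_VSA1
- SlogP_VSA2
- SlogP_VSA3
- SlogP_VSA4
- SlogP_VSA5
- SlogP_VSA6
- SlogP_VSA7
- SlogP_VSA8
- SlogP_VSA9
- SlogP_VSA10
- SlogP_VSA11
- SlogP_VSA12
- SMR_VSA1
- SMR_VSA2
- SMR_VSA3
- SMR_VSA4
- SMR_VSA5
- SMR_VSA6
- SMR_VSA7
- SMR_VSA8
- SMR_VSA9
- SMR_VSA10
- PEOE_VSA1
- PEOE_VSA2
- PEOE_VSA3
- PEOE_VSA4
- PEOE_VSA5
- PEOE_VSA6
- PEOE_VSA7
- PEOE_VSA8
- PEOE_VSA9
- PEOE_VSA10
- PEOE_VSA11
- PEOE_VSA12
- PEOE_VSA13
- PEOE_VSA14
- EState_VSA1
- EState_VSA2
- EState_VSA3
- EState_VSA4
- EState_VSA5
- EState_VSA6
- EState_VSA7
- EState_VSA8
- EState_VSA9
- EState_VSA10
- EState_VSA11
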