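# Drug-likeness rule thresholds.  Each condition is
#   [descriptor, operator, bound]  with operators <=, >=, <, >.
# logp resolves to a method-specific estimate when present
# (wlogp/xlogp3/mlogp), falling back to the generic estimate.
rules:
  lipinski:
    - [mw, "<=", 500]
    - [mlogp, "<=", 4.15]
    - [hbd, "<=", 5]
    - [hba, "<=", 10]
  ghose:
    - [mw, ">=", 160]
    - [mw, "<=", 480]
    - [wlogp, ">=", -0.4]
    - [wlogp, "<=", 5.6]
    - [molar_refractivity, ">=", 40]
    - [molar_refractivity, "<=", 130]
    - [atom_count, ">=", 20]
    - [atom_count, "<=", 70]
  veber:
    - [rotatable_bonds, "<=", 10]
    - [tpsa, "<=", 140]
  egan:
    - [wlogp, "<=", 5.88]
    - [tpsa, "<=", 131.6]
  muegge:
    - [mw, ">=", 200]
    - [mw, "<=", 600]
    - [xlogp3, ">=", -2]
    - [xlogp3, "<=", 5]
    - [tpsa, "<=", 150]
    - [ring_count, "<=", 7]
    - [carbon_count, ">", 4]
    - [heteroatom_count, ">", 1]
    - [rotatable_bonds, "<=", 15]
    - [hba, "<=", 10]
    - [hbd, "<=", 5]
cns_logp_window: [2.0, 3.5]
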