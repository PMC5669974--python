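# Default 21-node EGFR/IGF1R - MAPK - PI3K/mTOR signaling network.
#
# Parameter ledger (86 named parameters):
#   30 interaction edges: 29 Michaelis-Menten (k, K) + 1 mass-action
#     (BAD -> CASP, stoichiometric pro-apoptotic coupling)   -> 59
#   18 basal deactivation rates (one per dynamic node)       -> 18
#    4 receptor stimulus drives (strength + half-saturation) ->  8
#    1 LKB1 basal activation rate                            ->  1
# RasGAP, RafPP and PP2A are constitutively active phosphatase/GAP nodes
# (constant activity 1.0, no free parameters of their own); their
# inhibitory edges carry sampled (k, K) like every other edge.
# BAD starts fully active: survival signaling (AKT, p90RSK) inactivates it.

nodes:
  - {name: EGFR,   role: input-receptor, initial_active: 1.0e-3}
  - {name: IGF1R,  role: input-receptor, initial_active: 1.0e-3}
  - {name: ERBB4,  role: input-receptor, initial_active: 1.0e-3}
  - {name: cKIT,   role: input-receptor, initial_active: 1.0e-3}
  - {name: SOS,    role: kinase}
  - {name: RAS,    role: kinase}
  - {name: RasGAP, role: phosphatase, constant: true}
  - {name: RAF,    role: kinase}
  - {name: RafPP,  role: phosphatase, constant: true}
  - {name: MEK,    role: kinase}
  - {name: ERK,    role: kinase}
  - {name: p90RSK, role: kinase}
  - {name: PP2A,   role: phosphatase, constant: true}
  - {name: PI3K,   role: kinase}
  - {name: AKT,    role: kinase}
  - {name: mTOR,   role: kinase}
  - {name: p70S6K, role: kinase}
  - {name: AMPK,   role: kinase}
  - {name: LKB1,   role: kinase}
  - {name: BAD,    role: effector, initial_active: 1.0}
  - {name: CASP,   role: effector}

edges:
  # receptor layer onto the adaptor and lipid-kinase branches
  - {source: EGFR,   target: SOS,    sign: activating}
  - {source: IGF1R,  target: SOS,    sign: activating}
  - {source: ERBB4,  target: SOS,    sign: activating}
  - {source: cKIT,   target: SOS,    sign: activating}
  - {source: EGFR,   target: PI3K,   sign: activating}
  - {source: IGF1R,  target: PI3K,   sign: activating}
  - {source: ERBB4,  target: PI3K,   sign: activating}
  - {source: cKIT,   target: PI3K,   sign: activating}
  # MAPK cascade
  - {source: SOS,    target: RAS,    sign: activating}
  - {source: RasGAP, target: RAS,    sign: inhibiting}
  - {source: RAS,    target: RAF,    sign: activating}
  - {source: RafPP,  target: RAF,    sign: inhibiting}
  - {source: AKT,    target: RAF,    sign: inhibiting}   # PI3K-MAPK crosstalk
  - {source: RAF,    target: MEK,    sign: activating}
  - {source: MEK,    target: ERK,    sign: activating}
  - {source: PP2A,   target: MEK,    sign: inhibiting}
  - {source: PP2A,   target: ERK,    sign: inhibiting}
  - {source: ERK,    target: p90RSK, sign: activating}
  - {source: p90RSK, target: SOS,    sign: inhibiting}   # negative feedback
  - {source: p90RSK, target: BAD,    sign: inhibiting}
  # PI3K/AKT/mTOR branch
  - {source: PI3K,   target: AKT,    sign: activating}
  - {source: AKT,    target: mTOR,   sign: activating}
  - {source: AKT,    target: BAD,    sign: inhibiting}
  - {source: AKT,    target: CASP,   sign: inhibiting}
  - {source: mTOR,   target: p70S6K, sign: activating}
  - {source: p70S6K, target: PI3K,   sign: inhibiting}   # IRS-branch feedback
  # energy-stress arm
  - {source: LKB1,   target: AMPK,   sign: activating}
  - {source: ERK,    target: LKB1,   sign: inhibiting}   # MAPK-LKB1 interaction
  - {source: AMPK,   target: mTOR,   sign: inhibiting}
  # apoptosis
  - {source: BAD,    target: CASP,   sign: activating, law: mass_action}

drives:
  - {node: EGFR,  strength: 0.5, K: 0.5}
  - {node: IGF1R, strength: 0.5, K: 0.5}
  - {node: ERBB4, strength: 0.5, K: 0.5}
  - {node: cKIT,  strength: 0.5, K: 0.5}

basal_activations:
  - {node: LKB1, rate: 0.1}

decay:
  default: 0.1
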