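# Default residue windows (author numbering, inclusive) for the PsBphP1
# conformational metrics, and the chromophore D-ring atom set.  The
# boundaries are reconstructed from textual anchors of the deposited
# models (hairpin 467-480, helical-spine kink Thr326, GAF exit pivot
# Val307, S-helix resolved to ~Ala526, phosphoacceptor His530 in the
# DHp, CA domain predicted from residues 594-745) and are approximate;
# override them per run when exact boundaries are known.
domains:
  PAS: [12, 128]
  GAF: [129, 320]
  PHY: [330, 465]
  S_HELIX: [490, 525]
  DHP: [526, 590]
  CA: [594, 745]

# Default state comparison: Pr model 8U4X vs Pfr (DoD-derived PSM) 8U63,
# protomer A; both protomers should always be reported.
default_pair:
  pr: 8U4X
  pfr: 8U63
  protomers: [A, B]

# Biliverdin (chemical component BLA): the five-membered pyrrole ring
# bearing the 18-vinyl substituent is ring D.
biliverdin:
  residue_name: BLA
  ring_d_atoms: [ND, C1D, C2D, C3D, C4D]

# Atom pair whose separation reports hairpin-driven GAF-PHY contraction.
hairpin_contraction_pair:
  atom_a: [A, 177, CA]
  atom_b: [A, 483, CA]

# Dimer molar mass (kDa) for mg/mL -> M conversion in SEC titrations.
dimer_molar_mass_kda: 165.0
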