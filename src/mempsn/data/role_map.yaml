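# Chemical-role lookup keyed by (residue_name, atom_name).
#
# This file is data, not code: edit or replace it (see load_role_map) to adapt
# the interaction detectors to a different force field's naming scheme or to a
# coarse-grained representation.  Roles drawn from:
#   hbond_donor, hbond_acceptor, charged_positive, charged_negative, hydrophobic
#
# Protein entries list side-chain atoms only; backbone roles (N donor, O/OXT
# acceptor) are applied uniformly to every protein residue by the loader.
# "hydrophobic" atoms define the side-chain group whose centre of mass enters
# the hydrophobic-contact criterion; only the apolar residue set carries them.
# "formal_charge" names the atom carrying the residue's formal charge, used by
# the macrodipole fallback when no partial charges are available.
#
# Lipid entries include both all-atom head-group names (CHARMM-style) and the
# single-letter bead names used by the bundled coarse-grained generator
# (P = phosphate bead, N = amine/choline bead, OC = PS carboxylate bead,
# CA1/CA2 = acyl-chain beads).

backbone:
  donors: [N]
  acceptors: [O, OXT]

residues:
  ALA: {class: protein, hydrophobic: [CB]}
  VAL: {class: protein, hydrophobic: [CB, CG1, CG2]}
  LEU: {class: protein, hydrophobic: [CB, CG, CD1, CD2]}
  ILE: {class: protein, hydrophobic: [CB, CG1, CG2, CD1, CD]}
  MET: {class: protein, hydrophobic: [CB, CG, SD, CE]}
  PHE: {class: protein, hydrophobic: [CB, CG, CD1, CD2, CE1, CE2, CZ]}
  TRP: {class: protein, hydrophobic: [CB, CG, CD1, CD2, CE2, CE3, CZ2, CZ3, CH2],
        donors: [NE1]}
  PRO: {class: protein, hydrophobic: [CB, CG, CD]}
  GLY: {class: protein}
  SER: {class: protein, donors: [OG], acceptors: [OG]}
  THR: {class: protein, donors: [OG1], acceptors: [OG1]}
  CYS: {class: protein, donors: [SG], acceptors: [SG]}
  TYR: {class: protein, donors: [OH], acceptors: [OH]}
  ASN: {class: protein, donors: [ND2], acceptors: [OD1]}
  GLN: {class: protein, donors: [NE2], acceptors: [OE1]}
  ASP: {class: protein, acceptors: [OD1, OD2], negative: [OD1, OD2],
        formal_charge: {atom: OD1, charge: -1}}
  GLU: {class: protein, acceptors: [OE1, OE2], negative: [OE1, OE2],
        formal_charge: {atom: OE1, charge: -1}}
  LYS: {class: protein, donors: [NZ], positive: [NZ],
        formal_charge: {atom: NZ, charge: 1}}
  ARG: {class: protein, donors: [NE, NH1, NH2], positive: [NE, NH1, NH2, CZ],
        formal_charge: {atom: CZ, charge: 1}}
  HIS: {class: protein, donors: [ND1, NE2], acceptors: [ND1, NE2]}
  HSP: {class: protein, donors: [ND1, NE2], positive: [ND1, NE2],
        formal_charge: {atom: NE2, charge: 1}}

  # Myristoyl group: C14 saturated acyl chain, one network node, all-hydrophobic.
  MYR: {class: myristoyl,
        hydrophobic: [C1, C2, C3, C4, C5, C6, C7, C8, C9, C10, C11, C12, C13, C14],
        acceptors: [O1, O2]}

  # Phosphatidylserine: anionic head (phosphate + carboxylate), ammonium donor.
  DGPS: &ps
    class: lipid_PS
    headgroup: [P, O11, O12, O13, O14, C12, C13, N, O35, O36, OC, HN1]
    negative: [P, O13, O14, O35, O36, OC]
    positive: [N]
    donors: [N]
    acceptors: [O11, O12, O13, O14, O35, O36, OC]
    acyl: [C2, C3, C21, C22, C23, C31, C32, C33, CA1, CA2]
  # Phosphatidylethanolamine: zwitterionic, ammonium donor.
  DGPE: &pe
    class: lipid_PE
    headgroup: [P, O11, O12, O13, O14, C11, C12, N, HN1]
    negative: [P, O13, O14]
    positive: [N]
    donors: [N]
    acceptors: [O11, O12, O13, O14]
    acyl: [C2, C3, C21, C22, C23, C31, C32, C33, CA1, CA2]
  # Phosphatidylcholine: zwitterionic, quaternary amine (no donor H).
  DGPC: &pc
    class: lipid_PC
    headgroup: [P, O11, O12, O13, O14, C11, C12, N, C13, C14, C15]
    negative: [P, O13, O14]
    positive: [N]
    acceptors: [O11, O12, O13, O14]
    acyl: [C2, C3, C21, C22, C23, C31, C32, C33, CA1, CA2]
  POPS: *ps
  POPE: *pe
  POPC: *pc

  HOH: {class: water}
  SOL: {class: water}
  TIP3: {class: water}
  WAT: {class: water}
  K:   {class: ion}
  CL:  {class: ion}
  CLA: {class: ion}
  POT: {class: ion}
  CA:  {class: ion}
  CAL: {class: ion}
  MG:  {class: ion}
  NA:  {class: ion}
  SOD: {class: ion}
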