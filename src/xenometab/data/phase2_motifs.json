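{
 "motifs": [
  {
   "name": "amine",
   "smarts": "[NX3+0,NX4+;!$([N]~[!#6]);!$([N]*~[#7,#8,#15,#16])]"
  },
  {
   "name": "carboxyl",
   "smarts": "[#8;A;X2H1,X1-][#6]([#6,#1;A])=O"
  },
  {
   "name": "aliphatic_hydroxyl",
   "smarts": "[CX4][OX2H1]"
  },
  {
   "name": "phenol",
   "smarts": "[c][OX2H1]"
  },
  {
   "name": "catechol",
   "smarts": "[OX2H1][c][c][OX2H1]"
  },
  {
   "name": "primary_amine",
   "smarts": "[NX3;H2;!$(NC=O)][#6]"
  },
  {
   "name": "secondary_amine",
   "smarts": "[NX3;H1;!$(NC=O)]([#6])[#6]"
  },
  {
   "name": "tertiary_amine",
   "smarts": "[NX3;H0;!$(NC=O)]([#6])([#6])[#6]"
  },
  {
   "name": "aromatic_amine",
   "smarts": "[c][NX3;H2,H1]"
  },
  {
   "name": "thiol",
   "smarts": "[#6][SX2H1]"
  },
  {
   "name": "thioether",
   "smarts": "[#6][SX2][#6]"
  },
  {
   "name": "carboxylic_ester",
   "smarts": "[CX3](=O)[OX2][#6]"
  },
  {
   "name": "amide",
   "smarts": "[CX3](=[OX1])[NX3]"
  },
  {
   "name": "ketone",
   "smarts": "[#6][CX3](=O)[#6]"
  },
  {
   "name": "aldehyde",
   "smarts": "[CX3H1](=O)[#6]"
  },
  {
   "name": "aryl_ether",
   "smarts": "[c][OX2][CX4]"
  },
  {
   "name": "alkyl_ether",
   "smarts": "[CX4][OX2][CX4]"
  },
  {
   "name": "pyridine",
   "smarts": "c1ccncc1"
  },
  {
   "name": "imidazole",
   "smarts": "c1c[nH]cn1"
  },
  {
   "name": "pyrrole",
   "smarts": "c1cc[nH]c1"
  },
  {
   "name": "indole",
   "smarts": "c1ccc2[nH]ccc2c1"
  },
  {
   "name": "pyrimidine",
   "smarts": "c1cncnc1"
  },
  {
   "name": "piperidine",
   "smarts": "C1CCNCC1"
  },
  {
   "name": "piperazine",
   "smarts": "C1CNCCN1"
  },
  {
   "name": "morpholine",
   "smarts": "C1COCCN1"
  },
  {
   "name": "sulfonamide",
   "smarts": "[SX4](=O)(=O)[NX3]"
  },
  {
   "name": "sulfate_ester",
   "smarts": "[#6][OX2][SX4](=O)(=O)[OX2H1,OX1-]"
  },
  {
   "name": "phosphate",
   "smarts": "[PX4](=O)([OX2,OX1-])([OX2,OX1-])"
  },
  {
   "name": "nitro",
   "smarts": "[NX3+](=O)[O-]"
  },
  {
   "name": "nitrile",
   "smarts": "[CX2]#[NX1]"
  },
  {
   "name": "alkene",
   "smarts": "[CX3]=[CX3]"
  },
  {
   "name": "alkyne",
   "smarts": "[CX2]#[CX2]"
  },
  {
   "name": "epoxide",
   "smarts": "[C]1[O][C]1"
  },
  {
   "name": "lactone",
   "smarts": "[CX3](=O)[OX2][#6;R]"
  },
  {
   "name": "lactam",
   "smarts": "[CX3;R](=O)[NX3;R]"
  },
  {
   "name": "urea",
   "smarts": "[NX3][CX3](=[OX1])[NX3]"
  },
  {
   "name": "carbamate",
   "smarts": "[NX3][CX3](=[OX1])[OX2][#6]"
  },
  {
   "name": "guanidine",
   "smarts": "[NX3][CX3](=[NX2])[NX3]"
  },
  {
   "name": "imine",
   "smarts": "[CX3]=[NX2][#6,#1]"
  },
  {
   "name": "hydrazine",
   "smarts": "[NX3][NX3]"
  },
  {
   "name": "hydroxylamine",
   "smarts": "[NX3][OX2H1]"
  },
  {
   "name": "n_oxide",
   "smarts": "[NX4+][O-]"
  },
  {
   "name": "quinone",
   "smarts": "O=C1C=CC(=O)C=C1"
  },
  {
   "name": "furan",
   "smarts": "c1ccoc1"
  },
  {
   "name": "thiophene",
   "smarts": "c1ccsc1"
  },
  {
   "name": "benzene_ring",
   "smarts": "c1ccccc1"
  },
  {
   "name": "naphthalene",
   "smarts": "c1ccc2ccccc2c1"
  },
  {
   "name": "anisole",
   "smarts": "[c][OX2][CH3]"
  },
  {
   "name": "methylenedioxy",
   "smarts": "[c]1[c]OCO1"
  },
  {
   "name": "o_glycoside",
   "smarts": "[#6][OX2][CH]1O[CH](CO)[CH](O)[CH](O)[CH]1O"
  },
  {
   "name": "halogen_f",
   "smarts": "[#6][F]"
  },
  {
   "name": "halogen_cl",
   "smarts": "[#6][Cl]"
  },
  {
   "name": "halogen_br",
   "smarts": "[#6][Br]"
  },
  {
   "name": "halogen_i",
   "smarts": "[#6][I]"
  },
  {
   "name": "trifluoromethyl",
   "smarts": "[CX4]([F])([F])[F]"
  },
  {
   "name": "benzylic_methyl",
   "smarts": "[CH3][c]"
  },
  {
   "name": "allylic_alcohol",
   "smarts": "[CX3]=[CX3][CX4][OX2H1]"
  },
  {
   "name": "benzylic_alcohol",
   "smarts": "[c][CX4][OX2H1]"
  },
  {
   "name": "alpha_beta_unsat_carbonyl",
   "smarts": "[CX3]=[CX3][CX3]=[OX1]"
  },
  {
   "name": "phosphorothioate",
   "smarts": "[PX4]=[SX1]"
  },
  {
   "name": "aryl_sulfonic_acid",
   "smarts": "[c][SX4](=O)(=O)[OX2H1,OX1-]"
  },
  {
   "name": "flavonoid_core",
   "smarts": "O=c1ccoc2ccccc12"
  },
  {
   "name": "chromene",
   "smarts": "C1=Cc2ccccc2OC1"
  },
  {
   "name": "steroid_like_decalin",
   "smarts": "C1CCC2CCCCC2C1"
  }
 ]
}
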