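{
 "name": "env_fixture",
 "rules": [
  {
   "id": "env_ester_cleavage",
   "name": "Carboxylic ester cleavage (environmental microbial)",
   "smirks": "[CX3:1](=[O:2])[OX2:3][#6;!$([CX3]=O):4]>>[C:1](=[O:2])[OX2H1].[OX2H1][#6:4]",
   "enzymes": [
    "ENV_UNSPECIFIED"
   ],
   "biosystems": [
    "env"
   ],
   "reaction_type": "hydrolysis",
   "formula_delta": "+H2O"
  },
  {
   "id": "env_nitro_reduction",
   "name": "Aromatic nitro reduction (environmental microbial)",
   "smirks": "[c:1][NX3+:2](=[OX1:3])[OX1-:4]>>[c:1][NX3+0;H2:2]",
   "enzymes": [
    "ENV_UNSPECIFIED"
   ],
   "biosystems": [
    "env"
   ],
   "reaction_type": "reduction",
   "formula_delta": "-O2+H2"
  },
  {
   "id": "env_aromatic_hydroxylation",
   "name": "Aromatic hydroxylation (environmental microbial)",
   "smirks": "[c;H1:1]>>[c:1]O",
   "enzymes": [
    "ENV_UNSPECIFIED"
   ],
   "biosystems": [
    "env"
   ],
   "reaction_type": "oxidation",
   "formula_delta": "+O"
  },
  {
   "id": "env_phosphorothioate_hydrolysis",
   "name": "Aryl phosphorothioate hydrolysis (environmental microbial)",
   "smirks": "[PX4;$(P=[S,O]):1][O:2][c:3]>>[P:1][O:2].[c:3]O",
   "enzymes": [
    "ENV_UNSPECIFIED"
   ],
   "biosystems": [
    "env"
   ],
   "reaction_type": "hydrolysis",
   "formula_delta": "+H2O"
  }
 ],
 "enzymes": [
  {
   "id": "ENV_UNSPECIFIED",
   "name": "Unspecified environmental microbial enzyme",
   "family": "UNSPECIFIED"
  }
 ],
 "precedence": [
  {
   "dominant": "env_ester_cleavage",
   "suppressed": "env_aromatic_hydroxylation",
   "biosystems": [
    "env"
   ]
  }
 ],
 "pathways": [],
 "records": [],
 "config": {
  "max_steps_cap": 12
 }
}
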