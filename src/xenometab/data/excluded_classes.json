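{
 "classes": {
  "ether_lipid": "[CX4][CX4][CX4][OX2][CH2X4][CHX4]([OX2])[CH2X4][OX2]",
  "glycerolipid": "[CX3](=O)[OX2][CH2X4][CHX4]([OX2][CX3]=O)[CH2X4][OX2;!$([OX2][PX4])]",
  "glycerophospholipid": "[CX3](=O)[OX2][CH2X4][CHX4]([OX2][CX3]=O)[CH2X4][OX2][PX4]",
  "sphingolipid": "[CX4][CHX4]([NX3][CX3]=O)[CHX4]([OX2H1])[CX3]=[CX3]",
  "acyl_coa": "[CX3](=O)[SX2][CH2][CH2][NX3][CX3](=O)[CH2][CH2][NX3][CX3](=O)"
 },
 "cyp_excluded": [
  "glycerolipid",
  "glycerophospholipid"
 ],
 "phase2_excluded": [
  "ether_lipid",
  "glycerolipid",
  "glycerophospholipid",
  "sphingolipid",
  "acyl_coa"
 ]
}
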