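{
 "ISWSIDIOOBJBQZ-UHFFFAOYSA-N": [
  "phenol"
 ],
 "LFQSCWFLJHTTHZ-UHFFFAOYSA-N": [
  "ethanol"
 ],
 "PFTAWBLQPZVEMU-UHFFFAOYSA-N": [
  "epicatechin",
  "(-)-epicatechin"
 ],
 "RYYVLZVUVIJVGH-UHFFFAOYSA-N": [
  "caffeine"
 ],
 "RZVAJINKPMORJF-UHFFFAOYSA-N": [
  "acetaminophen",
  "paracetamol"
 ],
 "UHOVQNZJYSORNB-UHFFFAOYSA-N": [
  "benzene"
 ],
 "URNSECGXFRDEDC-UHFFFAOYSA-N": [
  "NAPQI",
  "N-acetyl-p-benzoquinone imine"
 ],
 "YCIMNLLNPGFGHC-UHFFFAOYSA-N": [
  "catechol"
 ]
}
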