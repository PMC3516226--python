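# Karyotype evolution scenarios for the plant (monocot + eudicot) lineages.
#
# Each lineage starts from a named ancestor (or another lineage's end state)
# and applies count-level events: WGD (doubles n), fis: k (k fissions, +k),
# fus: k (k fusions, -k).  expected_n is the count-law result; stated_n is
# the reported modern chromosome number when it differs.
ancestors:
  AGK: 5    # ancestral grass karyotype, n = 5 protochromosomes
  AEK: 21   # ancestral eudicot karyotype: n = 7 hexaploidized to n = 21
lineages:
  monocot_intermediate:
    start: AGK
    steps: [WGD, {fis: 4}, {fus: 2}]
    expected_n: 12
  rice:
    start: monocot_intermediate
    steps: []
    expected_n: 12
  panicoideae_intermediate:
    start: monocot_intermediate
    steps: [{fis: 2}, {fus: 4}]
    expected_n: 10
  sorghum:
    start: panicoideae_intermediate
    steps: []
    expected_n: 10
  maize:
    start: panicoideae_intermediate
    steps: [WGD, {fis: 7}, {fus: 17}]
    expected_n: 10
  brachypodium:
    start: monocot_intermediate
    steps: [{fis: 7}, {fus: 14}]
    expected_n: 5
  grape:
    start: AEK
    steps: [{fis: 2}, {fus: 4}]
    expected_n: 19
  fragaria:
    start: AEK
    steps: [{fis: 3}, {fus: 17}]
    expected_n: 7
  cacao:
    start: AEK
    steps: [{fis: 2}, {fus: 13}]
    expected_n: 10
  malpighiales_intermediate:
    start: AEK
    steps: [{fis: 6}, {fus: 15}]
    expected_n: 12
  poplar:
    start: malpighiales_intermediate
    steps: [WGD, {fis: 4}, {fus: 9}]
    expected_n: 19
  rosaceae_intermediate:
    start: AEK
    steps: [{fis: 3}, {fus: 15}]
    expected_n: 9
  apple:
    start: rosaceae_intermediate
    steps: [WGD, {fis: 4}, {fus: 5}]
    expected_n: 17
  brassicales_intermediate:
    start: AEK
    steps: [{fis: 10}, {fus: 22}]
    expected_n: 9
  arabidopsis:
    start: brassicales_intermediate
    steps: [WGD, {fus: 13}]
    expected_n: 5
  papilionoideae_intermediate:
    start: AEK
    steps: [{fis: 1}, {fus: 16}]
    expected_n: 6
  soybean:
    start: papilionoideae_intermediate
    steps: [WGD, WGD, {fis: 13}, {fus: 17}]
    expected_n: 20
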