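# Karyotype evolution scenarios for the vertebrate lineages.
#
# The three interchromosomal translocations-and-fusions between the two
# ancestral WGD rounds are modelled as three chromosome-gaining events
# (fis: 3), consistent with the 10+10+3 = 23 arithmetic.  For chicken,
# human and chimpanzee the curated event counts do not satisfy the count
# law against the stated modern chromosome numbers; the scripts keep the
# curated counts and record the stated_n separately rather than silently
# correcting either.
ancestors:
  AVK: 10   # ancestral vertebrate karyotype, n = 10 protochromosomes
lineages:
  post1R_intermediate:
    start: AVK
    steps: [WGD, {fis: 3}]
    expected_n: 23
  gnathostome_intermediate:
    start: post1R_intermediate
    steps: [WGD, {fus: 6}]
    expected_n: 40
  osteichthyes_intermediate:
    start: gnathostome_intermediate
    steps: [{fus: 10}, {fis: 1}]
    expected_n: 31
  teleost_intermediate:
    start: osteichthyes_intermediate
    steps: [{fus: 23}, {fis: 5}]
    expected_n: 13
  medaka:
    start: teleost_intermediate
    steps: [WGD, {fus: 7}, {fis: 5}]
    expected_n: 24
  amniote_intermediate:
    start: osteichthyes_intermediate
    steps: [{fus: 1}]
    expected_n: 30
  chicken:
    start: amniote_intermediate
    steps: [{fis: 1}, {fus: 3}]
    expected_n: 28
    stated_n: 33
  opossum:
    start: amniote_intermediate
    steps: [{fis: 43}, {fus: 64}]
    expected_n: 9
  laurasiatheria_intermediate:
    start: amniote_intermediate
    steps: [{fis: 57}, {fus: 22}]
    expected_n: 65
  horse:
    start: laurasiatheria_intermediate
    steps: [{fis: 2}, {fus: 35}]
    expected_n: 32
  dog:
    start: laurasiatheria_intermediate
    steps: [{fis: 6}, {fus: 32}]
    expected_n: 39
  euarchontoglires_intermediate:
    start: amniote_intermediate
    steps: [{fis: 24}, {fus: 15}]
    expected_n: 39
  mouse:
    start: euarchontoglires_intermediate
    steps: [{fis: 31}, {fus: 50}]
    expected_n: 20
  human:
    start: euarchontoglires_intermediate
    steps: [{fis: 1}, {fus: 18}]
    expected_n: 22
    stated_n: 23
  chimpanzee:
    start: euarchontoglires_intermediate
    steps: [{fis: 1}, {fus: 17}]
    expected_n: 23
    stated_n: 24
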