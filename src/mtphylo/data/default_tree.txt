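# Cohort-wide haplogroup tree with control-region defining motifs.
# The A2 sub-tree (A2ad / A2af and descendants) follows the published
# clade definitions; the remaining major-haplogroup motifs are coarse
# control-region stand-ins adequate for classifying the synthetic cohort
# and for demonstration — real analyses should supply a full phylogeny.
root:
  A2: 64 73 146 153 235 263 16111 16223 16290 16319 16362
    A2ad: 16175 16300
    A2af: 73@ 106-111d 5460 16360
      A2af1: 64@ 6794 7960
        A2af1a: 89
        A2af1b: 11482
  B2: 73 263 499 16189 16217
  C1: 73 249d 263 290-291d 16223 16298 16325 16327
  D1: 73 263 16223 16325 16362
  L0: 73 146 152 195 263 16129 16148 16172 16187 16223 16278
  L1: 73 146 152 182 195 247 263 16126 16187 16223 16278
  L2: 73 146 150 152 195 263 16223 16278 16390
  L3: 73 263 16223
  HV: 263
  JT: 73 263 16126
  N1'2: 73 199 204 250 263 16223
  U: 73 263 16270
  G: 73 263 489 16223 16362
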