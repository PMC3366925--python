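# A2ad / A2af clade definitions, rooted at A2. Variant tokens are relative
# to the rCRS; "@" marks back mutations relative to the upstream motif.
A2:
  A2ad: 16175 16300
  A2af: 73@ 106-111d 5460 16360
    A2af1: 64@ 6794 7960
      A2af1a: 89
      A2af1b: 11482
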