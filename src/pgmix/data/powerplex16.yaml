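# Synthetic 15-locus STR panel modeled on the Promega PowerPlex 16 multiplex
# (autosomal STR loci only; the amelogenin sex marker and the internal size
# standard are omitted).  Dye assignments, repeat unit lengths and approximate
# fragment-size offsets follow the kit layout; allele ranges are plausible
# simplifications, not the kit's certified allelic ladders.
name: powerplex16-like
loci:
  D3S1358:
    dye: blue
    repeat_unit: 4
    offset_bp: 99
    alleles: ["12", "13", "14", "15", "16", "17", "18", "19"]
  TH01:
    dye: blue
    repeat_unit: 4
    offset_bp: 152
    alleles: ["5", "6", "7", "8", "9", "9.3", "10", "11"]
  D21S11:
    dye: blue
    repeat_unit: 4
    offset_bp: 86
    alleles: ["27", "28", "29", "30", "30.2", "31", "31.2", "32", "32.2", "33.2"]
  D18S51:
    dye: blue
    repeat_unit: 4
    offset_bp: 231
    alleles: ["11", "12", "13", "14", "15", "16", "17", "18", "19", "20"]
  PentaE:
    dye: blue
    repeat_unit: 5
    offset_bp: 354
    alleles: ["5", "6", "7", "8", "9", "10", "11", "12", "13", "14",
              "15", "16", "17", "18", "19", "20", "21", "22", "23", "24"]
  D5S818:
    dye: green
    repeat_unit: 4
    offset_bp: 91
    alleles: ["7", "8", "9", "10", "11", "12", "13", "14"]
  D13S317:
    dye: green
    repeat_unit: 4
    offset_bp: 145
    alleles: ["8", "9", "10", "11", "12", "13", "14", "15"]
  D7S820:
    dye: green
    repeat_unit: 4
    offset_bp: 179
    alleles: ["6", "7", "8", "9", "10", "11", "12", "13", "14"]
  D16S539:
    dye: green
    repeat_unit: 4
    offset_bp: 228
    alleles: ["5", "8", "9", "10", "11", "12", "13", "14", "15"]
  CSF1PO:
    dye: green
    repeat_unit: 4
    offset_bp: 277
    alleles: ["7", "8", "9", "10", "11", "12", "13", "14", "15"]
  PentaD:
    dye: green
    repeat_unit: 5
    offset_bp: 330
    alleles: ["2.2", "5", "7", "8", "9", "10", "11", "12", "13", "14",
              "15", "16", "17"]
  vWA:
    dye: yellow
    repeat_unit: 4
    offset_bp: 87
    alleles: ["11", "13", "14", "15", "16", "17", "18", "19", "20", "21"]
  D8S1179:
    dye: yellow
    repeat_unit: 4
    offset_bp: 158
    alleles: ["8", "9", "10", "11", "12", "13", "14", "15", "16"]
  TPOX:
    dye: yellow
    repeat_unit: 4
    offset_bp: 230
    alleles: ["6", "7", "8", "9", "10", "11", "12", "13"]
  FGA:
    dye: yellow
    repeat_unit: 4
    offset_bp: 308
    alleles: ["18", "19", "20", "21", "22", "22.2", "23", "24", "25", "26",
              "27", "28"]
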