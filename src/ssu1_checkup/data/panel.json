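{
  "size_tolerance_bp": 3.0,
  "primers": [
    {"name": "1189", "sequence": "ATGGCAGCTTCTAAGTTGTGG", "dye": "FAM"},
    {"name": "1190", "sequence": "GTTTATGTTTGGTTTGGGGG", "dye": null},
    {"name": "1191", "sequence": "AAAGAAGTTGCATGCGCCTA", "dye": "ATTO550"},
    {"name": "1192", "sequence": "ACCTGAGTGCATTTGCAACA", "dye": null},
    {"name": "1193", "sequence": "TGTCAAGTTGAGACAAACCGA", "dye": null},
    {"name": "1194", "sequence": "GGGGAAAGCTGTAATTTGTGT", "dye": "HEX"},
    {"name": "1196", "sequence": "TGCATAAGCAGGCAACTCCT", "dye": "ATTO565"}
  ],
  "alleles": [
    {"allele_id": "VIII-wt", "chrom_class": "VIII-wt", "size_range": [550, 700],
     "dyes": ["FAM"], "primers": ["1189", "1190"]},
    {"allele_id": "XV-wt^702", "chrom_class": "XV-wt", "size": 702,
     "dyes": ["ATTO550"], "primers": ["1191", "1192"]},
    {"allele_id": "XVI-wt^991", "chrom_class": "XVI-wt", "size": 991,
     "dyes": ["HEX"], "primers": ["1193", "1194"]},
    {"allele_id": "VIII-t-XVI^388", "chrom_class": "VIII-t-XVI", "size": 388,
     "dyes": ["FAM", "HEX"], "primers": ["1189", "1194"]},
    {"allele_id": "VIII-t-XVI^478", "chrom_class": "VIII-t-XVI", "size": 478,
     "dyes": ["FAM", "HEX"], "primers": ["1189", "1194"]},
    {"allele_id": "VIII-t-XVI^555", "chrom_class": "VIII-t-XVI", "size": 555,
     "dyes": ["FAM", "HEX"], "primers": ["1189", "1194"]},
    {"allele_id": "VIII-t-XVI^631", "chrom_class": "VIII-t-XVI", "size": 631,
     "dyes": ["FAM", "HEX"], "primers": ["1189", "1194"]},
    {"allele_id": "XV-t-XVI^496", "chrom_class": "XV-t-XVI", "size": 496,
     "dyes": ["ATTO550", "HEX"], "primers": ["1191", "1194"]},
    {"allele_id": "inv-XVI^781", "chrom_class": "inv-XVI", "size": 781,
     "dyes": ["ATTO565", "HEX"], "primers": ["1196", "1194"]}
  ]
}
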