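# Structural candidate events of the fixture cohort (1-based inclusive
# coordinates, hg19).  Breakpoints of the second event are known only to
# intervals; its first/last coordinates are the maximal deleted region.
events:
  - label: "CRIM1:g.36769283_36778290del"
    genes: [CRIM1]
    chrom: "2"
    first_deleted: 36769283
    last_deleted: 36778290
    microhomology: CT
    exon_span: "exons 15-17 + 3'UTR"
    genotypes:
      "1[III:3]": het
      "1[II:3]": het
      "1[I:1]": het
      "1[II:1]": het
  - label: "FAT1:g.(187149541_188971489)del"
    genes: [FAT1, F11, MTNR1A, ZFP42]
    chrom: "4"
    first_deleted: 187149541
    last_deleted: 188971489
    microhomology: ""
    exon_span: "whole gene"
    breakpoint_intervals:
      proximal: [187179210, 187179486]
      distal: [188926200, 189012426]
    genotypes:
      "3[II:1]": het
      "3[I:1]": het
      "3[I:2]": ref
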