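# Transcript and assay constants of the fixture.  Values not printed in
# the source tables (primer coordinates, most exon lengths, reporter
# exon lengths) are reconstructed/synthetic, chosen to be consistent
# with the printed product sizes; they are marked below.
chd7:
  transcript_id: NM_017780.3
  strand: "+"
  n_exons: 38
  # exon 3 length (431 nt) and the exon count are as printed; the other
  # lengths are synthetic but keep the canonical exon2-5 product at 871 nt.
  exon_lengths_head: [315, 270, 431, 88, 200]
  exon_length_rest: 150
  genome_start: 61600000
  intron_length: 2000
  cds_start_offset: 400
  amplicon:
    first_exon: 2
    last_exon: 5
    forward_offset: 0     # reconstructed primer offsets: canonical = 871 nt
    reverse_offset: 82
  cryptic_donor:
    exon_index: 3
    removed_nt: 380
  ptc_codon: 573
crim1_multiplex:
  # reconstructed coordinates consistent with the printed 22,240-bp
  # long-range product, the 9,612-bp internal product, and the
  # 13,232-bp deleted-allele product
  primers:
    - {name: CRIM1_int13_F, position: 36757000, strand: "+"}
    - {name: CRIM1_int15_F, position: 36769628, strand: "+"}  # inside the deletion
    - {name: FEZ2_int8_R, position: 36779239, strand: "-"}
eftud2_minigene:
  insert_exon_length: 125          # c.765-267 .. c.889+171 carries the 125-nt exon 10
  vector_exon_lengths: [169, 240]  # synthetic reporter (rhodopsin-like) exon lengths
fat1_deletion:
  chrom: "4"
  first_deleted: 187149541
  last_deleted: 188971489
crim1_deletion:
  chrom: "2"
  first_deleted: 36769283
  last_deleted: 36778290
  microhomology: CT
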