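# Default evidence-combining table for the reduced ACMG-style classifier.
#
# Rules are evaluated top to bottom; the first match assigns the class.
# Each rule may require codes (`all`), require at least one of a set
# (`any`), and forbid codes (`none`).  If nothing matches, the class is
# VUS.  Codes produced by the classifier:
#   PVS1 null variant (frameshift/nonsense/canonical splice/multi-exon del)
#   PS2  confirmed de novo (STR-verified parentage)
#   PM2  absent/ultra-rare in population controls
#   PM5  different missense change at a residue with a reported
#        pathogenic change and comparable phenotype
#   PP1  co-segregation with disease in the family
#   PP3  in-silico predictor consensus (>=3/5 deleterious)
#   BS4  nonsegregation (affected non-carrier)
#   BP5  alternative molecular basis established in the same family
#
# This table deliberately deviates from a strict Richards-2015 reading
# in two places, reflecting the conservative practice this pipeline
# formalizes for a screening (not diagnostic) context:
#   - PVS1 + PM2 alone stays VUS (strict reading: LP).  A null allele in
#     a gene without an established dominant LoF mechanism is not
#     upgraded on rarity alone.
#   - PS2 + PM2 (+PP3) stays VUS (strict reading: LP).  A confirmed de
#     novo missense is upgraded only through the category logic, which
#     separately credits de novo confirmation.
rules:
  - class: P
    all: [PVS1, PS2]
  - class: LB
    any: [BS4, BP5]
    none: [PVS1, PS2]
  - class: LP
    all: [PM2, PM5, PP3]
default: VUS
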