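# Reviewer-level evidence that cannot be derived from genotypes alone:
# functional assay outcomes, reviewed segregation judgments, and
# established alternative causes.  Keys are candidate keys
# (GENE:HGVS_C or the CNV event label).
overrides:
  "CHD7:c.2095A>G":
    functional: supports
    functional_ref: "RT-PCR exons 2-5: increased cryptic-donor product in the index"
  "CRIM1:c.926C>T":
    alternative_cause_in_family: true   # the CRIM1 deletion explains family 1
  "TBX5:c.349G>T":
    segregation: nonsegregating         # reviewed: does not track with disease
  "FZD7:c.1154C>T":
    segregation: nonsegregating
  "PPP1R12A:c.2014C>G":
    segregation: nonsegregating
  "ACTG1:c.803-18dup":
    functional: refutes
    functional_ref: "RT-PCR exons 4-6: no altered splicing"
  "EFTUD2:c.765-15C>G":
    functional: refutes
    functional_ref: "RT-PCR exons 7-12/8-11/2-27 and minigene: no altered splicing"
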