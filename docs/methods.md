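# Methods

This note records the models, conventions, and design choices behind
`mac-prioritize`, in the order the pipeline applies them.

## Coordinate and unit conventions

All genomic coordinates are 1-based inclusive; a deletion is identified
by its first and last deleted bases, so `span = last − first + 1`.
This is the only convention under which the CRIM1 breakpoint pair
(36,769,283; 36,778,290) yields the 9,008-bp span the fixture asserts.
BED input is converted from 0-based half-open on read. Allele
frequencies are fractions in [0, 1]; `%`-suffixed values are divided by
100 at parse time, so a gnomAD column entry of `0.00082%` becomes
8.2 × 10⁻⁶. `boundary_distance` mirrors HGVS intronic offsets:
c.765-15 ⇒ −15 (negative = intronic), exonic/downstream positive, 0 at
the boundary base.

## Filter cascade

Stages are per-variant, order-independent, and fully logged.

| parameter | default | rationale |
|---|---|---|
| `het_af_max` | 0.01 | heterozygous population-frequency exclusion bound |
| `hom_af_max` | 1e-7 | literal percent reading of the "0.00001%" homozygote bound; set 1e-5 if your source stores that bound as a fraction — the two readings are not distinguishable from the screening criteria themselves, so both are supported |
| `splice_window` | 30 bp | synonymous/intronic variants considered only near splice sites |
| `consensus_required` | 3 of 5 | deleterious-predictor majority for missense |
| `sift_max` | 0.05 | conventional SIFT deleteriousness cutoff |
| `fathmm_min` | 0.5 | FATHMM-MKL coding score threshold |
| `cadd_min` | 15.0 | CADD PHRED cutoff; consistent with a 15.4 score counting as a deleterious vote in the fixture |
| `gvgd_min_grade` | C15 | Align-GVGD grades at or above C15 count as deleterious |

A missing predictor is a non-deleterious vote: the denominator stays at
five, which is the conservative reading of a "three out of five"
majority. Splice-region variants that pass the window but carry no
predicted splice-strength change (`splice_delta` absent or 0) are
flagged *fallback-only*: they survive the cascade but are never
upgraded to disease-causing on family evidence alone, matching their
role as candidates of last resort. The only rescue rule is a prior
report of the same variant/residue for UTR/other classes, and every
rescue is logged.

## Segregation, de novo, STR parentage

Segregation is evaluated over genotyped family members only:
*nonsegregating* iff an affected member is reference; *segregates* iff
all genotyped affected members carry the allele; *uninformative* when
only one member is genotyped. Unaffected and unknown-status carriers
do not break segregation (dominant eye-malformation pedigrees show
reduced penetrance); they are listed in the result, and a strict mode
treats phenotypically unaffected carriers as nonsegregation.

De novo candidates (child carrier, both parents genotyped reference)
are confirmed only by STR parentage: a marker is consistent when the
child's allele pair partitions into one paternal and one maternal
allele; confirmation tolerates `max_mismatches = 1` of 24 markers (one
single-step mutation), a repo decision since no concordance tolerance
is standard. Fewer than 20 shared markers flags the result
low-confidence. Under the simulator's population model (10 equifrequent
alleles per marker) an unrelated putative father is confirmed in fewer
than 1 % of trios, verified by simulation.

## CNV calling and breakpoint resolution

The depth model is deliberately simple and explicit, replacing the
undocumented commercial caller used in routine practice: each cell of
the targets × samples matrix is divided by its sample median (library
size), then by its target median across reference samples (capture
bias), giving expectation 1.0 for diploid targets. Calls are maximal
runs of ≥ `min_exons` (2) consecutive same-gene targets with ratio in
a band: het deletion [0.35, 0.65], hom deletion [0, 0.15], duplication
≥ 1.4. Bands are configuration, not science; at the simulator's 10 %
depth CV a per-exon het-deletion z-score is ≈ 3, which gives ≥ 95 %
recall for 3-exon events with essentially no false calls (verified by
simulation). Zero-median targets are excluded and reported.

Junction resolution: a junction read must decompose as
`proximal[:a] + distal[b:]`. The set of valid `a` forms a contiguous
interval whose width is the microhomology length; the implementation
computes it from maximal prefix/suffix matches and is checked in tests
against a brute-force enumeration of all splits. Reported breakpoints
assign the microhomology to the proximal retained side, making the
coordinate pair unique; the graphical convention of showing the
ambiguity interval at both flanks carries the same information.

Multiplex-PCR products are inclusive spans between forward/reverse
primer positions; on the deleted allele a spanning pair shrinks by the
deletion span, and a primer inside the deleted interval produces no
product (warned). An optional `max_length` models amplifiability.

## Splice fragments, frame, NMD

Fragment prediction is arithmetic on declared events — the pipeline
does not model splice-site strength (predicted alterations enter as
the `splice_delta` annotation). Product length = canonical amplicon
length − removed + retained nucleotides. Frame is `Δ mod 3`; NMD
candidacy applies the standard 55-nt rule (PTC at least 55 nt upstream
of the last exon–exon junction), adopted here as an explicit
convention. The exact PTC codon of a frameshift depends on coding
sequence and is supplied, not computed. Minigene products are vector
exon sums with and without the insert exon.

## Classification

Evidence codes: PVS1 (null allele, including multi-exon deletions),
PS2 (STR-confirmed de novo), PM2 (heterozygous frequency ≤ 1e-4), PM5
(different change at a residue with a reported comparable-phenotype
variant), PP1 (co-segregation), PP3 (predictor consensus), BS4
(nonsegregation), BP5 (alternative molecular basis established in the
family). The combining table ships as editable YAML
(`macprio/data/acmg_rules.yaml`) and deviates from a strict
Richards-2015 reading in two documented places (PVS1+PM2 alone and
PS2+PM2±PP3 stay VUS), reflecting a conservative screening posture:
upgrades beyond VUS require either a de novo null allele, or
rarity+residue-match+consensus.

Categories: P/LP are potentially disease-causing; a VUS is upgraded
when supported by confirmed de novo occurrence, co-segregation under a
fitting inheritance model (dominant fit requires ≥ 2 affected
carriers or confirmed de novo; biallelic fit requires homozygous or
hemizygous carriage, the latter encoding an SNV in trans with a
deletion), a same-variant prior report, or biallelic carriage.
Nonsegregation and functional refutation exclude a variant outright;
a lower-tier variant in a family with an established alternative cause
is excluded as incidental. "Additional findings" in the cohort summary
are cascade-passing candidates that are neither disease-causing nor
incidental — the set a results table of near-miss variants would list.

Percentages are integers rounded half away from zero; this convention
reproduces all five fixture rates (4/6→67, 6/13→46, 7/15→47, 7/12→58,
3/7→43). The colobomatous-microphthalmia stratum is counted over
affected patients (its published 3/7 rate uses all seven affected CM
patients, only six of whom are index patients). The fixture's
enrollment-time extraocular flag marks six affected patients; the
aortic finding of one index patient postdates genetic testing and is
therefore not an enrollment flag — the clinical table does not itself
enumerate the six-member stratum, so this membership is a documented
fixture assumption rather than an assertion about intent.

## Fixture

The fixture transcribes the published cohort: 21 clinical-table
individuals (19 affected, 2 asymptomatic carriers) in 15 families, 13
SNV/indel candidate rows, and 2 structural events, with per-variant
evidence flags (functional outcomes, reviewed nonsegregation, the
incidental-finding flag) that genotypes alone cannot encode. The
candidate tables list seven non-causal variants; one (the CRIM1
missense) is the incidental finding, leaving six additional findings.
Individual predictor scores are reconstructed to match the printed
vote counts and CADD values; primer coordinates and most exon lengths
are reconstructed to match printed product sizes and are labelled as
such in the data files. Pedigree members outside the clinical table
(spouses, parents of index patients) carry a `TABLE1=0` flag and do
not enter stratum denominators. File integrity is checked by SHA-256
against `checksums.sha256`.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not sequence-level realism (no reads, no alignment, no annotation):

- architectures: trio (0.5), three-generation (0.3), index-only (0.2);
  inheritance models: de novo dominant (0.25, trios only), inherited
  dominant with reduced penetrance (0.2, three-generation), compound
  het SNV+CNV (0.2, trios), unsolved (0.35);
- background: Poisson(40) panel variants per founder, transmitted with
  probability ½ per meiosis (hence ≈ 40 per sample and no spurious de
  novo events); het frequency ~ 0.3·δ₀ + 0.7·Beta(0.2, 5); benign
  deleterious votes ~ Binomial(5, 0.1);
- causal variants: frequency 0; loss-of-function with probability 0.6,
  otherwise missense with votes ~ max(3, Binomial(5, 0.8));
- depth: Normal(100·copy/2, 10) truncated at 0 over 20 genes × 8
  exons; planted deletions span 3 consecutive exons;
- STR: 24 markers, 10 equifrequent alleles per marker.

These settings were chosen once to put realistic mass on both sides of
every threshold (common and rare benign variants, sub- and
supra-consensus vote counts, boundary distances inside and outside the
window); the expected number of background cascade survivors per
family has a closed form (Poisson mean × pass probability) that the
test suite checks against simulation. What passing tests show is that
the decision logic is correct under this explicit model; they do not
certify performance on real exomes, where annotation errors, correlated
predictor scores, capture-bias structure, and pedigree errors are the
dominant failure modes and none are modelled here.

## Problem sizes and numerical notes

The validation suite uses 200-family cohorts for end-to-end
recall/specificity, 100 planted deletions for CNV recall, 500 random
junctions for breakpoint recovery, and 1,500–2,000 trios for STR
false-confirmation rates — sizes at which binomial standard errors are
comfortably below the asserted margins while the whole suite runs in
well under a minute. All randomness flows through
`numpy.random.default_rng` seeds; gene-to-chromosome assignment avoids
Python's per-process string hashing so outputs are identical across
interpreter sessions. Frequencies round-trip through text at 17
significant digits (bit-exact for doubles).

## Known limitations

- Raw-read processing (alignment, variant calling, annotation) is out
  of scope; the pipeline consumes annotated tables.
- The CNV caller has no per-target variance model or GC correction; it
  is adequate for the simulator's noise model and for panel-scale
  screening, not for genome-wide discovery.
- Breakpoints known only to intervals (array-resolved deletions) are
  carried as interval metadata; only junction-sequenced deletions get
  base-pair breakpoints.
- The classifier is a deterministic formalization of what is, in
  practice, a holistic judgment; the rule table is data, and evidence
  the data model cannot express (animal models, literature depth)
  enters only through the prior-report and override flags.
- One cohort-level count is reproduced under a documented fixture
  assumption (the extraocular stratum membership, see above), because
  the source tables underdetermine it.
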