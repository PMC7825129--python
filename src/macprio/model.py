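"""Core domain types and coordinate conventions.

All genomic coordinates in this package are 1-based and inclusive: a
deletion is described by the positions of its first and last deleted
bases, so its span is ``last - first + 1``.  BED input (0-based,
half-open) is converted on read.  Allele frequencies are stored as
fractions in [0, 1]; percentage-formatted inputs are divided by 100 at
parse time.

``boundary_distance`` is a signed offset from the nearest exon-intron
boundary, mirroring HGVS intronic offsets: c.765-15 has distance -15
(intronic, upstream of the acceptor), exonic/downstream positions are
positive, and 0 denotes the boundary base itself.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class Consequence(enum.Enum):
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    INTRONIC = "intronic"
    FRAMESHIFT = "frameshift"
    NONSENSE = "nonsense"
    CANONICAL_SPLICE = "canonical_splice"
    INFRAME_INDEL = "inframe_indel"
    UTR = "utr"
    OTHER = "other"


#: Consequence classes treated as null (loss-of-function) alleles.
NULL_CONSEQUENCES = frozenset(
    {Consequence.FRAMESHIFT, Consequence.NONSENSE, Consequence.CANONICAL_SPLICE}
)

#: Classes for which a splice-region distance must be annotated.
SPLICE_REGION_CONSEQUENCES = frozenset(
    {Consequence.SYNONYMOUS, Consequence.INTRONIC, Consequence.CANONICAL_SPLICE}
)


class GvgdGrade(enum.IntEnum):
    """Align-GVGD grades, ordered from most benign (C0) to most deleterious (C65)."""

    C0 = 0
    C15 = 15
    C25 = 25
    C35 = 35
    C45 = 45
    C55 = 55
    C65 = 65


class MutationTasterCall(enum.Enum):
    DISEASE_CAUSING = "disease_causing"
    POLYMORPHISM = "polymorphism"
    MISSING = "missing"


class PriorReport(enum.Enum):
    NONE = "none"
    SAME_VARIANT_COMPARABLE_PHENOTYPE = "same_variant_comparable_phenotype"
    SAME_RESIDUE_DIFFERENT_CHANGE = "same_residue_different_change"


class Genotype(enum.Enum):
    REF = "ref"
    HET = "het"
    HOM = "hom"
    HEMI = "hemi"
    MISSING = "missing"


#: Genotypes that carry at least one copy of the alternate allele.
CARRIER_GENOTYPES = frozenset({Genotype.HET, Genotype.HOM, Genotype.HEMI})


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    ASYMPTOMATIC_CARRIER = "asymptomatic_carrier"
    UNKNOWN = "unknown"


@dataclass
class PredictionProfile:
    """Scores from the five in-silico predictors consumed as annotations.

    Any field may be missing (``None`` / MISSING); a missing predictor
    never counts as a deleterious vote.
    """

    align_gvgd: Optional[GvgdGrade] = None
    fathmm_mkl: Optional[float] = None
    cadd_phred: Optional[float] = None
    mutation_taster: MutationTasterCall = MutationTasterCall.MISSING
    sift: Optional[float] = None

    def __post_init__(self) -> None:
        if self.fathmm_mkl is not None and not 0.0 <= self.fathmm_mkl <= 1.0:
            raise ValueError(f"FATHMM-MKL score out of [0,1]: {self.fathmm_mkl}")
        if self.sift is not None and not 0.0 <= self.sift <= 1.0:
            raise ValueError(f"SIFT score out of [0,1]: {self.sift}")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError(f"CADD PHRED score negative: {self.cadd_phred}")

    @property
    def n_present(self) -> int:
        return sum(
            (
                self.align_gvgd is not None,
                self.fathmm_mkl is not None,
                self.cadd_phred is not None,
                self.mutation_taster is not MutationTasterCall.MISSING,
                self.sift is not None,
            )
        )


@dataclass
class VariantRecord:
    """One annotated alternate allele with per-sample genotypes."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    transcript: str = ""
    hgvs_c: str = ""
    hgvs_p: str = ""
    consequence: Consequence = Consequence.OTHER
    exon_index: Optional[int] = None
    intron_index: Optional[int] = None
    boundary_distance: Optional[int] = None
    het_af: float = 0.0
    hom_af: float = 0.0
    predictions: PredictionProfile = field(default_factory=PredictionProfile)
    splice_delta: Optional[float] = None
    prior_report: PriorReport = PriorReport.NONE
    genotypes: dict[str, Genotype] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for name, val in (("het_af", self.het_af), ("hom_af", self.hom_af)):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} out of [0,1]: {val}")
        if (
            self.consequence in SPLICE_REGION_CONSEQUENCES
            and self.boundary_distance is None
        ):
            raise ValueError(
                f"{self.key}: boundary_distance required for "
                f"{self.consequence.value} variants"
            )
        if not self.genotypes:
            raise ValueError(f"{self.key}: genotypes must be non-empty")

    @property
    def key(self) -> str:
        return f"{self.gene}:{self.hgvs_c or f'{self.chrom}:{self.pos}{self.ref}>{self.alt}'}"

    def carriers(self) -> list[str]:
        return [s for s, g in self.genotypes.items() if g in CARRIER_GENOTYPES]


@dataclass
class Individual:
    id: str
    family: str
    sex: Sex = Sex.UNKNOWN
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    affection: Affection = Affection.UNKNOWN
    is_index: bool = False
    has_coloboma: bool = False
    has_microphthalmia: bool = False
    extraocular_at_enrollment: bool = False
    in_clinical_table: bool = True


def validate_pedigree(members: list[Individual]) -> None:
    """Check referential integrity and index uniqueness family by family."""
    by_family: dict[str, list[Individual]] = {}
    for ind in members:
        by_family.setdefault(ind.family, []).append(ind)
    seen: set[str] = set()
    for ind in members:
        if ind.id in seen:
            raise ValueError(f"duplicate individual ID: {ind.id}")
        seen.add(ind.id)
    for fam, inds in by_family.items():
        ids = {i.id for i in inds}
        for ind in inds:
            for parent in (ind.father_id, ind.mother_id):
                if parent is not None and parent not in ids:
                    raise ValueError(
                        f"{ind.id}: parent {parent!r} not found in family {fam}"
                    )
        n_index = sum(i.is_index for i in inds)
        if n_index != 1:
            raise ValueError(f"family {fam}: expected exactly one index, got {n_index}")


@dataclass
class GenePanel:
    """Set of panel gene symbols, optionally with genomic intervals."""

    entries: frozenset[str]
    intervals: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, (chrom, start, end) in self.intervals.items():
            if start > end or start < 1:
                raise ValueError(f"panel interval malformed for {gene}: {chrom}:{start}-{end}")

    def __contains__(self, gene: str) -> bool:
        return gene in self.entries

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class TranscriptModel:
    """Exon structure of one reference transcript.

    ``exons`` are (genomic_start, genomic_end) pairs, 1-based inclusive,
    ordered 5'->3' in transcript orientation.  ``cds_start_offset`` is the
    0-based position of the first coding base within the spliced mRNA.
    """

    transcript_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start_offset: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for start, end in self.exons:
            if start > end:
                raise ValueError(f"exon {start}-{end} malformed")
        spans = sorted((min(s, e), max(s, e)) for s, e in self.exons)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("exons overlap")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_length(self, index: int) -> int:
        """Length in nt of the 1-based exon ``index`` (transcript order)."""
        start, end = self.exons[index - 1]
        return abs(end - start) + 1

    @property
    def mrna_length(self) -> int:
        return sum(self.exon_length(i) for i in range(1, self.n_exons + 1))

    def exon_offset(self, index: int) -> int:
        """0-based offset of the first base of exon ``index`` in the mRNA."""
        return sum(self.exon_length(i) for i in range(1, index))

    @property
    def last_junction_offset(self) -> int:
        """0-based mRNA position of the last exon-exon junction."""
        return self.mrna_length - self.exon_length(self.n_exons)


@dataclass
class GenomicDeletion:
    """A deletion described by its first and last deleted bases (1-based)."""

    chrom: str
    first_deleted: int
    last_deleted: int
    microhomology: str = ""

    def __post_init__(self) -> None:
        if self.first_deleted > self.last_deleted:
            raise ValueError(
                f"first_deleted {self.first_deleted} > last_deleted {self.last_deleted}"
            )
        if self.first_deleted < 1:
            raise ValueError("positions are 1-based")

    @property
    def span(self) -> int:
        return self.last_deleted - self.first_deleted + 1


def deletion_span(d: GenomicDeletion) -> int:
    """Size of a deletion in bp under the 1-based inclusive convention.

    The printed CRIM1 breakpoint pair (36,769,283; 36,778,290) yields
    9,008 bp only under this convention.
    """
    return d.last_deleted - d.first_deleted + 1


@dataclass
class CnvEvent:
    """A structural candidate event (whole-exon/gene deletion) entering
    classification alongside SNV/indel records.

    Multi-exon deletions are treated as null alleles.  ``genotypes`` use
    the same carrier semantics as :class:`VariantRecord`.
    """

    genes: tuple[str, ...]
    deletion: GenomicDeletion
    exon_span: str = ""
    genotypes: dict[str, Genotype] = field(default_factory=dict)
    label: str = ""

    @property
    def gene(self) -> str:
        return self.genes[0]

    @property
    def key(self) -> str:
        return self.label or (
            f"{self.gene}:del({self.deletion.first_deleted}-{self.deletion.last_deleted})"
        )

    @property
    def het_af(self) -> float:
        return 0.0

    def carriers(self) -> list[str]:
        return [s for s, g in self.genotypes.items() if g in CARRIER_GENOTYPES]
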