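"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a panel-restricted exome screen of small
eye-malformation pedigrees: families of three architectures (trio,
three-generation, index-only) carry a Poisson background of benign
panel variants (population allele frequencies from a zero-inflated
Beta, predictor votes binomial) plus, per the family's inheritance
model, a planted causal event — a de novo dominant variant, an
inherited dominant variant with reduced penetrance tolerated, or a
compound-heterozygous SNV-plus-CNV pair mirroring an SNV in trans with
a multi-exon deletion.  Per-exon coverage depths are Gaussian around
copy-number expectation, STR trios are drawn from a marker allele pool,
and junction constructions plant an exact-length microhomology.

All outputs are deterministic given the seed, and writers emit exactly
the text formats the core readers accept.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .model import (
    Affection,
    Consequence,
    GenePanel,
    Genotype,
    GenomicDeletion,
    GvgdGrade,
    Individual,
    MutationTasterCall,
    PredictionProfile,
    Sex,
    VariantRecord,
)
from .cnv import JunctionRead
from .segregation import StrProfile
from . import io as mio


class FamilyModel(enum.Enum):
    DE_NOVO_DOMINANT = "de_novo_dominant"
    INHERITED_DOMINANT = "inherited_dominant_reduced_penetrance"
    COMPOUND_HET_SNV_CNV = "compound_het_snv_cnv"
    UNSOLVED = "unsolved"


class Architecture(enum.Enum):
    TRIO = "trio"
    THREE_GENERATION = "three_generation"
    INDEX_ONLY = "index_only"


#: Architectures in which each inheritance model can be realized.
COMPATIBLE_ARCHITECTURES = {
    FamilyModel.DE_NOVO_DOMINANT: (Architecture.TRIO,),
    FamilyModel.INHERITED_DOMINANT: (Architecture.THREE_GENERATION,),
    FamilyModel.COMPOUND_HET_SNV_CNV: (Architecture.TRIO,),
    FamilyModel.UNSOLVED: tuple(Architecture),
}


@dataclass
class SimConfig:
    """Generator parameters (defaults are the package's study conditions).

    The benign allele-frequency model is a 0.3 point mass at zero (never
    seen in controls) mixed with Beta(0.2, 5); benign deleterious-vote
    counts are Binomial(5, 0.1) and causal ones Binomial(5, 0.8) clamped
    to >=3; per-exon depth is Normal(100 * copy/2, 10) truncated at 0.
    """

    n_families: int = 15
    architecture_weights: dict = field(
        default_factory=lambda: {
            Architecture.TRIO: 0.5,
            Architecture.THREE_GENERATION: 0.3,
            Architecture.INDEX_ONLY: 0.2,
        }
    )
    model_weights: dict = field(
        default_factory=lambda: {
            FamilyModel.DE_NOVO_DOMINANT: 0.25,
            FamilyModel.INHERITED_DOMINANT: 0.2,
            FamilyModel.COMPOUND_HET_SNV_CNV: 0.2,
            FamilyModel.UNSOLVED: 0.35,
        }
    )
    background_mean: float = 40.0
    af_zero_weight: float = 0.3
    af_beta: tuple[float, float] = (0.2, 5.0)
    benign_vote_p: float = 0.1
    causal_vote_p: float = 0.8
    causal_lof_fraction: float = 0.6
    csq_weights: dict = field(
        default_factory=lambda: {
            Consequence.MISSENSE: 0.5,
            Consequence.SYNONYMOUS: 0.2,
            Consequence.INTRONIC: 0.25,
            Consequence.UTR: 0.05,
        }
    )
    synonymous_dist_max: int = 100
    intronic_dist_max: int = 200
    depth_mean: float = 100.0
    depth_sd: float = 10.0
    coverage_genes: int = 20
    exons_per_gene: int = 8
    cnv_exons: int = 3
    str_markers: int = 24
    str_allele_pool: int = 10
    panel_size: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        for weights in (self.architecture_weights, self.model_weights):
            total = sum(weights.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"weights must sum to 1, got {total}")
        if self.background_mean < 0 or self.depth_sd < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class FamilyTruth:
    family: str
    model: FamilyModel
    causal_keys: list[str] = field(default_factory=list)
    cnv_gene: Optional[str] = None
    cnv_exons: Optional[tuple[int, int]] = None
    cnv_samples: list[str] = field(default_factory=list)

    @property
    def solvable(self) -> bool:
        return self.model is not FamilyModel.UNSOLVED


@dataclass
class TruthSet:
    families: dict[str, FamilyTruth] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            fam: {
                "model": t.model.value,
                "causal_keys": t.causal_keys,
                "cnv_gene": t.cnv_gene,
                "cnv_exons": list(t.cnv_exons) if t.cnv_exons else None,
                "cnv_samples": t.cnv_samples,
            }
            for fam, t in sorted(self.families.items())
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class SimulatedCohort:
    cohort: list[Individual]
    variants: list[VariantRecord]
    coverage: pd.DataFrame
    str_profiles: dict[str, StrProfile]
    panel: GenePanel
    truth: TruthSet

    def write(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        mio.write_pedigree(self.cohort, f"{outdir}/cohort.ped")
        mio.write_variants(self.variants, f"{outdir}/variants.tsv")
        self.coverage.reset_index().to_csv(
            f"{outdir}/coverage.tsv", sep="\t", index=False
        )
        rows = []
        for sid in sorted(self.str_profiles):
            prof = self.str_profiles[sid]
            for marker in sorted(prof.genotypes):
                a1, a2 = prof.genotypes[marker]
                rows.append((sid, marker, a1, a2))
        pd.DataFrame(rows, columns=["individual", "marker", "allele1", "allele2"]).to_csv(
            f"{outdir}/str_profiles.tsv", sep="\t", index=False
        )
        with open(f"{outdir}/panel.txt", "w") as fh:
            for gene in sorted(self.panel.entries):
                fh.write(gene + "\n")
        with open(f"{outdir}/truth.json", "w") as fh:
            fh.write(self.truth.to_json())


# ---------------------------------------------------------------------------
# helpers

def _stable_chrom(gene: str) -> str:
    # deterministic across processes (unlike hash())
    return str(1 + sum(ord(c) for c in gene) % 22)


_BENIGN_PROFILE = dict(sift=0.8, mt=MutationTasterCall.POLYMORPHISM, fmkl=0.1,
                       cadd=3.0, gvgd=GvgdGrade.C0)
_DELETERIOUS_PROFILE = dict(sift=0.01, mt=MutationTasterCall.DISEASE_CAUSING,
                            fmkl=0.95, cadd=28.0, gvgd=GvgdGrade.C65)


def _profile_with_votes(votes: int) -> PredictionProfile:
    """A predictor profile with exactly ``votes`` deleterious calls
    (at default thresholds), filled in a fixed predictor order."""
    picks = [v < votes for v in range(5)]
    src = [_DELETERIOUS_PROFILE if p else _BENIGN_PROFILE for p in picks]
    return PredictionProfile(
        sift=src[0]["sift"],
        mutation_taster=src[1]["mt"],
        fathmm_mkl=src[2]["fmkl"],
        cadd_phred=src[3]["cadd"],
        align_gvgd=src[4]["gvgd"],
    )


def _draw_af(rng: np.random.Generator, cfg: SimConfig) -> float:
    if rng.random() < cfg.af_zero_weight:
        return 0.0
    return float(min(1.0, rng.beta(*cfg.af_beta)))


def _make_panel(cfg: SimConfig) -> GenePanel:
    genes = [f"GENE{i:03d}" for i in range(1, cfg.panel_size + 1)]
    return GenePanel(entries=frozenset(genes))


def _weighted_choice(rng, weights: dict):
    keys = list(weights)
    probs = np.array([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def _family_members(family: str, arch: Architecture, rng) -> list[Individual]:
    def ind(local, sex, father=None, mother=None, affected=False, index=False):
        return Individual(
            id=f"{family}:{local}",
            family=family,
            sex=sex,
            father_id=f"{family}:{father}" if father else None,
            mother_id=f"{family}:{mother}" if mother else None,
            affection=Affection.AFFECTED if affected else Affection.UNAFFECTED,
            is_index=index,
            has_coloboma=affected,
            has_microphthalmia=bool(affected and rng.random() < 0.35),
            extraocular_at_enrollment=bool(affected and rng.random() < 0.3),
        )

    if arch is Architecture.TRIO:
        return [
            ind("I:1", Sex.MALE),
            ind("I:2", Sex.FEMALE),
            ind("II:1", rng.choice([Sex.MALE, Sex.FEMALE]), "I:1", "I:2",
                affected=True, index=True),
        ]
    if arch is Architecture.THREE_GENERATION:
        return [
            ind("I:1", Sex.MALE, affected=True),
            ind("I:2", Sex.FEMALE),
            ind("II:1", Sex.MALE, "I:1", "I:2", affected=True),
            ind("II:2", Sex.FEMALE),
            ind("III:1", rng.choice([Sex.MALE, Sex.FEMALE]), "II:1", "II:2",
                affected=True, index=True),
        ]
    return [ind("II:1", rng.choice([Sex.MALE, Sex.FEMALE]), affected=True, index=True)]


def _transmit(members: list[Individual], origin: str, rng) -> dict[str, Genotype]:
    """Drop one het allele from ``origin`` down the pedigree (p=1/2 per
    meiosis); returns genotypes for every family member."""
    genotypes = {m.id: Genotype.REF for m in members}
    genotypes[origin] = Genotype.HET
    by_id = {m.id: m for m in members}
    # children in declaration order follow their parents
    for m in members:
        if m.father_id is None and m.mother_id is None:
            continue
        carrier_parent = any(
            genotypes.get(p) is Genotype.HET
            for p in (m.father_id, m.mother_id)
            if p in by_id
        )
        if carrier_parent and rng.random() < 0.5:
            genotypes[m.id] = Genotype.HET
    return genotypes


def _background_variant(
    family: str,
    members: list[Individual],
    origin: str,
    idx: int,
    panel_genes: list[str],
    cfg: SimConfig,
    rng,
) -> VariantRecord:
    gene = panel_genes[rng.integers(len(panel_genes))]
    csq = _weighted_choice(rng, cfg.csq_weights)
    boundary = None
    intron = exon = None
    if csq is Consequence.SYNONYMOUS:
        boundary = int(rng.integers(1, cfg.synonymous_dist_max + 1))
        exon = int(rng.integers(1, 10))
    elif csq is Consequence.INTRONIC:
        boundary = -int(rng.integers(1, cfg.intronic_dist_max + 1))
        intron = int(rng.integers(1, 10))
    else:
        exon = int(rng.integers(1, 10))
    votes = int(rng.binomial(5, cfg.benign_vote_p)) if csq is Consequence.MISSENSE else 0
    return VariantRecord(
        chrom=_stable_chrom(gene),
        pos=1_000_000 + idx,
        ref="A",
        alt="G",
        gene=gene,
        hgvs_c=f"c.{idx}A>G",
        consequence=csq,
        exon_index=exon,
        intron_index=intron,
        boundary_distance=boundary,
        het_af=_draw_af(rng, cfg),
        hom_af=0.0,
        predictions=_profile_with_votes(votes),
        splice_delta=None,
        genotypes=_transmit(members, origin, rng),
    )


def _causal_variant(
    family: str,
    members: list[Individual],
    carriers: dict[str, Genotype],
    idx: int,
    gene: str,
    cfg: SimConfig,
    rng,
    force_lof: Optional[bool] = None,
) -> VariantRecord:
    lof = force_lof if force_lof is not None else rng.random() < cfg.causal_lof_fraction
    if lof:
        csq = Consequence.FRAMESHIFT
        votes = 0
    else:
        csq = Consequence.MISSENSE
        votes = max(3, int(rng.binomial(5, cfg.causal_vote_p)))
    genotypes = {m.id: Genotype.REF for m in members}
    genotypes.update(carriers)
    return VariantRecord(
        chrom=_stable_chrom(gene),
        pos=2_000_000 + idx,
        ref="C",
        alt="T",
        gene=gene,
        hgvs_c=f"c.{idx}C>T" if not lof else f"c.{idx}del",
        consequence=csq,
        exon_index=int(rng.integers(1, 10)),
        het_af=0.0,
        hom_af=0.0,
        predictions=_profile_with_votes(votes),
        genotypes=genotypes,
    )


def _str_trio(
    child: str, father: str, mother: str, cfg: SimConfig, rng
) -> dict[str, StrProfile]:
    markers = [f"M{i:02d}" for i in range(1, cfg.str_markers + 1)]
    pool = list(range(8, 8 + cfg.str_allele_pool))
    profs = {s: StrProfile(individual=s) for s in (child, father, mother)}
    for marker in markers:
        pat = (pool[rng.integers(len(pool))], pool[rng.integers(len(pool))])
        mat = (pool[rng.integers(len(pool))], pool[rng.integers(len(pool))])
        child_pair = (pat[rng.integers(2)], mat[rng.integers(2)])
        profs[father].genotypes[marker] = pat
        profs[mother].genotypes[marker] = mat
        profs[child].genotypes[marker] = child_pair
    return profs


def random_str_profile(individual: str, cfg: SimConfig, rng) -> StrProfile:
    """An individual drawn from the population allele pool (unrelated)."""
    markers = [f"M{i:02d}" for i in range(1, cfg.str_markers + 1)]
    pool = list(range(8, 8 + cfg.str_allele_pool))
    prof = StrProfile(individual=individual)
    for marker in markers:
        prof.genotypes[marker] = (
            pool[rng.integers(len(pool))],
            pool[rng.integers(len(pool))],
        )
    return prof


# ---------------------------------------------------------------------------
# cohort simulation

def simulate_cohort(cfg: SimConfig, seed: Optional[int] = None) -> SimulatedCohort:
    """Generate a cohort plus ground truth, deterministic given the seed."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    panel = _make_panel(cfg)
    panel_genes = sorted(panel.entries)
    coverage_genes = panel_genes[: cfg.coverage_genes]

    cohort: list[Individual] = []
    variants: list[VariantRecord] = []
    str_profiles: dict[str, StrProfile] = {}
    truth = TruthSet()
    variant_counter = 0

    # coverage targets shared by all samples
    targets = []
    for g_i, gene in enumerate(coverage_genes):
        for exon in range(1, cfg.exons_per_gene + 1):
            start = 1_000_000 * (g_i + 1) + exon * 2_000
            targets.append((gene, exon, str(1 + g_i % 22), start, start + 150))
    target_index = pd.MultiIndex.from_tuples(
        targets, names=["GENE", "EXON", "CHROM", "START", "END"]
    )
    coverage_cols: dict[str, np.ndarray] = {}

    for fam_i in range(cfg.n_families):
        family = f"F{fam_i + 1:03d}"
        model = _weighted_choice(rng, cfg.model_weights)
        arch_weights = {
            a: w
            for a, w in cfg.architecture_weights.items()
            if a in COMPATIBLE_ARCHITECTURES[model] and w > 0
        }
        if not arch_weights:
            raise ValueError(
                f"no compatible architecture with positive weight for model "
                f"{model.value} (needs one of "
                f"{[a.value for a in COMPATIBLE_ARCHITECTURES[model]]})"
            )
        arch = _weighted_choice(rng, arch_weights)
        members = _family_members(family, arch, rng)
        cohort.extend(members)
        fam_truth = FamilyTruth(family=family, model=model)
        by_id = {m.id: m for m in members}
        index = next(m for m in members if m.is_index)

        # background: Poisson(mean) private variants per founder
        founders = [m for m in members if m.father_id is None]
        for founder in founders:
            for _ in range(int(rng.poisson(cfg.background_mean))):
                variant_counter += 1
                variants.append(
                    _background_variant(
                        family, members, founder.id, variant_counter,
                        panel_genes, cfg, rng,
                    )
                )

        # per-sample copy numbers for the coverage matrix
        copy: dict[str, np.ndarray] = {
            m.id: np.full(len(targets), 2, dtype=float) for m in members
        }

        if model is FamilyModel.DE_NOVO_DOMINANT:
            variant_counter += 1
            v = _causal_variant(
                family, members, {index.id: Genotype.HET}, variant_counter,
                panel_genes[int(rng.integers(len(panel_genes)))], cfg, rng,
            )
            variants.append(v)
            fam_truth.causal_keys.append(v.key)
            str_profiles.update(
                _str_trio(index.id, index.father_id, index.mother_id, cfg, rng)
            )
        elif model is FamilyModel.INHERITED_DOMINANT:
            carriers = {
                m.id: Genotype.HET
                for m in members
                if m.affection is Affection.AFFECTED
            }
            variant_counter += 1
            v = _causal_variant(
                family, members, carriers, variant_counter,
                panel_genes[int(rng.integers(len(panel_genes)))], cfg, rng,
            )
            variants.append(v)
            fam_truth.causal_keys.append(v.key)
        elif model is FamilyModel.COMPOUND_HET_SNV_CNV:
            gene_i = int(rng.integers(len(coverage_genes)))
            gene = coverage_genes[gene_i]
            variant_counter += 1
            v = _causal_variant(
                family, members,
                {index.id: Genotype.HEMI, index.mother_id: Genotype.HET},
                variant_counter, gene, cfg, rng, force_lof=True,
            )
            variants.append(v)
            fam_truth.causal_keys.append(v.key)
            first_exon = int(rng.integers(1, cfg.exons_per_gene - cfg.cnv_exons + 2))
            exon_slice = slice(
                gene_i * cfg.exons_per_gene + first_exon - 1,
                gene_i * cfg.exons_per_gene + first_exon - 1 + cfg.cnv_exons,
            )
            for sid in (index.id, index.father_id):
                copy[sid][exon_slice] = 1
            fam_truth.cnv_gene = gene
            fam_truth.cnv_exons = (first_exon, first_exon + cfg.cnv_exons - 1)
            fam_truth.cnv_samples = [index.id, index.father_id]
            str_profiles.update(
                _str_trio(index.id, index.father_id, index.mother_id, cfg, rng)
            )

        for sid, copies in copy.items():
            depths = rng.normal(cfg.depth_mean * copies / 2.0, cfg.depth_sd)
            coverage_cols[sid] = np.clip(depths, 0.0, None)

        truth.families[family] = fam_truth

    coverage = pd.DataFrame(coverage_cols, index=target_index)
    return SimulatedCohort(
        cohort=cohort,
        variants=variants,
        coverage=coverage,
        str_profiles=str_profiles,
        panel=panel,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# junction simulation

_BASES = np.array(list("ACGT"))


def simulate_junction(
    reference_length: int,
    deletion_span: int,
    microhomology_length: int,
    seed: int,
    motif: Optional[str] = None,
    flank: int = 60,
) -> tuple[dict[str, tuple[str, int]], JunctionRead, GenomicDeletion]:
    """Construct references whose breakpoint flanks share exactly
    ``microhomology_length`` identical bases (no longer run), the
    junction read across the deletion, and the ground truth.

    The truth deletion is the representative with the microhomology on
    the proximal retained side.  ``motif`` optionally fixes the shared
    bases (its length must equal ``microhomology_length``).
    """
    k, span = microhomology_length, deletion_span
    if span < 1:
        raise ValueError("deletion span must be >= 1")
    if k < 0:
        raise ValueError("microhomology length must be >= 0")
    if k > span:
        raise ValueError(f"microhomology length {k} exceeds deletion span {span}")
    if motif is not None and len(motif) != k:
        raise ValueError("motif length must equal microhomology_length")
    needed = span + 2 * (flank + k + 2)
    if reference_length < needed:
        raise ValueError(f"reference_length must be >= {needed}")

    rng = np.random.default_rng(seed)
    seq = rng.choice(_BASES, size=reference_length)
    f = flank + k + 2  # 1-based first deleted base
    l = f + span - 1

    def set1(pos: int, base: str) -> None:
        seq[pos - 1] = base

    def get1(pos: int) -> str:
        return str(seq[pos - 1])

    def different_from(*bases: str) -> str:
        for b in "ACGT":
            if b not in bases:
                return b
        raise AssertionError

    if k:
        mh = motif.upper() if motif else "".join(
            str(b) for b in rng.choice(_BASES, size=k)
        )
        for j, base in enumerate(mh):
            set1(f - k + j, base)
            set1(l - k + 1 + j, base)
    # forbid extension of the ambiguity interval on either side
    if get1(f - k - 1) == get1(l - k):
        set1(f - k - 1, different_from(get1(l - k)))
    if get1(f) == get1(l + 1):
        set1(l + 1, different_from(get1(f)))

    ext = min(20, span)
    prox_start = max(1, f - flank)
    prox_end = f + ext - 1
    dist_start = l - ext + 1
    dist_end = min(reference_length, l + flank)
    joined = "".join(str(b) for b in seq)
    proximal_seq = joined[prox_start - 1 : prox_end]
    distal_seq = joined[dist_start - 1 : dist_end]
    read = joined[prox_start - 1 : f - 1] + joined[l : dist_end]
    junction = JunctionRead(
        sequence=read,
        proximal_seq=proximal_seq,
        proximal_offset=prox_start,
        distal_seq=distal_seq,
        distal_offset=dist_start,
        chrom="chrSim",
    )
    mh_seq = joined[f - k - 1 : f - 1] if k else ""
    truth = GenomicDeletion(
        chrom="chrSim", first_deleted=f, last_deleted=l, microhomology=mh_seq
    )
    references = {
        "proximal": (proximal_seq, prox_start),
        "distal": (distal_seq, dist_start),
    }
    return references, junction, truth


def write_junction_fasta(references: dict[str, tuple[str, int]], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=name, description=f"offset={offset}")
        for name, (seq, offset) in references.items()
    ]
    SeqIO.write(records, path, "fasta")
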