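"""Read-depth CNV detection over panel genes and breakpoint resolution
from deletion-spanning junction sequences.

Depths are normalized by a median-ratio scheme: each sample is divided
by its own median target depth (removing library-size effects), then
each target by its median across reference samples (removing capture
bias), so a diploid target has expected ratio 1.0, a heterozygous
deletion ~0.5, a homozygous deletion ~0, a duplication ~1.5.  Calls are
maximal runs of consecutive targets whose ratio falls in a copy-state
band.

Junction resolution finds every split of a junction read into a prefix
matching the proximal reference and a suffix matching the distal
reference.  When breakpoint flanks share terminal bases the valid
splits form an interval; those shared bases are the microhomology, and
the reported breakpoints assign it to the proximal retained side so the
deletion coordinates are unique.
"""

from __future__ import annotations

from dataclasses import dataclass
import enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import GenomicDeletion, deletion_span


class CopyState(enum.Enum):
    HET_DEL = "het_del"
    HOM_DEL = "hom_del"
    DUP = "dup"
    NORMAL = "normal"


@dataclass
class CnvConfig:
    """Bands on the normalized depth ratio and the minimum run length."""

    min_exons: int = 2
    het_del_band: tuple[float, float] = (0.35, 0.65)
    hom_del_band: tuple[float, float] = (0.0, 0.15)
    dup_min: float = 1.4


@dataclass
class CnvCall:
    sample: str
    genes: tuple[str, ...]
    chrom: str
    first_exon: int
    last_exon: int
    start: int
    end: int
    copy_state: CopyState
    mean_ratio: float
    n_targets: int
    resolved: Optional[GenomicDeletion] = None
    breakpoint_intervals: Optional[tuple[tuple[int, int], tuple[int, int]]] = None

    @property
    def exon_span(self) -> str:
        if self.first_exon == self.last_exon:
            return f"exon {self.first_exon}"
        return f"exons {self.first_exon}-{self.last_exon}"


def normalize_depth(
    matrix: pd.DataFrame, reference_samples: Optional[Sequence[str]] = None
) -> tuple[pd.DataFrame, list[tuple]]:
    """Median-ratio normalization of a targets x samples depth matrix.

    Returns the normalized matrix and the list of targets excluded
    because their reference median was zero.  Requires >=2 samples
    unless an explicit reference sample set is given.
    """
    if reference_samples is None:
        if matrix.shape[1] < 2:
            raise ValueError("need >=2 samples or an explicit reference sample set")
        reference_samples = list(matrix.columns)
    sample_medians = matrix.median(axis=0)
    if (sample_medians == 0).any():
        bad = list(sample_medians[sample_medians == 0].index)
        raise ValueError(f"samples with zero median depth: {bad}")
    scaled = matrix / sample_medians
    target_medians = scaled[list(reference_samples)].median(axis=1)
    excluded = list(scaled.index[target_medians == 0])
    keep = target_medians > 0
    normalized = scaled.loc[keep].div(target_medians[keep], axis=0)
    return normalized, excluded


def _state_of(ratio: float, cfg: CnvConfig) -> CopyState:
    lo, hi = cfg.hom_del_band
    if lo <= ratio <= hi:
        return CopyState.HOM_DEL
    lo, hi = cfg.het_del_band
    if lo <= ratio <= hi:
        return CopyState.HET_DEL
    if ratio >= cfg.dup_min:
        return CopyState.DUP
    return CopyState.NORMAL


def call_cnvs(normalized: pd.DataFrame, cfg: Optional[CnvConfig] = None) -> list[CnvCall]:
    """Call copy-state runs per sample from a normalized depth matrix.

    Targets are scanned in (chrom, start) order within each gene; a call
    is a maximal run of >= ``min_exons`` consecutive targets of one gene
    sharing a non-normal copy state.
    """
    cfg = cfg or CnvConfig()
    calls: list[CnvCall] = []
    # index levels: GENE, EXON, CHROM, START, END
    ordered = normalized.sort_index(level=["GENE", "START"], sort_remaining=False)
    for sample in ordered.columns:
        ratios = ordered[sample]
        run: list[tuple] = []
        run_state: Optional[CopyState] = None

        def flush() -> None:
            nonlocal run, run_state
            if run_state is not None and run_state is not CopyState.NORMAL and len(run) >= cfg.min_exons:
                genes = tuple(dict.fromkeys(t[0] for t in run))
                exons = [t[1] for t in run]
                starts = [t[3] for t in run]
                ends = [t[4] for t in run]
                calls.append(
                    CnvCall(
                        sample=sample,
                        genes=genes,
                        chrom=run[0][2],
                        first_exon=min(exons),
                        last_exon=max(exons),
                        start=min(starts),
                        end=max(ends),
                        copy_state=run_state,
                        mean_ratio=float(np.mean([ratios[t] for t in run])),
                        n_targets=len(run),
                    )
                )
            run, run_state = [], None

        for target, ratio in ratios.items():
            state = _state_of(float(ratio), cfg)
            same_gene = bool(run) and run[-1][0] == target[0]
            if state is run_state and same_gene:
                run.append(target)
            else:
                flush()
                if state is not CopyState.NORMAL:
                    run, run_state = [target], state
        flush()
    return calls


def write_calls(calls: Sequence[CnvCall], path) -> None:
    """Emit calls as a BED-like TSV (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("# coordinates are 1-based inclusive\n")
        fh.write("CHROM\tSTART\tEND\tSAMPLE\tGENES\tEXONS\tSTATE\tMEAN_RATIO\tN_TARGETS\n")
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.sample}\t{','.join(c.genes)}\t"
                f"{c.first_exon}-{c.last_exon}\t{c.copy_state.value}\t"
                f"{c.mean_ratio:.4g}\t{c.n_targets}\n"
            )


# ---------------------------------------------------------------------------
# Junction / microhomology resolution

@dataclass
class JunctionRead:
    """A deletion-spanning junction sequence with its two reference
    segments.

    ``proximal_offset`` / ``distal_offset`` are the 1-based genomic
    positions of the first base of each reference segment; the junction
    read is expected to start at the proximal segment's first base and
    end at the distal segment's last base.
    """

    sequence: str
    proximal_seq: str
    proximal_offset: int
    distal_seq: str
    distal_offset: int
    chrom: str = "."

    def __post_init__(self) -> None:
        alphabet = set("ACGTN")
        for name in ("sequence", "proximal_seq", "distal_seq"):
            seq = getattr(self, name).upper()
            object.__setattr__(self, name, seq)
            if not set(seq) <= alphabet:
                raise ValueError(f"{name} contains non-ACGTN characters")


def _common_prefix_len(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def resolve_junction(j: JunctionRead) -> GenomicDeletion:
    """Resolve a junction read into deletion breakpoints + microhomology.

    The read must decompose as ``proximal_seq[:a] + distal_seq[b:]``
    with ``b`` determined by the read length.  All valid ``a`` form an
    interval ``[n - S, P]`` where ``P``/``S`` are the maximal
    prefix/suffix match lengths; the interval's width is the
    microhomology length.  Reported coordinates retain the microhomology
    on the proximal side.
    """
    read, prox, dist = j.sequence, j.proximal_seq, j.distal_seq
    n = len(read)
    p_max = _common_prefix_len(read, prox)
    s_max = _common_prefix_len(read[::-1], dist[::-1])
    a_hi = min(p_max, n, len(prox))
    a_lo = max(n - s_max, 0, n - len(dist))
    if a_lo > a_hi:
        raise ValueError("junction does not span a deletion of these references")
    microhomology = read[a_lo:a_hi]
    a = a_hi  # proximal retains the ambiguous bases
    b = a + len(dist) - n
    first_deleted = j.proximal_offset + a
    last_deleted = j.distal_offset + b - 1
    if first_deleted > last_deleted:
        raise ValueError("junction does not span a deletion of these references")
    return GenomicDeletion(
        chrom=j.chrom,
        first_deleted=first_deleted,
        last_deleted=last_deleted,
        microhomology=microhomology,
    )


# ---------------------------------------------------------------------------
# Multiplex PCR span arithmetic

@dataclass
class Primer:
    name: str
    position: int  # 1-based genomic position of the primer's outermost base
    strand: str  # '+' forward, '-' reverse

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("primer strand must be '+' or '-'")


@dataclass
class PcrProduct:
    allele: str  # 'reference' or 'deleted'
    forward: str
    reverse: str
    length: int


def multiplex_fragments(
    primers: Sequence[Primer],
    deletion: Optional[GenomicDeletion] = None,
    max_length: Optional[int] = None,
) -> tuple[list[PcrProduct], list[str]]:
    """Expected product sizes for the reference and deleted alleles.

    Products are inclusive genomic spans between each forward/reverse
    primer pair; on the deleted allele a pair spanning the deletion
    shrinks by the deletion span, and a primer inside the deleted
    interval yields no product (reported as a warning).  ``max_length``
    optionally drops products too long to amplify.
    """
    warnings: list[str] = []
    products: list[PcrProduct] = []
    forwards = [p for p in primers if p.strand == "+"]
    reverses = [p for p in primers if p.strand == "-"]
    for f in forwards:
        for r in reverses:
            if r.position <= f.position:
                continue
            ref_len = r.position - f.position + 1
            if max_length is None or ref_len <= max_length:
                products.append(PcrProduct("reference", f.name, r.name, ref_len))
            if deletion is None:
                continue
            inside = [
                p.name
                for p in (f, r)
                if deletion.first_deleted <= p.position <= deletion.last_deleted
            ]
            if inside:
                warnings.append(
                    f"primer(s) {', '.join(inside)} inside deleted interval: "
                    f"no deleted-allele product for pair {f.name}/{r.name}"
                )
                continue
            if f.position < deletion.first_deleted and r.position > deletion.last_deleted:
                del_len = ref_len - deletion_span(deletion)
                if max_length is None or del_len <= max_length:
                    products.append(PcrProduct("deleted", f.name, r.name, del_len))
            else:
                # deletion not between the pair: same size on both alleles
                if max_length is None or ref_len <= max_length:
                    products.append(PcrProduct("deleted", f.name, r.name, ref_len))
    return products, warnings
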