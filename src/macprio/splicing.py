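"""Transcript arithmetic for splice events: RT-PCR fragment sizes,
frame/PTC consequences, and minigene inclusion/exclusion products.

Fragment prediction is pure arithmetic on declared splice events
(exon skipping, cryptic donor/acceptor usage, intron retention); no
splice-site strength model is involved — predicted alterations are
consumed upstream as the ``splice_delta`` annotation.  NMD candidacy
uses the standard 55-nt rule: a premature termination codon more than
55 nt upstream of the last exon-exon junction marks the transcript for
nonsense-mediated decay.
"""

from __future__ import annotations

from dataclasses import dataclass
import enum
from typing import Iterable, Optional

from .model import TranscriptModel

NMD_JUNCTION_RULE_NT = 55


class SpliceEventKind(enum.Enum):
    NONE = "none"
    EXON_SKIP = "exon_skip"
    CRYPTIC_DONOR = "cryptic_donor"
    CRYPTIC_ACCEPTOR = "cryptic_acceptor"
    INTRON_RETENTION = "intron_retention"


class FrameCall(enum.Enum):
    IN_FRAME = "in_frame"
    FRAMESHIFT = "frameshift"


@dataclass
class SpliceEvent:
    """A declared aberrant splicing outcome on one exon or intron.

    ``removed_nt`` counts exonic sequence lost (exon skip or cryptic
    site inside the exon); ``retained_nt`` counts intronic sequence
    kept (intron retention or cryptic site inside the intron).
    """

    kind: SpliceEventKind
    exon_index: Optional[int] = None
    intron_index: Optional[int] = None
    removed_nt: int = 0
    retained_nt: int = 0
    cryptic_site_offset: Optional[int] = None  # distance from the affected boundary

    def __post_init__(self) -> None:
        if self.removed_nt < 0 or self.retained_nt < 0:
            raise ValueError("removed_nt/retained_nt must be non-negative")
        if self.kind is SpliceEventKind.NONE and (self.removed_nt or self.retained_nt):
            raise ValueError("event 'none' cannot remove or retain sequence")

    @property
    def delta_nt(self) -> int:
        """Signed length change of the spliced product."""
        return self.retained_nt - self.removed_nt


@dataclass
class AmpliconDesign:
    """An RT-PCR amplicon on a transcript, spanning whole exons with
    primer offsets into the two terminal exons."""

    transcript_id: str
    first_exon: int
    last_exon: int
    forward_offset: int = 0  # nt trimmed from the 5' end of the first exon
    reverse_offset: int = 0  # nt of the last exon covered (0 = whole exon)

    def canonical_length(self, t: TranscriptModel) -> int:
        if not 1 <= self.first_exon <= self.last_exon <= t.n_exons:
            raise ValueError("amplicon exons outside transcript")
        total = sum(
            t.exon_length(i) for i in range(self.first_exon, self.last_exon + 1)
        )
        if self.forward_offset >= t.exon_length(self.first_exon):
            raise ValueError("forward primer offset outside its exon")
        total -= self.forward_offset
        if self.reverse_offset:
            if self.reverse_offset > t.exon_length(self.last_exon):
                raise ValueError("reverse primer offset outside its exon")
            total -= t.exon_length(self.last_exon) - self.reverse_offset
        return total


def _check_event(t: TranscriptModel, e: SpliceEvent) -> None:
    if e.kind in (SpliceEventKind.EXON_SKIP, SpliceEventKind.CRYPTIC_DONOR, SpliceEventKind.CRYPTIC_ACCEPTOR):
        if e.exon_index is None:
            raise ValueError(f"{e.kind.value} event needs an exon index")
        if not 1 <= e.exon_index <= t.n_exons:
            raise ValueError(f"exon {e.exon_index} outside transcript")
        if e.removed_nt > t.exon_length(e.exon_index):
            raise ValueError(
                f"removed_nt {e.removed_nt} exceeds exon {e.exon_index} length "
                f"{t.exon_length(e.exon_index)}"
            )


def predict_fragments(
    t: TranscriptModel,
    amplicon: AmpliconDesign,
    events: Iterable[SpliceEvent],
) -> list[tuple[SpliceEvent, int]]:
    """Product length per event: canonical length - removed + retained.

    An event on an exon/intron outside the amplicon is an error; the
    ``none`` event returns the canonical product.
    """
    canonical = amplicon.canonical_length(t)
    out = []
    for e in events:
        if e.kind is SpliceEventKind.NONE:
            out.append((e, canonical))
            continue
        _check_event(t, e)
        affected = e.exon_index if e.exon_index is not None else e.intron_index
        if affected is None or not amplicon.first_exon <= affected <= amplicon.last_exon:
            raise ValueError(
                f"event on exon/intron {affected} outside amplicon "
                f"{amplicon.first_exon}-{amplicon.last_exon}"
            )
        out.append((e, canonical + e.delta_nt))
    return out


@dataclass
class EventConsequence:
    frame: FrameCall
    ptc_codon: Optional[int]
    nmd_candidate: bool


def consequence_of_event(
    t: TranscriptModel,
    e: SpliceEvent,
    ptc_codon: Optional[int] = None,
) -> EventConsequence:
    """Frame and PTC/NMD consequence of a splice event.

    The frame call is fully determined by the event's length change
    modulo 3.  A frameshift introduces a premature termination codon
    whose exact position depends on the coding sequence; when known
    (``ptc_codon``, 1-based codon index), NMD candidacy is assessed by
    the 55-nt junction rule against the unspliced transcript's exon
    structure.  Events confined to untranslated regions are in-frame
    with no PTC.
    """
    affected_exon = e.exon_index
    if affected_exon is not None:
        exon_end_offset = t.exon_offset(affected_exon) + t.exon_length(affected_exon)
        if exon_end_offset <= t.cds_start_offset:
            return EventConsequence(FrameCall.IN_FRAME, None, False)
    frame = FrameCall.IN_FRAME if e.delta_nt % 3 == 0 else FrameCall.FRAMESHIFT
    if ptc_codon is None:
        return EventConsequence(frame, None, False)
    ptc_mrna_pos = t.cds_start_offset + 3 * (ptc_codon - 1)
    nmd = ptc_mrna_pos <= t.last_junction_offset - NMD_JUNCTION_RULE_NT
    return EventConsequence(frame, ptc_codon, nmd)


def minigene_products(
    insert_exon_length: int,
    vector_exon_lengths: Iterable[int],
) -> tuple[int, int]:
    """Inclusion/exclusion product lengths of a minigene splicing assay.

    The reporter transcript consists of the vector exons with the test
    exon inserted between them: inclusion = sum(vector exons) + insert,
    exclusion = sum(vector exons).
    """
    vector_total = sum(vector_exon_lengths)
    if insert_exon_length <= 0:
        raise ValueError("insert exon length must be positive")
    if vector_total <= 0:
        raise ValueError("vector exon lengths must be positive")
    return vector_total + insert_exon_length, vector_total
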