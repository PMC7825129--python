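"""Machine-readable transcription of the study cohort's published data:
clinical table, candidate-variant tables, deletion coordinates, splice
fragment constants, and the evidence flags behind the final calls.

The fixture ships as versioned TSV/PED/YAML files inside the package
data directory and is the acceptance input for reproducing the
cohort-level detection rates.  Values the source does not print (primer
coordinates, most exon lengths, individual predictor scores beyond the
stated vote counts) are reconstructed and flagged as such in the data
files.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import yaml

from . import io as mio
from .classify import FunctionalEvidence
from .cnv import Primer
from .model import (
    Affection,
    CnvEvent,
    GenePanel,
    Genotype,
    GenomicDeletion,
    Individual,
    TranscriptModel,
    VariantRecord,
)
from .pipeline import EvidenceOverride
from .segregation import SegregationStatus, StrProfile
from .splicing import AmpliconDesign, SpliceEvent, SpliceEventKind

_FIXTURE_FILES = (
    "cohort.ped",
    "variants.tsv",
    "panel.txt",
    "cnv_events.yaml",
    "evidence.yaml",
    "constants.yaml",
    "str_profiles.tsv",
)


@dataclass
class FixtureBundle:
    cohort: list[Individual]
    variants: list[VariantRecord]
    cnv_events: list[CnvEvent]
    panel: GenePanel
    str_profiles: dict[str, StrProfile]
    overrides: dict[str, EvidenceOverride]
    constants: dict = field(default_factory=dict)

    # -- derived objects ---------------------------------------------------
    def chd7_transcript(self) -> TranscriptModel:
        c = self.constants["chd7"]
        lengths = list(c["exon_lengths_head"])
        lengths += [c["exon_length_rest"]] * (c["n_exons"] - len(lengths))
        exons = []
        pos = c["genome_start"]
        for ln in lengths:
            exons.append((pos, pos + ln - 1))
            pos += ln + c["intron_length"]
        return TranscriptModel(
            transcript_id=c["transcript_id"],
            strand=c["strand"],
            exons=exons,
            cds_start_offset=c["cds_start_offset"],
        )

    def chd7_amplicon(self) -> AmpliconDesign:
        a = self.constants["chd7"]["amplicon"]
        return AmpliconDesign(
            transcript_id=self.constants["chd7"]["transcript_id"],
            first_exon=a["first_exon"],
            last_exon=a["last_exon"],
            forward_offset=a["forward_offset"],
            reverse_offset=a["reverse_offset"],
        )

    def chd7_cryptic_donor(self) -> SpliceEvent:
        e = self.constants["chd7"]["cryptic_donor"]
        return SpliceEvent(
            kind=SpliceEventKind.CRYPTIC_DONOR,
            exon_index=e["exon_index"],
            removed_nt=e["removed_nt"],
        )

    def crim1_deletion(self) -> GenomicDeletion:
        d = self.constants["crim1_deletion"]
        return GenomicDeletion(
            chrom=str(d["chrom"]),
            first_deleted=d["first_deleted"],
            last_deleted=d["last_deleted"],
            microhomology=d.get("microhomology", ""),
        )

    def fat1_deletion(self) -> GenomicDeletion:
        d = self.constants["fat1_deletion"]
        return GenomicDeletion(
            chrom=str(d["chrom"]),
            first_deleted=d["first_deleted"],
            last_deleted=d["last_deleted"],
        )

    def crim1_primers(self) -> list[Primer]:
        return [
            Primer(p["name"], p["position"], p["strand"])
            for p in self.constants["crim1_multiplex"]["primers"]
        ]

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        clinical = [i for i in self.cohort if i.in_clinical_table]
        if len(clinical) != 21:
            raise ValueError(f"expected 21 clinical-table individuals, got {len(clinical)}")
        affected = [i for i in self.cohort if i.affection is Affection.AFFECTED]
        if len(affected) != 19:
            raise ValueError(f"expected 19 affected individuals, got {len(affected)}")
        families = {i.family for i in self.cohort}
        if len(families) != 15:
            raise ValueError(f"expected 15 families, got {len(families)}")
        n_index = sum(i.is_index for i in self.cohort)
        if n_index != 15:
            raise ValueError(f"expected 15 index patients, got {n_index}")
        if len(self.variants) != 13:
            raise ValueError(f"expected 13 SNV/indel rows, got {len(self.variants)}")
        if len(self.cnv_events) != 2:
            raise ValueError(f"expected 2 structural events, got {len(self.cnv_events)}")


def _data_dir():
    return resources.files("macprio") / "data" / "fixture"


def fixture_checksums() -> dict[str, str]:
    root = _data_dir()
    return {
        name: hashlib.sha256((root / name).read_bytes()).hexdigest()
        for name in _FIXTURE_FILES
    }


def load_fixture(verify_checksums: bool = True) -> FixtureBundle:
    """Load and validate the fixture bundle from package data."""
    root = _data_dir()
    if verify_checksums:
        recorded_path = root / "checksums.sha256"
        recorded = {}
        for line in recorded_path.read_text().splitlines():
            if line.strip():
                digest, name = line.split()
                recorded[name] = digest
        actual = fixture_checksums()
        mismatched = [n for n, d in recorded.items() if actual.get(n) != d]
        if mismatched:
            raise ValueError(f"fixture checksum mismatch: {mismatched}")

    import tempfile, os

    # readers take paths; materialize package resources
    with tempfile.TemporaryDirectory() as tmp:
        for name in _FIXTURE_FILES:
            with open(os.path.join(tmp, name), "wb") as fh:
                fh.write((root / name).read_bytes())
        cohort = mio.read_pedigree(os.path.join(tmp, "cohort.ped"))
        variants = mio.read_variants(os.path.join(tmp, "variants.tsv"), dialect="tsv")
        panel = mio.read_panel(os.path.join(tmp, "panel.txt"))
        str_raw = mio.read_str_profiles(os.path.join(tmp, "str_profiles.tsv"))

    str_profiles = {
        sid: StrProfile(individual=sid, genotypes=genos)
        for sid, genos in str_raw.items()
    }

    cnv_raw = yaml.safe_load((root / "cnv_events.yaml").read_text())
    cnv_events = []
    for e in cnv_raw["events"]:
        cnv_events.append(
            CnvEvent(
                genes=tuple(e["genes"]),
                deletion=GenomicDeletion(
                    chrom=str(e["chrom"]),
                    first_deleted=e["first_deleted"],
                    last_deleted=e["last_deleted"],
                    microhomology=e.get("microhomology", "") or "",
                ),
                exon_span=e.get("exon_span", ""),
                genotypes={s: Genotype(g) for s, g in e["genotypes"].items()},
                label=e["label"],
            )
        )

    ev_raw = yaml.safe_load((root / "evidence.yaml").read_text())
    overrides = {}
    for key, spec in (ev_raw.get("overrides") or {}).items():
        overrides[key] = EvidenceOverride(
            segregation=(
                SegregationStatus(spec["segregation"]) if "segregation" in spec else None
            ),
            functional=FunctionalEvidence(spec.get("functional", "untested")),
            functional_ref=spec.get("functional_ref", ""),
            alternative_cause_in_family=spec.get("alternative_cause_in_family", False),
        )

    constants = yaml.safe_load((root / "constants.yaml").read_text())
    bundle = FixtureBundle(
        cohort=cohort,
        variants=variants,
        cnv_events=cnv_events,
        panel=panel,
        str_profiles=str_profiles,
        overrides=overrides,
        constants=constants,
    )
    bundle.validate()
    return bundle
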