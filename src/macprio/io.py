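"""Readers and writers for the pipeline's tabular formats.

Variant tables are accepted either as annotated VCF (v4.x, INFO keys
documented below) or as a TSV dialect carrying the same fields in
columns.  Frequencies may be given as fractions or with a ``%`` suffix
(divided by 100 on read; gnomAD values are printed as percentages in the
source tables).  Pedigrees are standard 6-column PED extended with
phenotype-flag columns; panels are plain gene-symbol lists or BED
intervals (BED's 0-based half-open coordinates are converted to 1-based
inclusive on read).

VCF INFO keys / TSV column names:
    GENE, TRANSCRIPT, HGVS_C, HGVS_P, CSQ (consequence class), EXON,
    INTRON, BDIST (signed boundary distance), HETAF, HOMAF, GVGD, FMKL,
    CADD, MT, SIFT, SPLICE_DELTA, PRIOR.
TSV genotype columns are named ``GT:<sample-id>`` with values
ref/het/hom/hemi/. ; VCF genotypes come from the GT FORMAT field.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional, Union

import pandas as pd

from .model import (
    Affection,
    Consequence,
    GenePanel,
    Genotype,
    GvgdGrade,
    Individual,
    MutationTasterCall,
    PredictionProfile,
    PriorReport,
    Sex,
    VariantRecord,
    validate_pedigree,
)

_MISSING = {"", ".", "na", "NA", "NaN", "nan", None}

TSV_COLUMNS = [
    "CHROM", "POS", "REF", "ALT", "GENE", "TRANSCRIPT", "HGVS_C", "HGVS_P",
    "CSQ", "EXON", "INTRON", "BDIST", "HETAF", "HOMAF", "GVGD", "FMKL",
    "CADD", "MT", "SIFT", "SPLICE_DELTA", "PRIOR",
]


def parse_frequency(text: Union[str, float, None]) -> float:
    """Parse an allele frequency; a ``%`` suffix divides by 100.

    Missing values (empty, '.', 'NA') parse as 0.0 — absence from gnomAD
    is treated as frequency zero.
    """
    if text is None or (isinstance(text, float) and pd.isna(text)):
        return 0.0
    if isinstance(text, (int, float)):
        value = float(text)
    else:
        text = text.strip()
        if text in _MISSING:
            return 0.0
        if text.endswith("%"):
            value = float(text[:-1]) / 100.0
        else:
            value = float(text)
    if value < 0:
        raise ValueError(f"negative allele frequency: {text!r}")
    return value


def format_frequency(x: float) -> str:
    return format(float(x), ".17g")


def _parse_consequence(text: str, where: str) -> Consequence:
    try:
        return Consequence(text.strip().lower())
    except ValueError:
        accepted = ", ".join(c.value for c in Consequence)
        raise ValueError(
            f"{where}: unknown consequence {text!r}; accepted: {accepted}"
        ) from None


def _opt_int(value) -> Optional[int]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, str):
        if value.strip() in _MISSING:
            return None
        return int(value)
    return int(value)


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, str):
        if value.strip() in _MISSING:
            return None
        return float(value)
    return float(value)


def _parse_profile(row, where: str) -> PredictionProfile:
    gvgd = row.get("GVGD")
    grade = None
    if gvgd is not None and not (isinstance(gvgd, float) and pd.isna(gvgd)):
        gvgd = str(gvgd).strip()
        if gvgd not in _MISSING:
            try:
                grade = GvgdGrade[gvgd.upper()]
            except KeyError:
                raise ValueError(f"{where}: unknown Align-GVGD grade {gvgd!r}") from None
    mt_raw = row.get("MT")
    mt = MutationTasterCall.MISSING
    if mt_raw is not None and not (isinstance(mt_raw, float) and pd.isna(mt_raw)):
        mt_raw = str(mt_raw).strip().lower()
        if mt_raw not in {m.lower() for m in _MISSING if m}:
            mt = MutationTasterCall(mt_raw)
    return PredictionProfile(
        align_gvgd=grade,
        fathmm_mkl=_opt_float(row.get("FMKL")),
        cadd_phred=_opt_float(row.get("CADD")),
        mutation_taster=mt,
        sift=_opt_float(row.get("SIFT")),
    )


def _opt_str(value) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    text = str(value)
    return "" if text.strip() in _MISSING else text


def _record_from_row(row: dict, genotype_cols: list[str], where: str) -> VariantRecord:
    prior_raw = row.get("PRIOR")
    prior = PriorReport.NONE
    if prior_raw is not None and not (isinstance(prior_raw, float) and pd.isna(prior_raw)):
        prior_raw = str(prior_raw).strip().lower()
        if prior_raw not in {m.lower() for m in _MISSING if m}:
            prior = PriorReport(prior_raw)
    genotypes = {}
    for col in genotype_cols:
        sample = col[3:]
        raw = row.get(col)
        if raw is None or (isinstance(raw, float) and pd.isna(raw)) or str(raw).strip() in _MISSING:
            genotypes[sample] = Genotype.MISSING
        else:
            genotypes[sample] = Genotype(str(raw).strip().lower())
    return VariantRecord(
        chrom=str(row["CHROM"]),
        pos=int(row["POS"]),
        ref=str(row["REF"]),
        alt=str(row["ALT"]),
        gene=str(row["GENE"]),
        transcript=_opt_str(row.get("TRANSCRIPT")),
        hgvs_c=_opt_str(row.get("HGVS_C")),
        hgvs_p=_opt_str(row.get("HGVS_P")),
        consequence=_parse_consequence(str(row["CSQ"]), where),
        exon_index=_opt_int(row.get("EXON")),
        intron_index=_opt_int(row.get("INTRON")),
        boundary_distance=_opt_int(row.get("BDIST")),
        het_af=parse_frequency(row.get("HETAF")),
        hom_af=parse_frequency(row.get("HOMAF")),
        predictions=_parse_profile(row, where),
        splice_delta=_opt_float(row.get("SPLICE_DELTA")),
        prior_report=prior,
        genotypes=genotypes,
    )


def read_variants_tsv(path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in ("CHROM", "POS", "REF", "ALT", "GENE", "CSQ") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns: {missing}")
    genotype_cols = [c for c in df.columns if c.startswith("GT:")]
    records = []
    for i, row in enumerate(df.to_dict("records")):
        where = f"{path}:line {i + 2}"  # header is line 1
        try:
            records.append(_record_from_row(row, genotype_cols, where))
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{where}: {exc}") from exc
    return records


def read_variants_vcf(path) -> list[VariantRecord]:
    """Read an annotated VCF; one record is emitted per ALT allele."""
    import pysam

    records = []
    with pysam.VariantFile(os.fspath(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            info = dict(rec.info)
            for alt_i, alt in enumerate(rec.alts or ()):
                genotypes = {}
                for sample in samples:
                    gt = rec.samples[sample].get("GT")
                    if gt is None or all(a is None for a in gt):
                        genotypes[sample] = Genotype.MISSING
                    else:
                        alleles = [a for a in gt if a is not None]
                        n_alt = sum(a == alt_i + 1 for a in alleles)
                        if len(alleles) == 1:
                            genotypes[sample] = (
                                Genotype.HEMI if n_alt == 1 else Genotype.REF
                            )
                        elif n_alt == 0:
                            genotypes[sample] = Genotype.REF
                        elif n_alt == len(alleles):
                            genotypes[sample] = Genotype.HOM
                        else:
                            genotypes[sample] = Genotype.HET

                def _info(key, default=None):
                    val = info.get(key, default)
                    if isinstance(val, tuple):
                        val = val[alt_i] if alt_i < len(val) else val[0]
                    return val

                where = f"{path}:{rec.chrom}:{rec.pos}"
                row = {
                    "CHROM": rec.chrom,
                    "POS": rec.pos,
                    "REF": rec.ref,
                    "ALT": alt,
                    "GENE": _info("GENE", ""),
                    "TRANSCRIPT": _info("TRANSCRIPT", ""),
                    "HGVS_C": _info("HGVS_C", ""),
                    "HGVS_P": _info("HGVS_P", ""),
                    "CSQ": _info("CSQ", "other"),
                    "EXON": _info("EXON"),
                    "INTRON": _info("INTRON"),
                    "BDIST": _info("BDIST"),
                    "HETAF": _info("HETAF"),
                    "HOMAF": _info("HOMAF"),
                    "GVGD": _info("GVGD"),
                    "FMKL": _info("FMKL"),
                    "CADD": _info("CADD"),
                    "MT": _info("MT"),
                    "SIFT": _info("SIFT"),
                    "SPLICE_DELTA": _info("SPLICE_DELTA"),
                    "PRIOR": _info("PRIOR"),
                }
                genotype_cols = [f"GT:{s}" for s in samples]
                row.update({f"GT:{s}": genotypes[s].value for s in samples})
                records.append(_record_from_row(row, genotype_cols, where))
    return records


def read_variants(path, dialect: str = "tsv") -> list[VariantRecord]:
    if dialect == "tsv":
        return read_variants_tsv(path)
    if dialect == "vcf":
        return read_variants_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'vcf'")


def write_variants(records: Iterable[VariantRecord], path) -> None:
    """Write records to the TSV dialect (bit-exact round trip)."""
    records = list(records)
    samples: list[str] = []
    for rec in records:
        for s in rec.genotypes:
            if s not in samples:
                samples.append(s)
    rows = []
    for rec in records:
        row = {
            "CHROM": rec.chrom,
            "POS": rec.pos,
            "REF": rec.ref,
            "ALT": rec.alt,
            "GENE": rec.gene,
            "TRANSCRIPT": rec.transcript or ".",
            "HGVS_C": rec.hgvs_c or ".",
            "HGVS_P": rec.hgvs_p or ".",
            "CSQ": rec.consequence.value,
            "EXON": "." if rec.exon_index is None else rec.exon_index,
            "INTRON": "." if rec.intron_index is None else rec.intron_index,
            "BDIST": "." if rec.boundary_distance is None else rec.boundary_distance,
            "HETAF": format_frequency(rec.het_af),
            "HOMAF": format_frequency(rec.hom_af),
            "GVGD": "." if rec.predictions.align_gvgd is None else rec.predictions.align_gvgd.name,
            "FMKL": "." if rec.predictions.fathmm_mkl is None else format(rec.predictions.fathmm_mkl, ".17g"),
            "CADD": "." if rec.predictions.cadd_phred is None else format(rec.predictions.cadd_phred, ".17g"),
            "MT": "." if rec.predictions.mutation_taster is MutationTasterCall.MISSING else rec.predictions.mutation_taster.value,
            "SIFT": "." if rec.predictions.sift is None else format(rec.predictions.sift, ".17g"),
            "SPLICE_DELTA": "." if rec.splice_delta is None else format(rec.splice_delta, ".17g"),
            "PRIOR": rec.prior_report.value,
        }
        for s in samples:
            row[f"GT:{s}"] = rec.genotypes.get(s, Genotype.MISSING).value
        rows.append(row)
    cols = TSV_COLUMNS + [f"GT:{s}" for s in samples]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Pedigrees

_PED_SEX = {"1": Sex.MALE, "2": Sex.FEMALE}
_PED_AFFECTION = {"1": Affection.UNAFFECTED, "2": Affection.AFFECTED}


def read_pedigree(path) -> list[Individual]:
    """Read a 6-column PED file with the phenotype-flag extension.

    Extension columns (after the 6 PED columns, named in a ``#``-prefixed
    header): COLOBOMA, MICROPHTHALMIA, EXTRAOCULAR, INDEX, CARRIER,
    TABLE1.  ``CARRIER=1`` marks asymptomatic carriers (PED affection 1);
    ``TABLE1=0`` marks members not part of the clinical table.
    """
    extension = ["COLOBOMA", "MICROPHTHALMIA", "EXTRAOCULAR", "INDEX", "CARRIER", "TABLE1"]
    header: Optional[list[str]] = None
    members: list[Individual] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                header = line.lstrip("#").split("\t")
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:line {lineno}: expected >=6 PED columns")
            names = header or (
                ["FID", "IID", "FATHER", "MOTHER", "SEX", "AFFECTION"] + extension
            )
            row = dict(zip(names, fields))
            fam, iid = row["FID"], row["IID"]
            father = row["FATHER"] if row["FATHER"] not in ("0", "") else None
            mother = row["MOTHER"] if row["MOTHER"] not in ("0", "") else None
            affection = _PED_AFFECTION.get(row["AFFECTION"], Affection.UNKNOWN)
            if row.get("CARRIER", "0") == "1":
                affection = Affection.ASYMPTOMATIC_CARRIER
            members.append(
                Individual(
                    id=iid,
                    family=fam,
                    sex=_PED_SEX.get(row["SEX"], Sex.UNKNOWN),
                    father_id=father,
                    mother_id=mother,
                    affection=affection,
                    is_index=row.get("INDEX", "0") == "1",
                    has_coloboma=row.get("COLOBOMA", "0") == "1",
                    has_microphthalmia=row.get("MICROPHTHALMIA", "0") == "1",
                    extraocular_at_enrollment=row.get("EXTRAOCULAR", "0") == "1",
                    in_clinical_table=row.get("TABLE1", "1") == "1",
                )
            )
    validate_pedigree(members)
    return members


def write_pedigree(members: Iterable[Individual], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#FID\tIID\tFATHER\tMOTHER\tSEX\tAFFECTION\tCOLOBOMA\t"
            "MICROPHTHALMIA\tEXTRAOCULAR\tINDEX\tCARRIER\tTABLE1\n"
        )
        for ind in members:
            sex = {"male": "1", "female": "2"}.get(ind.sex.value, "0")
            aff = {
                Affection.AFFECTED: "2",
                Affection.UNAFFECTED: "1",
                Affection.ASYMPTOMATIC_CARRIER: "1",
            }.get(ind.affection, "0")
            fh.write(
                "\t".join(
                    [
                        ind.family,
                        ind.id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        sex,
                        aff,
                        "1" if ind.has_coloboma else "0",
                        "1" if ind.has_microphthalmia else "0",
                        "1" if ind.extraocular_at_enrollment else "0",
                        "1" if ind.is_index else "0",
                        "1" if ind.affection is Affection.ASYMPTOMATIC_CARRIER else "0",
                        "1" if ind.in_clinical_table else "0",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Panels, coverage, STR profiles

def read_panel(path) -> GenePanel:
    """Read a gene panel from a symbol list or a BED file.

    BED files (detected by >=3 tab-separated columns with integer
    coordinates and a name in column 4) carry 0-based half-open
    intervals, converted here to 1-based inclusive.
    """
    symbols: list[str] = []
    intervals: dict[str, tuple[str, int, int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) >= 4 and fields[1].isdigit() and fields[2].isdigit():
                chrom, start0, end0, gene = fields[0], int(fields[1]), int(fields[2]), fields[3]
                symbols.append(gene)
                intervals[gene] = (chrom, start0 + 1, end0)
            else:
                symbols.append(fields[0])
    if len(symbols) != len(set(symbols)):
        dupes = sorted({s for s in symbols if symbols.count(s) > 1})
        raise ValueError(f"{path}: duplicate panel symbols: {dupes}")
    return GenePanel(entries=frozenset(symbols), intervals=intervals)


def read_coverage(path) -> pd.DataFrame:
    """Read a per-exon coverage TSV into a targets x samples DataFrame.

    The first four columns are GENE, EXON, CHROM, START, END (1-based
    inclusive); remaining columns are per-sample mean depths.
    """
    df = pd.read_csv(path, sep="\t")
    meta = ["GENE", "EXON", "CHROM", "START", "END"]
    missing = [c for c in meta if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing coverage columns: {missing}")
    if (df["START"] > df["END"]).any():
        raise ValueError(f"{path}: malformed target interval (START > END)")
    df = df.set_index(meta)
    if (df < 0).any().any():
        raise ValueError(f"{path}: negative depth")
    return df


def read_str_profiles(path) -> dict[str, dict[str, tuple[int, int]]]:
    """Read STR genotypes: columns individual, marker, allele1, allele2."""
    df = pd.read_csv(path, sep="\t")
    profiles: dict[str, dict[str, tuple[int, int]]] = {}
    for row in df.itertuples(index=False):
        profiles.setdefault(str(row.individual), {})[str(row.marker)] = (
            int(row.allele1),
            int(row.allele2),
        )
    return profiles
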