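import pytest

from macprio import FilterConfig, load_fixture
from macprio.model import (
    Consequence,
    Genotype,
    GvgdGrade,
    MutationTasterCall,
    PredictionProfile,
    PriorReport,
    VariantRecord,
)


@pytest.fixture(scope="session")
def fixture_bundle():
    return load_fixture()


@pytest.fixture(scope="session")
def default_config():
    return FilterConfig()


def make_variant(
    gene="PAX6",
    consequence=Consequence.MISSENSE,
    het_af=0.0,
    hom_af=0.0,
    boundary_distance=None,
    votes=0,
    splice_delta=None,
    prior=PriorReport.NONE,
    genotypes=None,
    pos=1000,
    hgvs_c="c.1A>G",
):
    """Convenience factory for a single annotated variant."""
    deleterious = dict(
        sift=0.01,
        mutation_taster=MutationTasterCall.DISEASE_CAUSING,
        fathmm_mkl=0.95,
        cadd_phred=28.0,
        align_gvgd=GvgdGrade.C65,
    )
    benign = dict(
        sift=0.9,
        mutation_taster=MutationTasterCall.POLYMORPHISM,
        fathmm_mkl=0.05,
        cadd_phred=2.0,
        align_gvgd=GvgdGrade.C0,
    )
    fields = {}
    for i, name in enumerate(["sift", "mutation_taster", "fathmm_mkl", "cadd_phred", "align_gvgd"]):
        fields[name] = (deleterious if i < votes else benign)[name]
    return VariantRecord(
        chrom="1",
        pos=pos,
        ref="A",
        alt="G",
        gene=gene,
        hgvs_c=hgvs_c,
        consequence=consequence,
        boundary_distance=boundary_distance,
        het_af=het_af,
        hom_af=hom_af,
        predictions=PredictionProfile(**fields),
        splice_delta=splice_delta,
        prior_report=prior,
        genotypes=genotypes or {"S1": Genotype.HET},
    )
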