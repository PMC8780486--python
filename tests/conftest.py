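import pytest

import cardiotrio as ct


@pytest.fixture(scope="session")
def panel():
    return ct.load_panel()


@pytest.fixture(scope="session")
def cohort():
    return ct.load_cohort_fixture()


@pytest.fixture
def male_trio():
    return ct.Pedigree("PROBAND", "MOTHER", "FATHER", "M")


@pytest.fixture
def write_sam(tmp_path):
    """Write SAM text (or simulator output) to a temp file, return the path."""

    def _write(text, name="reads.sam"):
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write


@pytest.fixture
def write_vcf(tmp_path):
    def _write(text, name="trio.vcf"):
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write


def make_pair(
    read_id="t1",
    chrom="chrS",
    pos=10_001,
    mapq=60,
    tlen=5000,
    is_reverse=False,
    mate_is_reverse=True,
    is_first_in_pair=True,
):
    return ct.ReadPairRecord(
        read_id=read_id,
        chrom=chrom,
        pos=pos,
        mapq=mapq,
        tlen=tlen,
        is_reverse=is_reverse,
        mate_is_reverse=mate_is_reverse,
        is_first_in_pair=is_first_in_pair,
    )


def make_variant(
    chrom="chr1",
    pos=1_000_000,
    ref="A",
    alt="T",
    gene="MYH7",
    consequence="missense",
    gt=("het", "hom_ref", "hom_ref"),
    af_pop=None,
    clinical_class="pathogenic",
):
    return ct.TrioVariant(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        consequence=consequence,
        gt_proband=gt[0],
        gt_mother=gt[1],
        gt_father=gt[2],
        af_pop=af_pop,
        clinical_class=clinical_class,
    )
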