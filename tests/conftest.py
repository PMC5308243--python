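import pytest

from intronsig.simulate import generate_cohort, paper_style_cohort, write_cohort


@pytest.fixture(scope="session")
def paper_cohort():
    """The curated 12-gene venom-family cohort (fixed seed)."""
    return paper_style_cohort(seed=11)


@pytest.fixture(scope="session")
def paper_cohort_dir(paper_cohort, tmp_path_factory):
    """The same cohort written to FASTA/GFF3/TSV/JSON files."""
    outdir = tmp_path_factory.mktemp("paper_cohort")
    paths = write_cohort(paper_cohort, outdir)
    return paths


@pytest.fixture(scope="session")
def mixed_cohort():
    """60 random genes, both strands, some UTR introns, short introns."""
    return generate_cohort(
        60, signature_prob=0.6, seed=202, utr5_intron_prob=0.3,
        intron_len_range=(60, 300),
    )
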