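import pytest

from tftarget import FixtureSpec, PlantedSpec, build_fixture, generate
from tftarget.annotations import TranscriptRecord


def make_transcript(
    transcript_id="TX1",
    gene_id="G1",
    chrom="chr1",
    start=10_000,
    end=15_000,
    strand="+",
    transcript_name="",
    gene_name="",
    biotype="lincRNA",
):
    return TranscriptRecord(
        transcript_id=transcript_id,
        transcript_name=transcript_name,
        gene_id=gene_id,
        gene_name=gene_name,
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        biotype=biotype,
    )


@pytest.fixture(scope="session")
def planted_fixture():
    """Small genome with three null datasets and one strongly planted dataset."""
    spec = FixtureSpec(
        seed=11,
        n_genes=100,
        transcripts_per_gene=(1, 2),
        chrom_sizes={"chr1": 5_000_000},
        n_null_datasets=3,
        peaks_per_dataset=600,
        planted=PlantedSpec(foreground_size=20, hit_fraction_foreground=0.9,
                            hit_fraction_background=0.05),
    )
    return build_fixture(spec)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The same planted fixture written out as GTF / narrowPeak / manifest files."""
    out = tmp_path_factory.mktemp("fixture")
    spec = FixtureSpec(
        seed=11,
        n_genes=100,
        transcripts_per_gene=(1, 2),
        chrom_sizes={"chr1": 5_000_000},
        n_null_datasets=3,
        peaks_per_dataset=600,
        planted=PlantedSpec(foreground_size=20, hit_fraction_foreground=0.9,
                            hit_fraction_background=0.05),
    )
    paths = generate(spec, out)
    return paths
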