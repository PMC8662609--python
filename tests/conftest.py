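import dataclasses

import pysam
import pytest

from hotspotsym import assign, peaks, synthdata, variants


@pytest.fixture(scope="session")
def small_config() -> synthdata.SimConfig:
    """A 300 kb hybrid chromosome with realistic SNP density, 20 hotspots."""
    return synthdata.SimConfig(
        chrom_length=300_000,
        n_snps=3_000,
        n_decoy_snps=40,
        n_hotspots_per_allele=10,
        erosion_prob=0.5,
        read_depth=40.0,
        background_per_kb=0.5,
        min_hotspot_spacing=5_000,
        seq_error_rate=0.01,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("smallsim")
    return synthdata.simulate_dataset(small_config, out)


@pytest.fixture(scope="session")
def small_sites(small_dataset):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sites = variants.load_informative_snps(small_dataset["paths"]["vcf"])
    return variants.SiteIndex(sites)


@pytest.fixture(scope="session")
def small_assignments(small_dataset, small_sites):
    table, summary = assign.assign_all(small_dataset["paths"]["sam"], small_sites)
    return table, summary


@pytest.fixture(scope="session")
def small_peaks(small_dataset):
    return peaks.call_peaks(small_dataset["paths"]["sam"], peaks.PeakParams())


def make_read(
    chrom_header: pysam.AlignmentHeader,
    name: str,
    start: int,
    sequence: str,
    reverse: bool = False,
    quality: int = 40,
) -> pysam.AlignedSegment:
    """Construct a simple fully-aligned single-end read."""
    a = pysam.AlignedSegment(chrom_header)
    a.query_name = name
    a.query_sequence = sequence
    a.flag = 16 if reverse else 0
    a.reference_id = 0
    a.reference_start = start
    a.mapping_quality = 60
    a.cigartuples = [(0, len(sequence))]
    a.query_qualities = pysam.qualitystring_to_array(chr(quality + 33) * len(sequence))
    return a


@pytest.fixture()
def sam_header():
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": "chrT", "LN": 100_000}]}
    )


def replace(cfg: synthdata.SimConfig, **kw) -> synthdata.SimConfig:
    return dataclasses.replace(cfg, **kw)
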