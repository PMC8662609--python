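"""Generator contracts: determinism, counts, erosion law, read conservation."""

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pysam
import pytest

from hotspotsym import synthdata
from hotspotsym.synthdata import (
    ALLELE1,
    HOM_B6,
    InvalidConfigError,
    SimConfig,
    TruthHotspot,
    generate_haplotypes,
    generate_hotspots,
    simulate_reads,
)


def test_vcf_has_exactly_requested_snp_records(tmp_path):
    cfg = SimConfig(chrom_length=100_000, n_snps=100, n_decoy_snps=0, seed=3)
    haps = generate_haplotypes(cfg)
    vcf_path = tmp_path / "v.vcf"
    synthdata.write_vcf(haps, vcf_path)
    with pysam.VariantFile(str(vcf_path)) as vcf:
        recs = list(vcf)
    assert len(recs) == 100
    positions = [r.start for r in recs]
    assert len(set(positions)) == 100
    for r in recs:
        assert len(r.ref) == 1 and len(r.alts) == 1 and len(r.alts[0]) == 1
        assert r.ref != r.alts[0]


def test_no_snps_means_identical_haplotypes():
    cfg = SimConfig(chrom_length=10_000, n_snps=0, n_hotspots_per_allele=0, seed=1)
    haps = generate_haplotypes(cfg)
    assert np.array_equal(haps.alt_sequence, haps.reference)


def test_too_many_snps_rejected():
    cfg = SimConfig(chrom_length=100, n_snps=200)
    with pytest.raises(InvalidConfigError):
        generate_haplotypes(cfg)


def test_same_seed_gives_byte_identical_outputs(tmp_path):
    cfg = SimConfig(chrom_length=50_000, n_snps=500, n_decoy_snps=10,
                    n_hotspots_per_allele=4, read_depth=10.0, seed=42)
    outs = []
    for sub in ("a", "b"):
        result = synthdata.simulate_dataset(cfg, tmp_path / sub)
        outs.append({k: Path(p).read_bytes() for k, p in result["paths"].items()})
    assert outs[0] == outs[1]


def test_hotspot_centers_unique_and_spaced(small_dataset, small_config):
    hs = small_dataset["hotspots"]
    centers = sorted(h.center for h in hs)
    assert len(set(centers)) == len(centers)
    gaps = np.diff(centers)
    assert gaps.min() >= small_config.min_hotspot_spacing


def test_erosion_prob_zero_and_one():
    cfg = SimConfig(chrom_length=200_000, n_hotspots_per_allele=10, erosion_prob=0.0, seed=5)
    assert all(h.eroded_on == "none" for h in generate_hotspots(cfg))
    cfg2 = dataclasses.replace(cfg, erosion_prob=1.0, erosion_factor=0.0)
    for h in generate_hotspots(cfg2):
        if h.allele == ALLELE1:
            assert h.eroded_on == HOM_B6 and h.heat_homB6 == 0.0


def test_eroded_fraction_matches_binomial_law():
    cfg = SimConfig(chrom_length=2_000_000, n_snps=0, n_hotspots_per_allele=500,
                    erosion_prob=0.8, min_hotspot_spacing=100, seed=9)
    hs = generate_hotspots(cfg)
    frac = np.mean([h.eroded_on != "none" for h in hs])
    sd = np.sqrt(0.8 * 0.2 / len(hs))
    assert abs(frac - 0.8) < 3 * sd


def test_eroded_count_monotone_in_erosion_prob():
    counts = []
    for p in (0.0, 0.2, 0.5, 0.8, 1.0):
        cfg = SimConfig(chrom_length=500_000, n_hotspots_per_allele=50,
                        erosion_prob=p, min_hotspot_spacing=1000, seed=13)
        counts.append(sum(h.eroded_on != "none" for h in generate_hotspots(cfg)))
    assert counts == sorted(counts)


def test_every_read_appears_exactly_once_in_truth(small_dataset):
    reads = small_dataset["reads"]
    truth = small_dataset["truth"]
    assert len(reads) == len(truth)
    assert reads["read_id"].is_unique
    assert set(reads["read_id"]) == set(truth["read_id"])
    with pysam.AlignmentFile(small_dataset["paths"]["sam"]) as af:
        sam_ids = [r.query_name for r in af]
    assert sorted(sam_ids) == sorted(truth["read_id"])


def test_zero_heat_zero_background_warns_and_emits_nothing():
    cfg = SimConfig(chrom_length=20_000, n_snps=10, read_depth=0.0,
                    background_per_kb=0.0, n_hotspots_per_allele=1,
                    min_hotspot_spacing=1000, seed=2)
    haps = generate_haplotypes(cfg)
    hs = generate_hotspots(cfg)
    with pytest.warns(UserWarning):
        reads, truth = simulate_reads(hs, haps, cfg)
    assert len(reads) == 0 and len(truth) == 0


def test_error_free_reads_match_their_homolog_at_snps():
    cfg = SimConfig(chrom_length=30_000, n_snps=300, seq_error_rate=0.0,
                    n_hotspots_per_allele=1, min_hotspot_spacing=1_000,
                    background_per_kb=0.0, seed=21)
    haps = generate_haplotypes(cfg)
    hs = [TruthHotspot("hs0", cfg.chrom_name, 15_000, ALLELE1,
                       heat_homB6=5.0, heat_homALT=0.0, eroded_on="none")]
    reads, truth = simulate_reads(hs, haps, cfg)
    assert (truth["true_homolog"] == HOM_B6).all()
    ref = "".join(haps.reference)
    for r in reads.itertuples():
        assert r.sequence == ref[r.start : r.end]


def test_balanced_heats_give_half_b6_reads():
    cfg = SimConfig(chrom_length=100_000, n_snps=0, n_hotspots_per_allele=1,
                    background_per_kb=0.0, read_depth=1000.0, seed=17)
    haps = generate_haplotypes(cfg)
    hs = [TruthHotspot("hs0", cfg.chrom_name, 50_000, ALLELE1, 5.0, 5.0, "none")]
    _, truth = simulate_reads(hs, haps, cfg)
    n = len(truth)
    assert n > 5_000
    frac = (truth["true_homolog"] == HOM_B6).mean()
    assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)


def test_truth_matched_proportion_weightings():
    import pandas as pd

    hs = [
        TruthHotspot("h1", "chrSim", 1000, ALLELE1, 1.0, 1.0, "none"),  # matched
        TruthHotspot("h2", "chrSim", 5000, ALLELE1, 0.95, 0.05, HOM_B6),  # eroded
    ]
    # h1: 4 reads, 2 overlap the SNP at 1010; h2: 6 reads, 3 overlap 5010
    rows = []
    for i, (src, start, n, n_inf) in enumerate([("h1", 990, 4, 2), ("h2", 4990, 6, 3)]):
        for j in range(n):
            s = start if j < n_inf else start + 200
            rows.append(("r%d_%d" % (i, j), "chrSim", s, s + 50, "+", HOM_B6, src))
    truth = pd.DataFrame(rows, columns=synthdata.TRUTH_COLUMNS)
    out = synthdata.truth_matched_proportion(
        hs, truth, ALLELE1, snp_positions=np.array([1010, 5010])
    )
    assert out["read_weighted"] == pytest.approx(4 / 10)
    assert out["informative_read_weighted"] == pytest.approx(2 / 5)
    assert out["peak_weighted"] == pytest.approx(1 / 2)


class TestPhenotypes:
    def test_full_synapsis(self):
        g = [synthdata.GroupParams("g", n_mice=5, p_synapsis=1.0)]
        df = synthdata.simulate_phenotypes(g, seed=1)
        assert (df["nuclei_synapsed"] == df["nuclei_total"]).all()

    def test_below_threshold_groups_draw_near_zero_sperm(self):
        g = [synthdata.GroupParams("low", n_mice=20, p_synapsis=0.2)]
        laws = synthdata.PhenotypeLaws(tau=0.5, sperm_low_mean=1.0)
        df = synthdata.simulate_phenotypes(g, seed=2, laws=laws)
        assert (df["sperm_count"] < 20).all()

    def test_mean_synapsis_tracks_group_probability(self):
        g = [synthdata.GroupParams("hi", n_mice=10, p_synapsis=0.9, nuclei_total=60)]
        df = synthdata.simulate_phenotypes(g, seed=3)
        mean_frac = (df["nuclei_synapsed"] / df["nuclei_total"]).mean()
        sd = np.sqrt(0.9 * 0.1 / 60 / 10)
        assert abs(mean_frac - 0.9) < 3 * sd

    def test_invalid_probability_rejected(self):
        g = [synthdata.GroupParams("bad", n_mice=2, p_synapsis=1.5)]
        with pytest.raises(InvalidConfigError):
            synthdata.simulate_phenotypes(g, seed=1)
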