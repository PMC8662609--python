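"""Synthetic hybrid-mouse dataset generator with known ground truth.

The generator encodes the erosion model of hybrid sterility as a static
generative assumption: each PRDM9 allele activates its own set of hotspots
with heavy-tailed (log-normal) intensities; a hotspot may be *eroded* on the
homolog carrying that allele's own genetic background, in which case its
intensity there is multiplied by a small erosion factor. In an F1 hybrid
this produces homolog-asymmetric read pileups at eroded hotspots and
symmetric pileups at intact ("matched") ones. A de novo allele is emulated
by setting its erosion probability near zero.

Reads are emitted pre-aligned (SSDS-like strand-offset geometry or
symmetric H3K4me3-like geometry) together with a truth table recording each
read's homolog of origin, so every downstream stage can be scored exactly.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

BASES = np.array(["A", "C", "G", "T"])

#: Labels for the two homologous chromosomes of the F1 hybrid.
HOM_B6 = "B6"
HOM_ALT = "ALT"

#: Labels for the two PRDM9 alleles segregating in the hybrid.
ALLELE1 = "allele1"
ALLELE2 = "allele2"

TRUTH_COLUMNS = ["read_id", "chrom", "start", "end", "strand", "true_homolog", "source"]


class InvalidConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimConfig:
    """Parameters of the synthetic hybrid dataset.

    Intensities ("heats") are in arbitrary units; ``read_depth`` converts
    heat to an expected read count per homolog. ``erosion_prob`` applies to
    allele-1 hotspots (eroded on the B6 homolog, the allele's own
    background); ``erosion_prob_allele2`` applies to allele-2 hotspots
    (eroded on the ALT homolog) and defaults to ``erosion_prob`` when None.
    Setting an allele's erosion probability near 0 emulates a de novo
    (unereroded) allele.
    """

    chrom_name: str = "chrSim"
    chrom_length: int = 1_000_000
    n_snps: int = 10_000
    n_decoy_snps: int = 0
    n_hotspots_per_allele: int = 25
    erosion_prob: float = 0.5
    erosion_prob_allele2: float | None = None
    erosion_factor: float = 0.05
    # log-normal per-hotspot heat law: (mean, sd) of log heat
    heat_log_mean: float = 0.0
    heat_log_sd: float = 1.0
    # multiplicative log-normal jitter between the two homologs of a
    # non-eroded hotspot (binding is similar, not identical, on the two)
    homolog_jitter_sd: float = 0.2
    read_depth: float = 30.0
    background_per_kb: float = 0.2
    read_length: int = 50
    frag_offset_mean: float = 150.0
    frag_offset_sd: float = 50.0
    seq_error_rate: float = 0.01
    min_hotspot_spacing: int = 2_000
    assay_type: str = "ssds"
    seed: int = 0

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        errors: list[str] = []
        if self.chrom_length <= 0:
            errors.append("chrom_length must be positive")
        if self.n_snps < 0 or self.n_decoy_snps < 0:
            errors.append("SNP counts must be nonnegative")
        if self.n_snps + self.n_decoy_snps > self.chrom_length:
            errors.append("more SNPs requested than chromosome positions")
        if self.n_hotspots_per_allele < 0:
            errors.append("n_hotspots_per_allele must be nonnegative")
        for name in ("erosion_prob", "seq_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errors.append(f"{name} must be in [0, 1]")
        if self.erosion_prob_allele2 is not None and not 0.0 <= self.erosion_prob_allele2 <= 1.0:
            errors.append("erosion_prob_allele2 must be in [0, 1]")
        if self.erosion_factor < 0:
            errors.append("erosion_factor must be nonnegative")
        if self.read_depth < 0 or self.background_per_kb < 0:
            errors.append("depths must be nonnegative")
        if self.read_length <= 0 or self.read_length > self.chrom_length:
            errors.append("read_length must be in (0, chrom_length]")
        if self.assay_type not in ("ssds", "h3k4me3"):
            errors.append("assay_type must be 'ssds' or 'h3k4me3'")
        if 2 * self.min_hotspot_spacing * self.n_hotspots_per_allele > self.chrom_length and self.n_hotspots_per_allele > 0:
            errors.append("chromosome too short for requested hotspot count and spacing")
        return errors

    def require_valid(self) -> None:
        errors = self.validate()
        if errors:
            raise InvalidConfigError("; ".join(errors))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class TruthHotspot:
    """A simulated hotspot with its per-homolog binding intensities."""

    id: str
    chrom: str
    center: int  # 0-based
    allele: str  # ALLELE1 or ALLELE2
    heat_homB6: float
    heat_homALT: float
    eroded_on: str  # "none", HOM_B6 or HOM_ALT

    @property
    def total_heat(self) -> float:
        return self.heat_homB6 + self.heat_homALT

    @property
    def true_b6_fraction(self) -> float:
        return self.heat_homB6 / self.total_heat


@dataclass
class Haplotypes:
    """Reference (B6) sequence plus the SNPs defining the ALT haplotype."""

    chrom: str
    reference: np.ndarray  # array of single-character bases
    snp_pos: np.ndarray  # 0-based positions of true haplotype-defining SNPs
    snp_ref: np.ndarray
    snp_alt: np.ndarray
    # decoy VCF records that do NOT define the haplotype (het or non-PASS)
    decoys: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["pos", "ref", "alt", "filter", "gt"])
    )

    @property
    def alt_sequence(self) -> np.ndarray:
        seq = self.reference.copy()
        seq[self.snp_pos] = self.snp_alt
        return seq

    def homolog_sequence(self, homolog: str) -> np.ndarray:
        return self.reference if homolog == HOM_B6 else self.alt_sequence


def _rng_for(config: SimConfig, stage: str) -> np.random.Generator:
    # one master seed deterministically spawns per-stage streams
    stage_key = {"haplotypes": 0, "hotspots": 1, "reads": 2, "phenotypes": 3}[stage]
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(stage_key,)))


# ---------------------------------------------------------------------------
# haplotypes


def generate_haplotypes(config: SimConfig) -> Haplotypes:
    """Draw a random reference sequence and the SNPs defining the ALT haplotype.

    True haplotype-defining SNPs are biallelic substitutions at distinct
    positions, written as PASS / homozygous-alt VCF records. Decoy records
    (heterozygous or non-PASS, controlled by ``n_decoy_snps``) are written to
    the VCF but are *not* applied to the ALT haplotype, exercising the
    downstream variant filter.
    """
    config.require_valid()
    rng = _rng_for(config, "haplotypes")
    ref = rng.choice(BASES, size=config.chrom_length)

    n_total = config.n_snps + config.n_decoy_snps
    pos = np.sort(rng.choice(config.chrom_length, size=n_total, replace=False))
    which_true = np.sort(rng.choice(n_total, size=config.n_snps, replace=False))
    is_true = np.zeros(n_total, dtype=bool)
    is_true[which_true] = True

    # alt base: uniform among the three non-reference bases
    ref_idx = np.searchsorted(BASES, ref[pos])
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_total)) % 4
    alt = BASES[alt_idx]

    snp_pos = pos[is_true]
    decoy_pos = pos[~is_true]
    decoy_alt = alt[~is_true]
    # decoys alternate between non-PASS homozygous and PASS heterozygous
    n_dec = len(decoy_pos)
    dec_filter = np.where(np.arange(n_dec) % 2 == 0, "LowQual", "PASS")
    dec_gt = np.where(np.arange(n_dec) % 2 == 0, "1/1", "0/1")
    decoys = pd.DataFrame(
        {
            "pos": decoy_pos,
            "ref": ref[decoy_pos],
            "alt": decoy_alt,
            "filter": dec_filter,
            "gt": dec_gt,
        }
    )
    return Haplotypes(
        chrom=config.chrom_name,
        reference=ref,
        snp_pos=snp_pos,
        snp_ref=ref[snp_pos],
        snp_alt=alt[is_true],
        decoys=decoys,
    )


def write_fasta(haps: Haplotypes, path: str | Path, line_width: int = 60) -> None:
    seq = "".join(haps.reference)
    with open(path, "w") as fh:
        fh.write(f">{haps.chrom}\n")
        for i in range(0, len(seq), line_width):
            fh.write(seq[i : i + line_width] + "\n")


def write_vcf(haps: Haplotypes, path: str | Path, sample: str = "ALT_STRAIN") -> None:
    """Write the haplotype-defining SNPs (PASS, GT 1/1) plus any decoys."""
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={haps.chrom},length={len(haps.reference)}>")
    header.add_line('##FILTER=<ID=LowQual,Description="Low quality call">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_sample(sample)

    records = []
    for p, r, a in zip(haps.snp_pos, haps.snp_ref, haps.snp_alt):
        records.append((int(p), str(r), str(a), "PASS", (1, 1)))
    for row in haps.decoys.itertuples():
        gt = (1, 1) if row.gt == "1/1" else (0, 1)
        records.append((int(row.pos), str(row.ref), str(row.alt), str(row.filter), gt))
    records.sort(key=lambda t: t[0])

    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for pos0, ref, alt, filt, gt in records:
            rec = vcf.new_record(contig=haps.chrom, start=pos0, alleles=(ref, alt))
            rec.filter.add(filt)
            rec.samples[0]["GT"] = gt
            vcf.write(rec)


# ---------------------------------------------------------------------------
# hotspots


def generate_hotspots(config: SimConfig) -> list[TruthHotspot]:
    """Draw hotspot positions, heats and erosion states for both alleles.

    Heats follow a log-normal law (a spectrum of binding affinities from
    strong to weak). With the allele's erosion probability, a hotspot is
    eroded on the homolog carrying that allele's own background (B6 for
    allele 1, ALT for allele 2), multiplying its heat there by
    ``erosion_factor``. Centers keep a minimum pairwise spacing so hotspots
    do not overlap.
    """
    config.require_valid()
    rng = _rng_for(config, "hotspots")
    n_per = config.n_hotspots_per_allele
    n_total = 2 * n_per
    if n_total == 0:
        return []

    centers = _spaced_positions(rng, config.chrom_length, n_total, config.min_hotspot_spacing)
    # interleave alleles along the chromosome deterministically
    alleles = np.array([ALLELE1, ALLELE2] * n_per)
    rng.shuffle(alleles)

    p1 = config.erosion_prob
    p2 = config.erosion_prob if config.erosion_prob_allele2 is None else config.erosion_prob_allele2

    hotspots: list[TruthHotspot] = []
    for i, (center, allele) in enumerate(zip(centers, alleles)):
        base_heat = float(rng.lognormal(config.heat_log_mean, config.heat_log_sd))
        jitter = rng.normal(0.0, config.homolog_jitter_sd, size=2)
        heat_b6 = base_heat * float(np.exp(jitter[0]))
        heat_alt = base_heat * float(np.exp(jitter[1]))
        p_erode = p1 if allele == ALLELE1 else p2
        eroded_on = "none"
        if rng.random() < p_erode:
            if allele == ALLELE1:
                eroded_on = HOM_B6
                heat_b6 *= config.erosion_factor
            else:
                eroded_on = HOM_ALT
                heat_alt *= config.erosion_factor
        hotspots.append(
            TruthHotspot(
                id=f"hs{i:04d}",
                chrom=config.chrom_name,
                center=int(center),
                allele=str(allele),
                heat_homB6=heat_b6,
                heat_homALT=heat_alt,
                eroded_on=eroded_on,
            )
        )
    return hotspots


def _spaced_positions(
    rng: np.random.Generator, length: int, n: int, min_spacing: int
) -> np.ndarray:
    """Draw n sorted positions with pairwise gaps ≥ min_spacing."""
    margin = min_spacing  # keep clear of chromosome ends
    free = length - 2 * margin - (n - 1) * min_spacing
    if free <= 0:
        raise InvalidConfigError("chromosome too short for requested hotspot spacing")
    raw = np.sort(rng.choice(free, size=n, replace=False))
    return margin + raw + min_spacing * np.arange(n)


def hotspots_to_frame(hotspots: Sequence[TruthHotspot]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(h) for h in hotspots])


def write_hotspot_bed(hotspots: Sequence[TruthHotspot], path: str | Path, halfwidth: int = 500) -> None:
    """Write truth hotspots as BED6+ (name=id, score=total heat, extra cols)."""
    with open(path, "w") as fh:
        for h in sorted(hotspots, key=lambda h: (h.chrom, h.center)):
            start = max(0, h.center - halfwidth)
            fh.write(
                f"{h.chrom}\t{start}\t{h.center + halfwidth}\t{h.id}\t"
                f"{h.total_heat:.4f}\t+\t{h.center}\t{h.allele}\t{h.eroded_on}\n"
            )


# ---------------------------------------------------------------------------
# reads


def simulate_reads(
    hotspots: Sequence[TruthHotspot],
    haps: Haplotypes,
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate aligned single-end reads from hotspots plus uniform background.

    Per hotspot and homolog the read count is Poisson(read_depth × heat).
    For the SSDS assay, plus-strand reads center at ``center − offset`` and
    minus-strand reads at ``center + offset`` with offset ~
    Normal(frag_offset_mean, frag_offset_sd), reproducing the strand
    asymmetry of resected DSB ends; for H3K4me3 the placement is symmetric
    on both strands. Sequences are copied from the homolog of origin with
    per-base substitution error ``seq_error_rate``.

    Returns ``(reads, truth)`` where ``reads`` has columns
    (read_id, chrom, start, end, strand, sequence) and ``truth`` additionally
    records the homolog of origin and source hotspot (or "background").
    """
    config.require_valid()
    rng = _rng_for(config, "reads")
    L = config.read_length
    chrom_len = len(haps.reference)

    mids: list[np.ndarray] = []
    strands: list[np.ndarray] = []
    homs: list[np.ndarray] = []
    sources: list[np.ndarray] = []

    for h in hotspots:
        for hom, heat in ((HOM_B6, h.heat_homB6), (HOM_ALT, h.heat_homALT)):
            n = int(rng.poisson(config.read_depth * heat))
            if n == 0:
                continue
            strand = np.where(rng.random(n) < 0.5, "+", "-")
            offset = rng.normal(config.frag_offset_mean, config.frag_offset_sd, size=n)
            if config.assay_type == "ssds":
                mid = np.where(strand == "+", h.center - offset, h.center + offset)
            else:
                mid = h.center + rng.normal(0.0, config.frag_offset_sd, size=n)
            mids.append(mid)
            strands.append(strand)
            homs.append(np.full(n, hom))
            sources.append(np.full(n, h.id))

    n_bg = int(rng.poisson(config.background_per_kb * chrom_len / 1000.0))
    if n_bg > 0:
        mids.append(rng.uniform(0, chrom_len, size=n_bg))
        strands.append(np.where(rng.random(n_bg) < 0.5, "+", "-"))
        homs.append(np.where(rng.random(n_bg) < 0.5, HOM_B6, HOM_ALT))
        sources.append(np.full(n_bg, "background"))

    if not mids:
        warnings.warn("zero total heat and zero background: no reads simulated")
        empty = pd.DataFrame(columns=["read_id", "chrom", "start", "end", "strand", "sequence"])
        truth = pd.DataFrame(columns=TRUTH_COLUMNS)
        return empty, truth

    mid = np.concatenate(mids)
    strand = np.concatenate(strands)
    hom = np.concatenate(homs)
    source = np.concatenate(sources)

    start = np.clip(np.round(mid - L / 2).astype(np.int64), 0, chrom_len - L)
    order = np.argsort(start, kind="stable")
    start, strand, hom, source = start[order], strand[order], hom[order], source[order]

    seq_b6 = haps.reference
    seq_alt = haps.alt_sequence
    sequences = []
    for s, hm in zip(start, hom):
        src = seq_b6 if hm == HOM_B6 else seq_alt
        frag = src[s : s + L].copy()
        err = rng.random(L) < config.seq_error_rate
        if err.any():
            # substitution error: uniform among the three other bases
            idx = np.searchsorted(BASES, frag[err])
            frag[err] = BASES[(idx + rng.integers(1, 4, size=int(err.sum()))) % 4]
        sequences.append("".join(frag))

    read_ids = np.array([f"r{i:07d}" for i in range(len(start))])
    reads = pd.DataFrame(
        {
            "read_id": read_ids,
            "chrom": config.chrom_name,
            "start": start,
            "end": start + L,
            "strand": strand,
            "sequence": sequences,
        }
    )
    truth = reads[["read_id", "chrom", "start", "end", "strand"]].copy()
    truth["true_homolog"] = hom
    truth["source"] = source
    return reads, truth[TRUTH_COLUMNS]


def write_sam(reads: pd.DataFrame, chrom: str, chrom_length: int, path: str | Path) -> None:
    """Write simulated reads as a coordinate-sorted SAM file (MAPQ 60, Q40 bases)."""
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": chrom, "LN": int(chrom_length)}],
        }
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for row in reads.itertuples():
            a = pysam.AlignedSegment(header)
            a.query_name = row.read_id
            a.query_sequence = row.sequence
            a.flag = 16 if row.strand == "-" else 0
            a.reference_id = 0
            a.reference_start = int(row.start)
            a.mapping_quality = 60
            a.cigartuples = [(0, len(row.sequence))]
            a.query_qualities = pysam.qualitystring_to_array("I" * len(row.sequence))
            out.write(a)


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# phenotypes


@dataclass
class GroupParams:
    """Generative parameters for one genotype group of mice."""

    name: str
    n_mice: int
    p_synapsis: float
    nuclei_total: int = 100
    testis_mg_mean: float = 90.0
    testis_mg_sd: float = 10.0
    lean_g_mean: float = 22.0
    lean_g_sd: float = 2.0


@dataclass
class PhenotypeLaws:
    """Cohort-level laws: synapsis threshold and sperm-count distributions."""

    tau: float = 0.5
    sperm_low_mean: float = 1.0  # near-zero Poisson law below threshold
    sperm_high_log10_mean: float = 6.0  # log-normal law above threshold
    sperm_high_log10_sd: float = 0.2


def default_phenotype_groups() -> list[GroupParams]:
    """A 24-mouse cohort spanning both sides of the synapsis threshold.

    Six genotype groups of four mice whose true synapsis probabilities
    straddle the 50% cliff-edge, emulating the spread observed across
    wild-type and engineered hybrids (near-sterile hybrids with low synapsis,
    de-novo-allele hybrids and parental strains with high synapsis).
    """
    spec = [
        ("hybrid_wt", 0.20, 35.0),
        ("hybrid_low", 0.30, 40.0),
        ("hybrid_mid", 0.40, 45.0),
        ("hybrid_denovo", 0.60, 70.0),
        ("hybrid_high", 0.70, 85.0),
        ("parental", 0.80, 95.0),
    ]
    return [
        GroupParams(name=name, n_mice=4, p_synapsis=p, testis_mg_mean=tw)
        for name, p, tw in spec
    ]


def simulate_phenotypes(
    group_params: Sequence[GroupParams],
    seed: int,
    laws: PhenotypeLaws | None = None,
) -> pd.DataFrame:
    """Simulate one phenotype record per mouse.

    Synapsed nuclei are Binomial(nuclei_total, p_synapsis). The sperm count
    follows a near-zero Poisson law when the group's true synapsis
    probability is below the threshold tau, and a high log-normal law
    otherwise — the cliff-edge generative assumption.
    """
    laws = laws or PhenotypeLaws()
    if not 0.0 <= laws.tau <= 1.0:
        raise InvalidConfigError("tau must be in [0, 1]")
    for g in group_params:
        if not 0.0 <= g.p_synapsis <= 1.0:
            raise InvalidConfigError(f"p_synapsis out of [0, 1] for group {g.name}")
        if g.nuclei_total < 50:
            raise InvalidConfigError(f"nuclei_total must be ≥ 50 (group {g.name})")
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for g in group_params:
        for _ in range(g.n_mice):
            synapsed = int(rng.binomial(g.nuclei_total, g.p_synapsis))
            if g.p_synapsis < laws.tau:
                sperm = int(rng.poisson(laws.sperm_low_mean))
            else:
                sperm = int(
                    np.round(10 ** rng.normal(laws.sperm_high_log10_mean, laws.sperm_high_log10_sd))
                )
            rows.append(
                {
                    "mouse_id": f"m{i:03d}",
                    "group": g.name,
                    "nuclei_total": g.nuclei_total,
                    "nuclei_synapsed": synapsed,
                    "testis_weight_mg": float(np.round(rng.normal(g.testis_mg_mean, g.testis_mg_sd), 2)),
                    "lean_body_weight_g": float(np.round(abs(rng.normal(g.lean_g_mean, g.lean_g_sd)), 2)),
                    "sperm_count": sperm,
                }
            )
            i += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# named study-condition configurations


def expected_matched_read_proportion(erosion_prob: float, erosion_factor: float) -> float:
    """Nominal read-weighted matched proportion implied by the erosion model.

    A non-eroded hotspot contributes read mass ∝ 2h (both homologs); an
    eroded one contributes ∝ h(1 + c) with c the erosion factor. With
    erosion probability p and erosion independent of heat, the expected
    matched share of reads is 2(1 − p) / (2(1 − p) + p(1 + c)).
    """
    p, c = erosion_prob, erosion_factor
    return 2 * (1 - p) / (2 * (1 - p) + p * (1 + c))


def _regime_base(seed: int) -> SimConfig:
    return SimConfig(
        chrom_length=2_000_000,
        n_snps=20_000,  # ~1 SNP / 100 bp, as between distant mouse (sub)species
        n_hotspots_per_allele=40,
        read_depth=100.0,
        background_per_kb=0.5,
        heat_log_sd=0.5,
        min_hotspot_spacing=5_000,
        seed=seed,
    )


def eroded_regime_config(seed: int = 0) -> SimConfig:
    """Wild-type-like hybrid: heavy erosion on both alleles.

    erosion_prob = 0.915 solves expected_matched_read_proportion(p, 0.05)
    = 0.15, the regime where only a small minority of DSB signal comes from
    hotspots cut on both homologs.
    """
    cfg = _regime_base(seed)
    cfg.erosion_prob = 0.915
    cfg.erosion_prob_allele2 = 0.915
    return cfg


def denovo_regime_config(seed: int = 0) -> SimConfig:
    """Engineered hybrid: allele 1 is a de novo allele with only residual
    binding asymmetry, its partner allele stays heavily eroded.

    erosion_prob = 0.559 for the focal allele solves
    expected_matched_read_proportion(p, 0.05) = 0.60, mirroring the
    partial (not total) restoration of matched binding seen for engineered
    alleles rather than an idealized fully-symmetric 1.0.
    """
    cfg = _regime_base(seed)
    cfg.erosion_prob = 0.559
    cfg.erosion_prob_allele2 = 0.915
    return cfg


# ---------------------------------------------------------------------------
# truth-side evaluation helpers


def truth_b6_fraction(h: TruthHotspot) -> float:
    return h.true_b6_fraction


def truth_matched_proportion(
    hotspots: Sequence[TruthHotspot],
    truth: pd.DataFrame,
    allele: str,
    band: tuple[float, float] = (0.25, 0.75),
    snp_positions: np.ndarray | None = None,
) -> dict:
    """Realized matched-read proportion for one allele, from the truth table.

    A hotspot is *matched* when its true B6 heat fraction lies within the
    band. ``read_weighted`` uses all realized reads per hotspot;
    ``informative_read_weighted`` (when ``snp_positions`` is given) weights
    by reads overlapping at least one SNP — the subpopulation a
    homolog-assignment pipeline can actually measure, which matters because
    local SNP density varies strongly between hotspots. The peak weighting
    counts hotspots once each.
    """
    hs = truth[truth["source"] != "background"]
    counts = hs["source"].value_counts()
    if snp_positions is not None and len(hs):
        pos = np.sort(np.asarray(snp_positions))
        starts = hs["start"].to_numpy()
        ends = hs["end"].to_numpy()
        has_snp = np.searchsorted(pos, ends, side="left") > np.searchsorted(pos, starts, side="left")
        inf_counts = hs.loc[has_snp, "source"].value_counts()
    else:
        inf_counts = None
    lo, hi = band
    reads_matched = reads_total = peaks_matched = peaks_total = 0
    inf_matched = inf_total = 0
    for h in hotspots:
        if h.allele != allele:
            continue
        n = int(counts.get(h.id, 0))
        n_inf = int(inf_counts.get(h.id, 0)) if inf_counts is not None else 0
        matched = lo <= h.true_b6_fraction <= hi
        reads_total += n
        inf_total += n_inf
        peaks_total += 1
        if matched:
            reads_matched += n
            inf_matched += n_inf
            peaks_matched += 1
    out = {
        "read_weighted": reads_matched / reads_total if reads_total else float("nan"),
        "peak_weighted": peaks_matched / peaks_total if peaks_total else float("nan"),
        "n_reads": reads_total,
        "n_hotspots": peaks_total,
    }
    if inf_counts is not None:
        out["informative_read_weighted"] = inf_matched / inf_total if inf_total else float("nan")
        out["n_informative_capable_reads"] = inf_total
    return out


def simulate_dataset(config: SimConfig, out_dir: str | Path) -> dict:
    """Run genome → hotspots → reads and write all artifacts to ``out_dir``.

    Returns a dict of the in-memory objects and the file paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    haps = generate_haplotypes(config)
    hotspots = generate_hotspots(config)
    reads, truth = simulate_reads(hotspots, haps, config)

    paths = {
        "fasta": out / "genome.fa",
        "vcf": out / "variants.vcf",
        "sam": out / "reads.sam",
        "truth": out / "truth_reads.tsv",
        "hotspot_bed": out / "truth_hotspots.bed",
        "hotspot_tsv": out / "truth_hotspots.tsv",
    }
    write_fasta(haps, paths["fasta"])
    write_vcf(haps, paths["vcf"])
    write_sam(reads, config.chrom_name, config.chrom_length, paths["sam"])
    write_truth(truth, paths["truth"])
    write_hotspot_bed(hotspots, paths["hotspot_bed"])
    hotspots_to_frame(hotspots).to_csv(paths["hotspot_tsv"], sep="\t", index=False)
    return {
        "haplotypes": haps,
        "hotspots": hotspots,
        "reads": reads,
        "truth": truth,
        "paths": {k: str(v) for k, v in paths.items()},
    }
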