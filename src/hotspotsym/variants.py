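"""Strain-distinguishing SNP filtering.

Homolog assignment in an F1 hybrid relies on sites where the two parental
haplotypes are guaranteed to differ: biallelic SNPs that passed all variant
filters and are homozygous for the alternative allele in the non-reference
strain. Heterozygous calls, non-PASS records, indels and multiallelic sites
are excluded — a heterozygous or third allele cannot be attributed to either
homolog.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

logger = logging.getLogger(__name__)


class VcfParseError(ValueError):
    pass


@dataclass(frozen=True)
class VariantSite:
    """One candidate strain-distinguishing SNP (positions 0-based internally)."""

    chrom: str
    pos: int  # 0-based
    ref_base: str
    alt_base: str
    passed_filters: bool
    homozygous_alt: bool

    @property
    def informative(self) -> bool:
        return self.passed_filters and self.homozygous_alt


def load_informative_snps(vcf_path: str | Path, sample: str | None = None) -> list[VariantSite]:
    """Load the informative SNP set from a VCF.

    Keeps records that are single-nucleotide, biallelic, FILTER=PASS and
    homozygous for the alternative allele in ``sample`` (the first sample
    when None; records with no samples count as homozygous-alt, as in a
    sites-only strain VCF). Output is sorted by (chrom, pos). An empty
    result triggers a warning, not an error.
    """
    sites: list[VariantSite] = []
    try:
        vcf = pysam.VariantFile(str(vcf_path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot read VCF {vcf_path}: {exc}") from exc
    with vcf:
        if sample is not None and sample not in list(vcf.header.samples):
            raise VcfParseError(f"sample {sample!r} not in VCF {vcf_path}")
        for i, rec in enumerate(vcf):
            try:
                site = _site_from_record(rec, sample)
            except Exception as exc:  # malformed record
                raise VcfParseError(f"malformed VCF record #{i + 1} in {vcf_path}: {exc}") from exc
            if site is not None and site.informative:
                sites.append(site)
    sites.sort(key=lambda s: (s.chrom, s.pos))
    if not sites:
        warnings.warn(f"no informative SNPs found in {vcf_path}")
    return sites


def _site_from_record(rec: pysam.VariantRecord, sample: str | None) -> VariantSite | None:
    alts = rec.alts or ()
    if len(alts) != 1:
        return None  # multiallelic or missing alt: excluded entirely
    ref, alt = rec.ref, alts[0]
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        return None  # indel / MNP / degenerate
    passed = "PASS" in rec.filter or len(rec.filter) == 0
    if len(rec.samples) == 0:
        hom_alt = True
    else:
        smp = rec.samples[sample] if sample is not None else rec.samples[0]
        gt = smp.get("GT")
        # missing genotype => conservatively excluded
        hom_alt = gt is not None and None not in gt and all(a == 1 for a in gt)
    return VariantSite(
        chrom=rec.chrom,
        pos=rec.start,  # pysam start is already 0-based
        ref_base=ref,
        alt_base=alt,
        passed_filters=passed,
        homozygous_alt=hom_alt,
    )


class SiteIndex:
    """Per-chromosome sorted arrays of informative SNPs, for fast overlap lookup."""

    def __init__(self, sites: list[VariantSite]):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        from itertools import groupby

        for chrom, group in groupby(sorted(sites, key=lambda s: (s.chrom, s.pos)), key=lambda s: s.chrom):
            g = list(group)
            pos = np.array([s.pos for s in g], dtype=np.int64)
            ref = np.array([s.ref_base for s in g])
            alt = np.array([s.alt_base for s in g])
            self.by_chrom[chrom] = (pos, ref, alt)

    @property
    def chroms(self) -> set[str]:
        return set(self.by_chrom)

    def overlapping(self, chrom: str, start: int, end: int):
        """Yield (pos, ref, alt) for informative sites in [start, end)."""
        entry = self.by_chrom.get(chrom)
        if entry is None:
            return zip((), (), ())
        pos, ref, alt = entry
        i = np.searchsorted(pos, start, side="left")
        j = np.searchsorted(pos, end, side="left")
        return zip(pos[i:j], ref[i:j], alt[i:j])


def write_sites_vcf(
    sites: list[VariantSite],
    path: str | Path,
    sample: str = "ALT_STRAIN",
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write informative sites back out as a PASS / homozygous-alt VCF."""
    header = pysam.VariantHeader()
    chroms = sorted({s.chrom for s in sites})
    for chrom in chroms:
        length = (contig_lengths or {}).get(chrom, max(s.pos for s in sites if s.chrom == chrom) + 1)
        header.add_line(f"##contig=<ID={chrom},length={length}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for s in sorted(sites, key=lambda s: (s.chrom, s.pos)):
            rec = vcf.new_record(contig=s.chrom, start=s.pos, alleles=(s.ref_base, s.alt_base))
            rec.filter.add("PASS")
            rec.samples[0]["GT"] = (1, 1)
            vcf.write(rec)


def write_sites_bed(sites: list[VariantSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.pos + 1}\t{s.ref_base}>{s.alt_base}\n")
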