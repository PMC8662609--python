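"""Per-read homolog-of-origin assignment at informative SNPs.

Each aligned read is compared to the two parental haplotypes at the
informative SNPs it overlaps: a base matching the reference allele votes for
the B6 homolog, a base matching the alternative allele votes for the ALT
homolog, and anything else (a third base, or a base below the quality
threshold) abstains. The read's call is the majority vote; ties with at
least one overlapped site are ambiguous, and reads overlapping no
informative site are uninformative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import pysam

from .variants import SiteIndex, VariantSite

logger = logging.getLogger(__name__)

CALL_B6 = "B6"
CALL_ALT = "ALT"
CALL_AMBIGUOUS = "ambiguous"
CALL_UNINFORMATIVE = "uninformative"
CALL_CATEGORIES = (CALL_B6, CALL_ALT, CALL_AMBIGUOUS, CALL_UNINFORMATIVE)

ASSIGNMENT_COLUMNS = [
    "read_id",
    "chrom",
    "start",
    "end",
    "strand",
    "n_informative",
    "votes_B6",
    "votes_ALT",
    "call",
]


class ChromMismatchError(ValueError):
    """Alignment and variant files share no chromosome names."""


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    n_informative: int
    votes_B6: int
    votes_ALT: int
    call: str


def assign_read(
    read: pysam.AlignedSegment,
    sites: SiteIndex,
    min_base_quality: int = 20,
) -> ReadAssignment:
    """Assign one aligned read to a homolog by voting at overlapped SNPs."""
    votes_b6 = votes_alt = n_inf = 0
    # map reference position -> (query base, base quality) over aligned bases
    pairs = read.get_aligned_pairs(matches_only=True)
    if pairs:
        seq = read.query_sequence
        quals = read.query_qualities
        by_ref = {rpos: qpos for qpos, rpos in pairs}
        for pos, ref_base, alt_base in sites.overlapping(
            read.reference_name, read.reference_start, read.reference_end
        ):
            qpos = by_ref.get(int(pos))
            if qpos is None:
                continue  # site deleted in the read
            if quals is not None and quals[qpos] < min_base_quality:
                continue  # low-quality base: not readable
            base = seq[qpos]
            if base == "N":
                continue
            n_inf += 1
            if base == ref_base:
                votes_b6 += 1
            elif base == alt_base:
                votes_alt += 1
            # a third base abstains but still counts as a readable site

    if n_inf == 0:
        call = CALL_UNINFORMATIVE
    elif votes_b6 > votes_alt:
        call = CALL_B6
    elif votes_alt > votes_b6:
        call = CALL_ALT
    else:
        call = CALL_AMBIGUOUS

    return ReadAssignment(
        read_id=read.query_name,
        chrom=read.reference_name,
        start=read.reference_start,
        end=read.reference_end,
        strand="-" if read.is_reverse else "+",
        n_informative=n_inf,
        votes_B6=votes_b6,
        votes_ALT=votes_alt,
        call=call,
    )


def assign_all(
    alignment_path: str | Path,
    sites: SiteIndex | list[VariantSite],
    min_base_quality: int = 20,
) -> tuple[pd.DataFrame, dict]:
    """Assign every usable read in a SAM/BAM file.

    Duplicate, secondary, supplementary and unmapped reads are excluded
    (counted under ``skipped``). Raises :class:`ChromMismatchError` when the
    alignment references and the variant chromosomes are entirely disjoint —
    the classic ``chr1`` vs ``1`` naming clash.

    Returns the assignment table plus a summary dict whose call-category
    counts partition the usable reads.
    """
    if not isinstance(sites, SiteIndex):
        sites = SiteIndex(sites)
    rows = []
    skipped = 0
    with pysam.AlignmentFile(str(alignment_path), check_sq=False) as af:
        refs = set(af.references or ())
        if refs and sites.chroms and not (refs & sites.chroms):
            raise ChromMismatchError(
                f"no shared chromosomes between alignments ({sorted(refs)}) "
                f"and variants ({sorted(sites.chroms)})"
            )
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary or read.is_duplicate:
                skipped += 1
                continue
            rows.append(assign_read(read, sites, min_base_quality=min_base_quality))

    table = pd.DataFrame([r.__dict__ for r in rows], columns=ASSIGNMENT_COLUMNS)
    counts = table["call"].value_counts().to_dict() if len(table) else {}
    summary = {c: int(counts.get(c, 0)) for c in CALL_CATEGORIES}
    summary["total"] = int(len(table))
    summary["skipped"] = skipped
    return table, summary


def effective_misassignment_rate(seq_error_rate: float) -> float:
    """Per-read homolog misassignment rate implied by the per-base error.

    For a read overlapping a single SNP, a substitution error (probability
    e) lands on the other allele's base one time in three, flipping the
    vote; the other two thirds abstain, making the read ambiguous.
    Conditional on the read receiving a B6/ALT call, the misassignment
    probability is (e/3) / (1 − 2e/3). Reads spanning several SNPs are
    misassigned less often, so this single-SNP rate is a conservative
    default for the downstream fraction estimator.
    """
    e = seq_error_rate
    if not 0.0 <= e < 1.0:
        raise ValueError("seq_error_rate must be in [0, 1)")
    return (e / 3.0) / (1.0 - 2.0 * e / 3.0)
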