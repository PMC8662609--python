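"""Sliding-window Poisson peak caller with strand-aware center estimation.

Hotspots are detected as windows whose read count exceeds a Poisson
expectation set by the larger of the local background rate (a wide window
around the test window, excluding it) and the genome-wide rate, with
Benjamini–Hochberg correction across all tested windows. Significant
windows are merged into peaks. For an SSDS-type assay the hotspot center is
the midpoint between the mean plus-strand and mean minus-strand read
positions, exploiting the strand-offset geometry of resected DSB ends; for
an H3K4me3-type assay the center is the coverage-weighted midpoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


class UnsortedInputError(ValueError):
    pass


@dataclass
class PeakParams:
    """Tuning knobs of the window test; defaults resolve kb-scale hotspots."""

    window: int = 1000
    step: int = 100
    bg_window: int = 10_000
    min_reads: int = 5
    q_threshold: float = 0.01
    merge_dist: int = 200
    assay_type: str = "ssds"

    def validate(self) -> list[str]:
        errors = []
        if self.window <= 0 or self.step <= 0:
            errors.append("window and step must be positive")
        if self.bg_window < self.window:
            errors.append("bg_window must be ≥ window")
        if self.min_reads < 1:
            errors.append("min_reads must be ≥ 1")
        if not 0 < self.q_threshold <= 1:
            errors.append("q_threshold must be in (0, 1]")
        if self.merge_dist < 0:
            errors.append("merge_dist must be nonnegative")
        if self.assay_type not in ("ssds", "h3k4me3"):
            errors.append("assay_type must be 'ssds' or 'h3k4me3'")
        return errors


@dataclass
class CalledPeak:
    id: str
    chrom: str
    start: int
    end: int
    center: int
    n_plus: int
    n_minus: int
    enrichment: float
    p_value: float
    q_value: float


def _load_read_midpoints(alignment_path: str | Path):
    """Read midpoints/strands per chromosome; rejects coordinate-unsorted input."""
    per_chrom: dict[str, tuple[list, list]] = {}
    lengths: dict[str, int] = {}
    with pysam.AlignmentFile(str(alignment_path), check_sq=False) as af:
        for name, length in zip(af.references or (), af.lengths or ()):
            lengths[name] = length
        last: dict[str, int] = {}
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary or read.is_duplicate:
                continue
            chrom = read.reference_name
            if last.get(chrom, -1) > read.reference_start:
                raise UnsortedInputError(f"input not coordinate-sorted at {chrom}:{read.reference_start}")
            last[chrom] = read.reference_start
            mids, strands = per_chrom.setdefault(chrom, ([], []))
            mids.append((read.reference_start + read.reference_end) // 2)
            strands.append(read.is_reverse)
    return (
        {c: (np.array(m, dtype=np.int64), np.array(s, dtype=bool)) for c, (m, s) in per_chrom.items()},
        lengths,
    )


def call_peaks(alignment_path: str | Path, params: PeakParams | None = None) -> list[CalledPeak]:
    """Call enriched intervals from a coordinate-sorted SAM/BAM file."""
    params = params or PeakParams()
    errors = params.validate()
    if errors:
        raise ValueError("; ".join(errors))
    data, lengths = _load_read_midpoints(alignment_path)
    if not data:
        return []

    total_reads = sum(len(m) for m, _ in data.values())
    total_len = sum(lengths.get(c, (m.max() + 1) if len(m) else 1) for c, (m, _) in data.items())
    genome_rate = total_reads / max(total_len, 1)  # reads per bp

    peaks: list[CalledPeak] = []
    window_records = []  # (chrom, win_start, count, p)
    for chrom, (mids, is_rev) in sorted(data.items()):
        chrom_len = lengths.get(chrom, int(mids.max()) + 1 if len(mids) else 1)
        order = np.argsort(mids, kind="stable")
        mids = mids[order]
        is_rev = is_rev[order]
        starts = np.arange(0, max(chrom_len - params.window, 0) + 1, params.step, dtype=np.int64)
        if len(starts) == 0:
            starts = np.array([0], dtype=np.int64)
        counts = np.searchsorted(mids, starts + params.window, side="left") - np.searchsorted(
            mids, starts, side="left"
        )
        # local background: wide window centered on the test window, test window excluded
        half = params.bg_window // 2
        centers = starts + params.window // 2
        bg_lo = np.clip(centers - half, 0, chrom_len)
        bg_hi = np.clip(centers + half, 0, chrom_len)
        bg_counts = np.searchsorted(mids, bg_hi, side="left") - np.searchsorted(mids, bg_lo, side="left")
        bg_len = np.maximum((bg_hi - bg_lo) - params.window, 1)
        local_rate = np.maximum(bg_counts - counts, 0) / bg_len
        mu = np.maximum(local_rate, genome_rate) * params.window
        pvals = stats.poisson.sf(counts - 1, mu)
        for s, c, p in zip(starts, counts, pvals):
            window_records.append((chrom, int(s), int(c), float(p)))

    if not window_records:
        return []
    all_p = np.array([w[3] for w in window_records])
    _, qvals, _, _ = multipletests(all_p, method="fdr_bh")

    sig = [
        (chrom, s, c, p, q)
        for (chrom, s, c, p), q in zip(window_records, qvals)
        if q <= params.q_threshold and c >= params.min_reads
    ]
    # merge significant windows per chromosome (gap ≤ merge_dist)
    by_chrom: dict[str, list] = {}
    for rec in sig:
        by_chrom.setdefault(rec[0], []).append(rec)

    idx = 0
    for chrom in sorted(by_chrom):
        recs = sorted(by_chrom[chrom], key=lambda r: r[1])
        mids, is_rev = data[chrom]
        order = np.argsort(mids, kind="stable")
        mids = mids[order]
        is_rev = is_rev[order]
        chrom_len = lengths.get(chrom, int(mids.max()) + 1)
        clusters: list[list] = []
        for rec in recs:
            s, e = rec[1], rec[1] + params.window
            if clusters and s - clusters[-1][1] <= params.merge_dist:
                clusters[-1][1] = max(clusters[-1][1], e)
                clusters[-1][2].append(rec)
            else:
                clusters.append([s, e, [rec]])
        for s, e, members in clusters:
            lo = np.searchsorted(mids, s, side="left")
            hi = np.searchsorted(mids, e, side="left")
            m = mids[lo:hi]
            rev = is_rev[lo:hi]
            n_plus = int((~rev).sum())
            n_minus = int(rev.sum())
            if n_plus + n_minus == 0:
                continue
            center = _estimate_center(m, rev, params.assay_type)
            center = int(np.clip(center, s, e - 1))
            rate = (n_plus + n_minus) / (e - s)
            enrichment = rate / genome_rate if genome_rate > 0 else np.inf
            p_best = min(r[3] for r in members)
            q_best = min(r[4] for r in members)
            peaks.append(
                CalledPeak(
                    id=f"peak{idx:05d}",
                    chrom=chrom,
                    start=int(s),
                    end=int(min(e, chrom_len)),
                    center=center,
                    n_plus=n_plus,
                    n_minus=n_minus,
                    enrichment=float(enrichment),
                    p_value=float(p_best),
                    q_value=float(q_best),
                )
            )
            idx += 1
    return peaks


def _estimate_center(mids: np.ndarray, is_rev: np.ndarray, assay_type: str) -> int:
    if assay_type == "ssds":
        plus = mids[~is_rev]
        minus = mids[is_rev]
        if len(plus) and len(minus):
            return int(round((plus.mean() + minus.mean()) / 2))
    return int(round(mids.mean()))


def peaks_to_frame(peaks: list[CalledPeak]) -> pd.DataFrame:
    cols = ["id", "chrom", "start", "end", "center", "n_plus", "n_minus", "enrichment", "p_value", "q_value"]
    return pd.DataFrame([p.__dict__ for p in peaks], columns=cols)


def write_peaks_bed(peaks: list[CalledPeak], path: str | Path) -> None:
    """BED6+4: name=id, score=−10·log10(q) capped at 1000, extra cols incl. center."""
    with open(path, "w") as fh:
        for p in peaks:
            score = int(min(1000, -10 * np.log10(max(p.q_value, 1e-100))))
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.id}\t{score}\t+\t"
                f"{p.center}\t{p.n_plus}\t{p.n_minus}\t{p.q_value:.3e}\n"
            )


def attach_reads(peaks: list[CalledPeak] | pd.DataFrame, assignments: pd.DataFrame) -> pd.DataFrame:
    """Count homolog-assigned reads per peak (midpoint in [start, end)).

    Returns one row per peak with columns n_B6 / n_ALT / n_ambiguous /
    n_uninformative; a peak with no overlapping reads keeps all zeros.
    """
    pf = peaks if isinstance(peaks, pd.DataFrame) else peaks_to_frame(peaks)
    out = pf[["id", "chrom", "start", "end", "center"]].copy()
    for col in ("n_B6", "n_ALT", "n_ambiguous", "n_uninformative"):
        out[col] = 0
    if len(assignments) == 0 or len(pf) == 0:
        return out

    call_col = {"B6": "n_B6", "ALT": "n_ALT", "ambiguous": "n_ambiguous", "uninformative": "n_uninformative"}
    for chrom, pk in pf.groupby("chrom", sort=False):
        reads = assignments[assignments["chrom"] == chrom]
        if len(reads) == 0:
            continue
        mid = ((reads["start"].to_numpy() + reads["end"].to_numpy()) // 2).astype(np.int64)
        pk = pk.sort_values("start")
        starts = pk["start"].to_numpy()
        ends = pk["end"].to_numpy()
        # peaks are non-overlapping after merging: locate by start, check end
        j = np.searchsorted(starts, mid, side="right") - 1
        ok = (j >= 0) & (mid < ends[np.clip(j, 0, len(ends) - 1)])
        for peak_row, call in zip(pk.index[j[ok]], reads["call"].to_numpy()[ok]):
            out.loc[peak_row, call_col[call]] += 1
    return out
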