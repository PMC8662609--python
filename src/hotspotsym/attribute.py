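"""PRDM9-allele attribution of hybrid hotspots against single-allele maps.

Each PRDM9 allele's binding specificity is characterized in animals
carrying only that allele; a hybrid hotspot is attributed to the allele
whose reference map contains a hotspot center within ``max_dist`` of it —
provided the other allele's map does not. A peak near both maps, or near
neither, stays unattributed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UNATTRIBUTED = "unattributed"


@dataclass
class AlleleMap:
    """Reference hotspot centers for one PRDM9 allele."""

    allele_name: str
    intervals: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end", "center"]))

    def __post_init__(self) -> None:
        df = self.intervals
        if "center" not in df.columns:
            df = df.assign(center=((df["start"] + df["end"]) // 2))
        self.intervals = df.sort_values(["chrom", "center"]).reset_index(drop=True)

    @classmethod
    def from_bed(cls, allele_name: str, path: str | Path) -> "AlleleMap":
        """Load a BED file; a 7th column, when present, is the hotspot center."""
        rows = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                f = line.rstrip("\n").split("\t")
                chrom, start, end = f[0], int(f[1]), int(f[2])
                center = int(f[6]) if len(f) > 6 and f[6].lstrip("-").isdigit() else (start + end) // 2
                rows.append({"chrom": chrom, "start": start, "end": end, "center": center})
        return cls(allele_name, pd.DataFrame(rows, columns=["chrom", "start", "end", "center"]))

    @classmethod
    def from_centers(cls, allele_name: str, chrom: str, centers, halfwidth: int = 500) -> "AlleleMap":
        centers = np.asarray(sorted(int(c) for c in centers))
        df = pd.DataFrame(
            {
                "chrom": chrom,
                "start": np.maximum(centers - halfwidth, 0),
                "end": centers + halfwidth,
                "center": centers,
            }
        )
        return cls(allele_name, df)

    def centers_for(self, chrom: str) -> np.ndarray:
        sub = self.intervals[self.intervals["chrom"] == chrom]
        return sub["center"].to_numpy(dtype=np.int64)


def _min_center_distance(centers: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Distance from each query position to its nearest center (inf if none)."""
    if len(centers) == 0:
        return np.full(len(query), np.inf)
    centers = np.sort(centers)
    j = np.searchsorted(centers, query)
    left = np.where(j > 0, np.abs(query - centers[np.maximum(j - 1, 0)]), np.inf)
    right = np.where(j < len(centers), np.abs(centers[np.minimum(j, len(centers) - 1)] - query), np.inf)
    return np.minimum(left, right)


def attribute_peaks(
    peaks: pd.DataFrame,
    map1: AlleleMap,
    map2: AlleleMap,
    max_dist: int = 500,
) -> pd.DataFrame:
    """Attribute each peak to the unique allele map within ``max_dist``.

    ``peaks`` needs columns id / chrom / center. Returns a table
    (peak_id, allele, dist_map1, dist_map2) with allele one of the two map
    names or "unattributed".
    """
    if peaks["id"].duplicated().any():
        dups = peaks.loc[peaks["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate peak ids: {dups}")
    rows = []
    for chrom, sub in peaks.groupby("chrom", sort=False):
        q = sub["center"].to_numpy(dtype=np.int64)
        d1 = _min_center_distance(map1.centers_for(chrom), q)
        d2 = _min_center_distance(map2.centers_for(chrom), q)
        near1 = d1 <= max_dist
        near2 = d2 <= max_dist
        allele = np.where(
            near1 & ~near2, map1.allele_name, np.where(near2 & ~near1, map2.allele_name, UNATTRIBUTED)
        )
        for pid, a, x1, x2 in zip(sub["id"], allele, d1, d2):
            rows.append({"peak_id": pid, "allele": a, "dist_map1": float(x1), "dist_map2": float(x2)})
    return pd.DataFrame(rows, columns=["peak_id", "allele", "dist_map1", "dist_map2"])


def dominance_summary(
    attributions: pd.DataFrame,
    read_totals: pd.Series | dict | None = None,
) -> dict:
    """Per-allele proportions of peaks and (optionally) of reads.

    ``read_totals`` maps peak_id to its informative read total for the
    read-weighted summary. Both weightings sum to 1 over
    allele1 + allele2 + unattributed.
    """
    if len(attributions) == 0:
        warnings.warn("no peaks to summarize: empty dominance summary")
        return {"n_peaks": 0, "peak_weighted": {}, "read_weighted": {}}
    labels = sorted(set(attributions["allele"]) | {UNATTRIBUTED})
    peak_counts = attributions["allele"].value_counts()
    n = len(attributions)
    out = {
        "n_peaks": int(n),
        "peak_weighted": {lab: float(peak_counts.get(lab, 0) / n) for lab in labels},
    }
    if read_totals is not None:
        rt = pd.Series(read_totals)
        weights = attributions.set_index("peak_id")["allele"].to_frame()
        weights["reads"] = rt.reindex(weights.index).fillna(0.0)
        total = weights["reads"].sum()
        by_allele = weights.groupby("allele")["reads"].sum()
        out["read_weighted"] = {
            lab: float(by_allele.get(lab, 0.0) / total) if total > 0 else float("nan") for lab in labels
        }
        out["n_reads"] = float(total)
    else:
        out["read_weighted"] = {}
    return out
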