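"""Per-hotspot homolog read-fraction estimation and matched/eroded classes.

The central quantity is f, the fraction of a hotspot's DSB signal arising
from the B6 homolog. Each informative read carries a homolog label that is
wrong with a small misclassification probability eps (from sequencing
error), so the observed B6-label probability is p = eps + f·(1 − 2·eps).
The maximum-likelihood estimate of f inverts that map at the sample
proportion, clamped to [0, 1]; its confidence interval maps a binomial
interval on p through the same monotone transform.

Hotspots with an estimated B6 contribution between 25% and 75% are
*matched* (both homologs appreciably bound and cut); a hotspot with more
than 75% of reads from one homolog is *eroded* toward that homolog.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

logger = logging.getLogger(__name__)

CLASS_MATCHED = "matched"
CLASS_ERODED_B6 = "eroded_B6_biased"
CLASS_ERODED_ALT = "eroded_ALT_biased"
CLASS_UNRESOLVED = "unresolved"
CLASSES = (CLASS_MATCHED, CLASS_ERODED_B6, CLASS_ERODED_ALT, CLASS_UNRESOLVED)

MATCHED_BAND = (0.25, 0.75)


@dataclass
class HotspotSymmetry:
    peak_id: str
    n_B6: int
    n_ALT: int
    f_hat: float  # NaN when unresolved
    ci_low: float
    ci_high: float
    label: str


def estimate_fraction(
    n_b6: int,
    n_alt: int,
    epsilon: float = 0.0,
    alpha: float = 0.05,
    ci_method: str = "beta",
) -> tuple[float, float, float]:
    """MLE of the B6 heat fraction under read-label misclassification.

    Parameters
    ----------
    n_b6, n_alt
        Informative read counts labelled B6 and ALT.
    epsilon
        Per-read misclassification probability, 0 ≤ eps < 0.5.
    alpha
        1 − confidence level of the interval.
    ci_method
        Binomial interval method passed to statsmodels ``proportion_confint``
        ("beta" is Clopper–Pearson).

    Returns ``(f_hat, ci_low, ci_high)``.
    """
    n = n_b6 + n_alt
    if n < 1:
        raise ValueError("need at least one informative read")
    if not 0.0 <= epsilon < 0.5:
        raise ValueError("epsilon must satisfy 0 ≤ epsilon < 0.5")
    p_obs = n_b6 / n
    lo_p, hi_p = proportion_confint(n_b6, n, alpha=alpha, method=ci_method)

    def unmix(p: float) -> float:
        return float(np.clip((p - epsilon) / (1.0 - 2.0 * epsilon), 0.0, 1.0))

    # the map p -> f is monotone increasing for epsilon < 0.5
    return unmix(p_obs), unmix(lo_p), unmix(hi_p)


def classify_fraction(
    f_hat: float,
    n_informative: int,
    min_reads: int = 5,
    band: tuple[float, float] = MATCHED_BAND,
) -> str:
    """Matched / eroded / unresolved label for one hotspot.

    Band endpoints are inclusive for "matched": erosion requires strictly
    more than 75% (resp. less than 25%) of reads from one homolog.
    """
    if n_informative < min_reads:
        return CLASS_UNRESOLVED
    lo, hi = band
    if f_hat > hi:
        return CLASS_ERODED_B6
    if f_hat < lo:
        return CLASS_ERODED_ALT
    return CLASS_MATCHED


def summarize_peaks(
    peak_counts: pd.DataFrame,
    epsilon: float = 0.0,
    min_reads: int = 5,
    band: tuple[float, float] = MATCHED_BAND,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-peak symmetry table from attach_reads output.

    Expects columns ``id``, ``n_B6``, ``n_ALT``; ambiguous and
    uninformative reads never enter numerator or denominator.
    """
    rows = []
    for r in peak_counts.itertuples():
        n = int(r.n_B6) + int(r.n_ALT)
        if n >= max(min_reads, 1):
            f_hat, lo, hi = estimate_fraction(int(r.n_B6), int(r.n_ALT), epsilon, alpha=alpha)
            label = classify_fraction(f_hat, n, min_reads=min_reads, band=band)
        else:
            f_hat = lo = hi = float("nan")
            label = CLASS_UNRESOLVED
        rows.append(
            {
                "peak_id": r.id,
                "n_B6": int(r.n_B6),
                "n_ALT": int(r.n_ALT),
                "f_hat": f_hat,
                "ci_low": lo,
                "ci_high": hi,
                "label": label,
            }
        )
    return pd.DataFrame(
        rows, columns=["peak_id", "n_B6", "n_ALT", "f_hat", "ci_low", "ci_high", "label"]
    )


def matched_read_proportion(
    symmetries: pd.DataFrame,
    attributions: pd.DataFrame,
    allele: str,
) -> dict | None:
    """Matched-signal proportion for the hotspots attributed to one allele.

    ``read_weighted``: informative reads at matched peaks over informative
    reads at all resolved peaks of the allele; ``peak_weighted``: the same
    with every peak counting once. Returns None (with a warning) when the
    allele has no resolved attributed peaks.
    """
    merged = symmetries.merge(attributions, on="peak_id", how="inner")
    sel = merged[(merged["allele"] == allele) & (merged["label"] != CLASS_UNRESOLVED)]
    if len(sel) == 0:
        warnings.warn(f"no resolved peaks attributed to {allele}: matched proportion undefined")
        return None
    n_inf = sel["n_B6"] + sel["n_ALT"]
    is_matched = sel["label"] == CLASS_MATCHED
    total_reads = int(n_inf.sum())
    return {
        "allele": allele,
        "read_weighted": float(n_inf[is_matched].sum() / total_reads) if total_reads else float("nan"),
        "peak_weighted": float(is_matched.mean()),
        "n_peaks": int(len(sel)),
        "n_matched_peaks": int(is_matched.sum()),
        "n_informative_reads": total_reads,
    }


def class_counts(symmetries: pd.DataFrame) -> dict:
    counts = symmetries["label"].value_counts().to_dict()
    out = {c: int(counts.get(c, 0)) for c in CLASSES}
    out["total"] = int(len(symmetries))
    return out
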