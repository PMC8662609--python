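"""Phenotype statistics: synapsis rates, normalized testis weight, group
comparisons, and the cliff-edge threshold model.

The cliff-edge model posits that sperm production requires autosomal
synapsis above a threshold tau (observed around 50%): below tau there is
little or no sperm, above it production is substantial. It is fitted as a
two-level step function of log10 sperm count versus synapsis rate, with the
threshold found by exhaustive search over midpoints between observed
synapsis values and a bootstrap confidence interval over mice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

logger = logging.getLogger(__name__)


def synapsis_rate(nuclei_synapsed: int, nuclei_total: int, alpha: float = 0.05):
    """Synapsis fraction with a 95% Wilson score interval."""
    if nuclei_total < 1:
        raise ValueError("nuclei_total must be ≥ 1")
    if nuclei_synapsed > nuclei_total or nuclei_synapsed < 0:
        raise ValueError("nuclei_synapsed must be in [0, nuclei_total]")
    rate = nuclei_synapsed / nuclei_total
    lo, hi = proportion_confint(nuclei_synapsed, nuclei_total, alpha=alpha, method="wilson")
    return rate, float(lo), float(hi)


def normalize_testis(testis_weight_mg: float, lean_body_weight_g: float) -> float:
    """Paired testis weight per gram of lean body mass (mg/g)."""
    if lean_body_weight_g <= 0:
        raise ValueError("lean_body_weight must be positive")
    if testis_weight_mg < 0:
        raise ValueError("testis_weight must be nonnegative")
    return testis_weight_mg / lean_body_weight_g


def group_ttest(group_a, group_b, alternative: str = "two-sided") -> dict:
    """Welch (unequal-variance) two-sample t-test between phenotype groups."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n ≥ 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        # degenerate: no variance anywhere; equal means are maximally consistent
        if a.mean() == b.mean():
            return {"t": 0.0, "df": float(len(a) + len(b) - 2), "p": 1.0}
        return {"t": float("inf") if a.mean() > b.mean() else float("-inf"),
                "df": float(len(a) + len(b) - 2), "p": 0.0}
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return {"t": float(res.statistic), "df": float(res.df), "p": float(res.pvalue)}


@dataclass
class ThresholdFit:
    tau_hat: float
    mean_below: float  # log10 sperm count below threshold
    mean_above: float
    sse: float
    ci_tau: tuple[float, float] | None
    degenerate: bool
    valid: bool  # mean_above ≥ mean_below, i.e. a genuine cliff-edge


def _log_sperm(sperm: np.ndarray, floor: float) -> np.ndarray:
    # mice with no sperm are given an arbitrary small count (default 2)
    # so they can be placed on the log scale
    counts = np.where(sperm <= 0, floor, sperm).astype(float)
    return np.log10(counts)


def _step_sse(x: np.ndarray, y: np.ndarray, tau: float) -> tuple[float, float, float]:
    below = x < tau
    m_below = y[below].mean() if below.any() else np.nan
    m_above = y[~below].mean() if (~below).any() else np.nan
    sse = 0.0
    if below.any():
        sse += float(((y[below] - m_below) ** 2).sum())
    if (~below).any():
        sse += float(((y[~below] - m_above) ** 2).sum())
    return sse, float(m_below), float(m_above)


def _best_tau(x: np.ndarray, y: np.ndarray):
    xs = np.unique(x)
    candidates = (xs[:-1] + xs[1:]) / 2.0
    if len(candidates) == 0:
        return None
    best = None
    for tau in candidates:  # ties resolved toward the smallest tau
        sse, m_lo, m_hi = _step_sse(x, y, float(tau))
        if best is None or sse < best[1] - 1e-12:
            best = (float(tau), sse, m_lo, m_hi)
    return best


def fit_cliff_edge(
    records: pd.DataFrame,
    pseudo_count: float = 2.0,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> ThresholdFit:
    """Fit the step ("cliff-edge") model of sperm count versus synapsis rate.

    ``records`` needs either a precomputed ``synapsis`` column or the
    nuclei counts, plus ``sperm_count``. Requires at least 4 mice and at
    least two distinct synapsis values. The bootstrap resamples mice with
    replacement; resamples without a crossable threshold are dropped from
    the CI.
    """
    df = records.copy()
    if "synapsis" not in df.columns:
        df["synapsis"] = df["nuclei_synapsed"] / df["nuclei_total"]
    if len(df) < 4:
        raise ValueError("need at least 4 mice to fit a threshold")
    x = df["synapsis"].to_numpy(dtype=float)
    y = _log_sperm(df["sperm_count"].to_numpy(), pseudo_count)

    best = _best_tau(x, y)
    if best is None:
        raise ValueError("all mice share one synapsis value: no candidate threshold")
    tau_hat, sse, m_below, m_above = best

    # flat response: every candidate threshold fits equally well
    degenerate = bool(np.allclose(y, y.mean()))
    valid = bool(not degenerate and m_above >= m_below)

    ci = None
    if n_boot > 0 and not degenerate:
        rng = np.random.default_rng(seed)
        taus = []
        n = len(x)
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            b = _best_tau(x[idx], y[idx])
            if b is not None:
                taus.append(b[0])
        if taus:
            lo, hi = np.percentile(taus, [100 * alpha / 2, 100 * (1 - alpha / 2)])
            ci = (float(lo), float(hi))

    return ThresholdFit(
        tau_hat=tau_hat,
        mean_below=m_below,
        mean_above=m_above,
        sse=sse,
        ci_tau=ci,
        degenerate=degenerate,
        valid=valid,
    )


def cohort_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-group means/SDs of synapsis, normalized testis weight and sperm."""
    df = records.copy()
    df["synapsis"] = df["nuclei_synapsed"] / df["nuclei_total"]
    df["testis_norm"] = df["testis_weight_mg"] / df["lean_body_weight_g"]
    agg = df.groupby("group").agg(
        n=("mouse_id", "count"),
        synapsis_mean=("synapsis", "mean"),
        synapsis_sd=("synapsis", "std"),
        testis_norm_mean=("testis_norm", "mean"),
        testis_norm_sd=("testis_norm", "std"),
        sperm_mean=("sperm_count", "mean"),
        sperm_sd=("sperm_count", "std"),
    )
    return agg.reset_index()
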