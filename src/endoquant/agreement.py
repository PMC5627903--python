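"""Method-comparison statistics for paired density estimates.

Bland-Altman agreement between a reference method (nuclei-channel / Hoechst
counts) and a test method (calcein-based counts): bias is the mean of
reference minus test, so a positive bias means the calcein method
under-counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["AgreementResult", "bland_altman", "pearson"]


@dataclass(frozen=True)
class AgreementResult:
    n: int
    bias: float  # mean(reference - test)
    sd_diff: float
    loa_low: float
    loa_high: float
    bias_ci_low: float
    bias_ci_high: float
    pearson_r: float
    pearson_p: float
    means: np.ndarray  # per-pair (reference + test)/2, for the agreement plot
    differences: np.ndarray  # per-pair reference - test


def bland_altman(
    reference: np.ndarray,
    test: np.ndarray,
    loa_multiplier: float | None = 1.96,
) -> AgreementResult:
    """Bland-Altman agreement of paired measurements.

    Limits of agreement are bias +/- 1.96*SD of the differences by default;
    pass ``loa_multiplier=None`` for the small-sample t-quantile instead.
    The 95% CI of the bias is t-based.  Pearson correlation of the paired
    values is reported alongside.
    """
    ref = np.asarray(reference, dtype=float)
    tst = np.asarray(test, dtype=float)
    if ref.shape != tst.shape or ref.ndim != 1:
        raise ValueError("reference and test must be equal-length 1-D vectors")
    n = len(ref)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    diffs = ref - tst
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    if loa_multiplier is None:
        loa_multiplier = float(stats.t.ppf(0.975, n - 1))
    half = loa_multiplier * sd
    tq = float(stats.t.ppf(0.975, n - 1))
    se = sd / np.sqrt(n)
    if np.ptp(ref) > 0 and np.ptp(tst) > 0:
        r, p = stats.pearsonr(ref, tst)
    else:
        r, p = np.nan, np.nan
    return AgreementResult(
        n=n, bias=bias, sd_diff=sd,
        loa_low=bias - half, loa_high=bias + half,
        bias_ci_low=bias - tq * se, bias_ci_high=bias + tq * se,
        pearson_r=float(r), pearson_p=float(p),
        means=(ref + tst) / 2.0, differences=diffs,
    )


def pearson(reference: np.ndarray, test: np.ndarray) -> tuple[float, float]:
    """Pearson product-moment correlation with its two-sided t-test p-value."""
    ref = np.asarray(reference, dtype=float)
    tst = np.asarray(test, dtype=float)
    if ref.shape != tst.shape or len(ref) < 3:
        raise ValueError("need equal-length vectors with at least 3 pairs")
    if np.ptp(ref) == 0 or np.ptp(tst) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(ref, tst)
    return float(r), float(p)
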