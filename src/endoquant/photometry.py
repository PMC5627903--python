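"""Patch-array fluorescence photometry, ROC threshold calibration, kinetics fits.

Measurements follow the conventions of in-situ confocal viability imaging:
mean fluorescence over 25x25-pixel arrays, SNR = patch mean / patch pixel SD,
contrast = mean viable-patch fluorescence / mean non-viable-patch
fluorescence (the graft periphery serving as the standard non-viable
reference), and an ROC sweep of grey-level cutoffs for classifying patches
as viable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PatchSample",
    "ContrastResult",
    "ROCResult",
    "DoseFit",
    "DecayFit",
    "sample_patches",
    "sample_patches_in_mask",
    "contrast",
    "roc",
    "fit_dose_response",
    "fit_decay",
]

PatchLabel = Literal["viable", "non_viable", "unlabeled"]


@dataclass(frozen=True)
class PatchSample:
    """A square pixel array with its summary photometry.

    ``snr`` is mean/SD and is None for a constant patch (SD = 0).
    """

    row: int
    col: int
    side: int
    label: PatchLabel
    mean: float
    sd: float

    @property
    def snr(self) -> float | None:
        return None if self.sd == 0.0 else self.mean / self.sd


@dataclass(frozen=True)
class ContrastResult:
    viable_mean: float
    non_viable_mean: float
    contrast: float
    n_viable: int
    n_non_viable: int
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    cutoff: float
    sensitivity_at_cutoff: float
    specificity_at_cutoff: float


@dataclass(frozen=True)
class DoseFit:
    slope: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class DecayFit:
    peak_time_h: float
    peak_intensity: float
    rate_per_h: float
    r_squared: float


def _measure(image: np.ndarray, row: int, col: int, side: int, label: PatchLabel) -> PatchSample:
    if row < 0 or col < 0 or row + side > image.shape[0] or col + side > image.shape[1]:
        raise ValueError(
            f"patch at (row={row}, col={col}, side={side}) exceeds image bounds {image.shape}"
        )
    block = image[row : row + side, col : col + side].astype(np.float64)
    return PatchSample(
        row=row, col=col, side=side, label=label,
        mean=float(block.mean()), sd=float(block.std()),
    )


def sample_patches(
    image: np.ndarray,
    locations: Sequence[tuple[int, int]],
    side: int = 25,
    labels: Sequence[PatchLabel] | PatchLabel = "unlabeled",
) -> list[PatchSample]:
    """Measure mean/SD photometry of patches at explicit top-left locations."""
    if side < 3:
        raise ValueError("patch side must be at least 3 pixels")
    if isinstance(labels, str):
        labels = [labels] * len(locations)
    if len(labels) != len(locations):
        raise ValueError("labels and locations must have equal length")
    return [_measure(image, r, c, side, lab) for (r, c), lab in zip(locations, labels)]


def sample_patches_in_mask(
    image: np.ndarray,
    mask: np.ndarray,
    n: int,
    side: int = 25,
    label: PatchLabel = "unlabeled",
    seed: int = 0,
    min_inside: float = 0.9,
    max_tries: int = 200_000,
) -> list[PatchSample]:
    """Draw ``n`` non-overlapping patches uniformly within a region mask.

    Rejection sampling: a candidate is accepted when at least ``min_inside``
    of its area lies inside the mask and it does not overlap an accepted
    patch.
    """
    if side < 3:
        raise ValueError("patch side must be at least 3 pixels")
    if mask.shape != image.shape:
        raise ValueError("mask and image shapes differ")
    rng = np.random.default_rng(seed)
    # summed-area table for O(1) in-mask fractions
    integral = np.pad(mask.astype(np.int64).cumsum(0).cumsum(1), ((1, 0), (1, 0)))

    def box_sum(tab: np.ndarray, r: int, c: int) -> int:
        return int(
            tab[r + side, c + side] - tab[r, c + side] - tab[r + side, c] + tab[r, c]
        )

    rows, cols = np.nonzero(mask)
    if len(rows) == 0:
        raise ValueError("empty mask")
    need = min_inside * side * side
    accepted: list[tuple[int, int]] = []
    occ = np.zeros(image.shape, dtype=bool)
    for _ in range(max_tries):
        if len(accepted) == n:
            break
        k = rng.integers(len(rows))
        r = int(rows[k]) - side // 2
        c = int(cols[k]) - side // 2
        if r < 0 or c < 0 or r + side > image.shape[0] or c + side > image.shape[1]:
            continue
        if box_sum(integral, r, c) < need:
            continue
        if occ[r : r + side, c : c + side].any():
            continue
        occ[r : r + side, c : c + side] = True
        accepted.append((r, c))
    if len(accepted) < n:
        raise RuntimeError(
            f"could only place {len(accepted)}/{n} non-overlapping patches in the mask"
        )
    return sample_patches(image, accepted, side=side, labels=label)


def contrast(
    viable_patches: Sequence[PatchSample],
    non_viable_patches: Sequence[PatchSample],
    n_boot: int = 2000,
    seed: int = 0,
) -> ContrastResult:
    """Fluorescence contrast: mean of viable patch means over mean of non-viable.

    The 95% CI of the ratio comes from a seeded nonparametric bootstrap over
    patches within each group.
    """
    if not viable_patches or not non_viable_patches:
        raise ValueError("both patch groups must be non-empty")
    v = np.array([p.mean for p in viable_patches])
    nv = np.array([p.mean for p in non_viable_patches])
    if nv.mean() <= 0:
        raise ValueError("non-viable group mean is zero; contrast undefined")
    rng = np.random.default_rng(seed)
    ratios = (
        v[rng.integers(len(v), size=(n_boot, len(v)))].mean(axis=1)
        / nv[rng.integers(len(nv), size=(n_boot, len(nv)))].mean(axis=1)
    )
    lo, hi = np.percentile(ratios, [2.5, 97.5])
    return ContrastResult(
        viable_mean=float(v.mean()),
        non_viable_mean=float(nv.mean()),
        contrast=float(v.mean() / nv.mean()),
        n_viable=len(v),
        n_non_viable=len(nv),
        ci_low=float(lo),
        ci_high=float(hi),
    )


def roc(
    patches: Sequence[PatchSample],
    positive_label: PatchLabel = "viable",
    cutoff: float | None = 40.0,
    youden: bool = False,
) -> ROCResult:
    """ROC over integer grey-level thresholds 0-255 for patch-mean classification.

    A patch is called viable when its mean is strictly greater than the
    threshold.  ``cutoff`` fixes the reported operating point (the 40-unit
    default); with ``youden=True`` the Youden-optimal threshold is chosen
    instead, ties broken toward the lower threshold.
    """
    pos = np.array([p.mean for p in patches if p.label == positive_label])
    neg = np.array([p.mean for p in patches if p.label not in (positive_label, "unlabeled")])
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("ROC needs patches from both classes")
    thresholds = np.arange(0, 256, dtype=float)
    sens = (pos[None, :] > thresholds[:, None]).mean(axis=1)
    spec = (neg[None, :] <= thresholds[:, None]).mean(axis=1)
    # trapezoidal AUC over the full (FPR, TPR) sweep, closed at both ends
    fpr = np.concatenate([[1.0], 1.0 - spec, [0.0]])
    tpr = np.concatenate([[1.0], sens, [0.0]])
    auc = float(np.trapezoid(tpr[::-1], fpr[::-1]))
    if youden:
        j = sens + spec - 1.0
        cutoff = float(thresholds[np.argmax(j)])  # argmax takes the first (lowest) tie
    elif cutoff is None:
        raise ValueError("either supply a fixed cutoff or request youden=True")
    if not 0 <= cutoff <= 255:
        raise ValueError("cutoff must lie in [0, 255]")
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        cutoff=float(cutoff),
        sensitivity_at_cutoff=float((pos > cutoff).mean()),
        specificity_at_cutoff=float((neg <= cutoff).mean()),
    )


def fit_dose_response(doses: Sequence[float], intensities: Sequence[float]) -> DoseFit:
    """Ordinary least-squares line through dose-fluorescence data."""
    doses = np.asarray(doses, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if len(np.unique(doses)) < 3:
        raise ValueError("need at least 3 distinct doses")
    res = stats.linregress(doses, intensities)
    return DoseFit(slope=float(res.slope), intercept=float(res.intercept),
                   r_squared=float(res.rvalue**2))


def fit_decay(
    times_h: Sequence[float],
    intensities: Sequence[float],
    peak_time_h: float = 2.0,
) -> DecayFit:
    """Exponential decay anchored at the post-staining fluorescence peak.

    Fits ``I(t) = I_peak * exp(-k (t - t_peak))`` by least squares on the log
    scale over time points at or after the peak.  A constant series yields
    rate 0.
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if np.any(y <= 0):
        raise ValueError("intensities must be positive for an exponential fit")
    keep = t >= peak_time_h
    t, y = t[keep], y[keep]
    if len(t) < 3:
        raise ValueError("need at least 3 time points at or after the peak")
    logy = np.log(y)
    if np.ptp(logy) == 0.0:  # constant series: no decay, exact fit
        return DecayFit(peak_time_h=peak_time_h, peak_intensity=float(y[0]),
                        rate_per_h=0.0, r_squared=1.0)
    res = stats.linregress(t - peak_time_h, logy)
    return DecayFit(
        peak_time_h=peak_time_h,
        peak_intensity=float(math.exp(res.intercept)),
        rate_per_h=float(-res.slope),
        r_squared=float(res.rvalue**2),
    )
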