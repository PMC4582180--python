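"""Dye-penetration quantification and group statistics.

The barrier-integrity readout of a dye-injection assay is the mean pixel
intensity of a region of interest after excluding overexposed (saturated)
areas such as the body cavity, which would otherwise dominate the mean.
Group differences between genotypes are assessed with a one-way ANOVA
followed by the Student-Newman-Keuls (SNK) step-down multiple-comparison
procedure on studentized ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage.morphology import dilation, footprint_rectangle

from .frap_extract import RoiSpec

__all__ = [
    "DyeQuantResult",
    "saturation_mask",
    "quantify_roi",
    "AnovaResult",
    "anova_oneway",
    "SnkResult",
    "snk_posthoc",
    "GroupComparison",
    "compare_groups",
    "significance_stars",
]


@dataclass
class DyeQuantResult:
    """Saturation-excluding mean ROI intensity."""

    mean_pixel_intensity: float
    n_used: int
    n_excluded: int
    saturation_value: int


def saturation_mask(image: np.ndarray, bit_depth: int, dilate_px: int = 1) -> np.ndarray:
    """True for overexposed pixels (>= 2^bit_depth - 1), dilated by ``dilate_px``.

    Dilation uses a square footprint, so ``dilate_px=1`` masks the full
    8-neighborhood of each saturated pixel -- a safety margin against bloom
    around overexposed regions.
    """
    image = np.asarray(image)
    limit = 2 ** bit_depth - 1
    if image.max() > limit:
        raise ValueError(f"image exceeds the {bit_depth}-bit ceiling {limit}")
    mask = image >= limit
    if dilate_px > 0 and mask.any():
        size = 2 * int(dilate_px) + 1
        mask = dilation(mask, footprint_rectangle((size, size)))
    return mask


def quantify_roi(
    image: np.ndarray,
    roi: RoiSpec | np.ndarray,
    mask: np.ndarray | None = None,
    bit_depth: int = 8,
    dilate_px: int = 1,
) -> DyeQuantResult:
    """Mean over ROI pixels not covered by the saturation mask.

    ``mask`` defaults to :func:`saturation_mask` of the image itself.  A
    fully masked ROI is an unquantifiable image and raises.
    """
    image = np.asarray(image, dtype=float)
    roi_mask = roi.mask(image.shape) if isinstance(roi, RoiSpec) else np.asarray(roi, bool)
    if mask is None:
        mask = saturation_mask(image, bit_depth, dilate_px)
    keep = roi_mask & ~mask
    if not keep.any():
        raise ValueError("unquantifiable image: ROI entirely overexposed/masked")
    return DyeQuantResult(
        mean_pixel_intensity=float(image[keep].mean()),
        n_used=int(keep.sum()),
        n_excluded=int((roi_mask & mask).sum()),
        saturation_value=2 ** bit_depth - 1,
    )


def _to_groups(table) -> tuple[list[str], list[np.ndarray]]:
    if isinstance(table, pd.DataFrame):
        labels, groups = [], []
        for label, sub in table.groupby("group", sort=False):
            labels.append(str(label))
            groups.append(sub["value"].to_numpy(dtype=float))
        return labels, groups
    groups = [np.asarray(g, dtype=float) for g in table]
    return [f"group{i}" for i in range(len(groups))], groups


@dataclass
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float


def anova_oneway(table) -> AnovaResult:
    """One-way ANOVA over all groups (F from the SSB/SSW decomposition).

    ``table`` is a tidy DataFrame with ``group``/``value`` columns or a
    sequence of per-group arrays.
    """
    _, groups = _to_groups(table)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 measurements")
    if not all(np.all(np.isfinite(g)) for g in groups):
        raise ValueError("non-finite measurements")
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ssw == 0 and ssb == 0:
        raise ValueError("all measurements identical: F undefined")
    k = len(groups)
    dfb, dfw = k - 1, len(allv) - k
    f_stat, p = stats.f_oneway(*groups)
    return AnovaResult(f=float(f_stat), df_between=dfb, df_within=dfw, p=float(p))


_Q_CACHE: dict[tuple[float, int, int], float] = {}


def _q_crit(alpha: float, r: int, df: int) -> float:
    """Upper-alpha quantile of the studentized range (numerical, any df)."""
    key = (alpha, r, df)
    if key not in _Q_CACHE:
        _Q_CACHE[key] = float(stats.studentized_range.ppf(1.0 - alpha, r, df))
    return _Q_CACHE[key]


@dataclass
class SnkResult:
    """SNK step-down decisions on ordered group means."""

    labels: list[str]                 # original label order
    ordered: list[str]                # labels sorted by mean, ascending
    means: dict                       # label -> mean
    significant: pd.DataFrame         # symmetric bool matrix (original label order)
    q_stats: pd.DataFrame             # studentized-range statistic per pair
    alpha: float
    df_within: int
    harmonic_n_used: bool = False
    details: list[dict] = field(default_factory=list)


def snk_posthoc(table, alpha: float = 0.05) -> SnkResult:
    """Student-Newman-Keuls step-down studentized-range procedure.

    Means are ordered; a range spanning ``r`` ordered means is declared
    significant when ``q = (max - min) / sqrt(MSW / n) > q(alpha, r, df_w)``.
    Testing proceeds from the full range downward; a non-significant range
    seals all its sub-ranges (they are not tested and their pairs are
    declared non-significant).  Equal group sizes are assumed; otherwise the
    harmonic mean n is substituted and flagged.
    """
    labels, groups = _to_groups(table)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 measurements")
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    n_total = int(ns.sum())
    df_w = n_total - k
    msw = sum(((g - g.mean()) ** 2).sum() for g in groups) / df_w
    if msw <= 0:
        raise ValueError("zero within-group variance: studentized range undefined")
    harmonic = not np.all(ns == ns[0])
    n_eff = len(groups[0]) if not harmonic else k / np.sum(1.0 / ns)
    se = np.sqrt(msw / n_eff)

    order = np.argsort([g.mean() for g in groups], kind="stable")
    ordered_labels = [labels[i] for i in order]
    ordered_means = np.array([groups[i].mean() for i in order])

    sig = np.zeros((k, k), dtype=bool)        # indexed in ordered space
    qmat = np.full((k, k), np.nan)
    sealed = np.zeros((k, k), dtype=bool)
    details = []
    for r in range(k, 1, -1):
        for i in range(0, k - r + 1):
            j = i + r - 1
            q = (ordered_means[j] - ordered_means[i]) / se
            qmat[i, j] = qmat[j, i] = q
            if sealed[i, j]:
                continue
            crit = _q_crit(alpha, r, df_w)
            significant = q > crit
            sig[i, j] = sig[j, i] = significant
            details.append({
                "pair": (ordered_labels[i], ordered_labels[j]),
                "span": r, "q": float(q), "q_crit": crit, "significant": bool(significant),
            })
            if not significant:
                sealed[i: j + 1, i: j + 1] = True
    # fill remaining q stats for sealed (untested) pairs
    for i in range(k):
        for j in range(i + 1, k):
            if np.isnan(qmat[i, j]):
                q = (ordered_means[j] - ordered_means[i]) / se
                qmat[i, j] = qmat[j, i] = q

    # map back to original label order
    inv = {lab: idx for idx, lab in enumerate(ordered_labels)}
    perm = [inv[lab] for lab in labels]
    sig_df = pd.DataFrame(sig[np.ix_(perm, perm)], index=labels, columns=labels)
    q_df = pd.DataFrame(qmat[np.ix_(perm, perm)], index=labels, columns=labels)
    return SnkResult(
        labels=labels,
        ordered=ordered_labels,
        means={lab: float(groups[i].mean()) for i, lab in zip(range(k), labels)},
        significant=sig_df,
        q_stats=q_df,
        alpha=alpha,
        df_within=df_w,
        harmonic_n_used=harmonic,
        details=details,
    )


def significance_stars(p: float) -> str:
    """Conventional star annotation: *** P<0.001, ** P<0.01, * P<0.05."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


@dataclass
class GroupComparison:
    """Per-group summary, omnibus ANOVA and SNK decision matrix."""

    summary: pd.DataFrame             # group, n, mean, sd, sem
    anova: AnovaResult
    snk: SnkResult
    alpha: float

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        return self.summary, self.snk.significant


def compare_groups(table, alpha: float = 0.05) -> GroupComparison:
    """Omnibus + post-hoc analysis of a tidy group/value measurement table."""
    labels, groups = _to_groups(table)
    summary = pd.DataFrame({
        "group": labels,
        "n": [len(g) for g in groups],
        "mean": [g.mean() for g in groups],
        "sd": [g.std(ddof=1) for g in groups],
        "sem": [g.std(ddof=1) / np.sqrt(len(g)) for g in groups],
    })
    return GroupComparison(
        summary=summary,
        anova=anova_oneway(table),
        snk=snk_posthoc(table, alpha=alpha),
        alpha=alpha,
    )
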