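"""Double-positive pixel quantification and group comparison.

Counts pixels positive for two markers simultaneously (boundary rule:
intensity ≥ threshold counts as positive) inside each annotated region,
reports counts and area-normalized fractions, and compares region groups
— e.g. lymphoid follicles vs control areas of similar surface area — with
a one-tailed Mann–Whitney U test. The test is exact (full enumeration
distribution) whenever the combined sample size is ≤ 20 with no ties,
which covers small ROI designs such as 7 follicles vs 5 controls; larger
or tied samples fall back to the normal approximation with tie and
continuity corrections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io import ChannelStack, Roi
from .preprocess import DEFAULT_PERCENTILE

EXACT_MAX_COMBINED_N = 20
# default positivity: the per-channel maximum-signal threshold (98th
# percentile) scaled down by this fraction
DEFAULT_POSITIVITY_FRACTION = 0.5


@dataclass(frozen=True)
class DoublePositiveResult:
    """Double-positive pixel count for one region."""

    region: str
    group: str
    positive_count: int
    total_count: int

    @property
    def fraction(self) -> float:
        return self.positive_count / self.total_count

    def __post_init__(self) -> None:
        if not 0 <= self.positive_count <= self.total_count:
            raise ValueError(
                f"positive count {self.positive_count} outside "
                f"[0, {self.total_count}]"
            )


@dataclass(frozen=True)
class MwTestResult:
    """One-tailed Mann–Whitney comparison of two region groups.

    ``u`` is the U statistic of the first group; ``direction`` states
    which group is hypothesized to be larger.
    """

    u: float
    p_one_tailed: float
    method: str  # "exact" | "normal-approximation"
    n1: int
    n2: int
    direction: str

    def __post_init__(self) -> None:
        if not 0 <= self.u <= self.n1 * self.n2:
            raise ValueError(f"U={self.u} outside [0, {self.n1 * self.n2}]")


def default_positivity_threshold(
    channel: np.ndarray,
    percentile: float = DEFAULT_PERCENTILE,
    positivity_fraction: float = DEFAULT_POSITIVITY_FRACTION,
) -> float:
    """Per-channel default call threshold: q-th percentile × fraction.

    A channel with no signal at the reference percentile gets an infinite
    threshold, so a dead channel never produces positive calls.
    """
    t = float(np.percentile(channel, percentile)) * positivity_fraction
    return t if t > 0 else np.inf


def count_double_positive(
    stack: ChannelStack,
    marker_a: str,
    marker_b: str,
    roi: Roi,
    thresholds: tuple[float, float] | None = None,
) -> DoublePositiveResult:
    """Count pixels ≥ threshold in both marker channels within one ROI.

    ``thresholds`` are raw-count positivity cutoffs for (marker_a,
    marker_b); when omitted, each defaults to the channel's 98th-percentile
    maximum-signal threshold scaled by the positivity fraction. Raising
    either threshold never increases the count.
    """
    for m in (marker_a, marker_b):
        if m not in stack.panel.marker_names:
            raise ValueError(f"marker {m!r} not in panel {stack.panel.marker_names}")
    mask = np.asarray(roi.mask, dtype=bool)
    if mask.shape != stack.shape[1:]:
        raise ValueError(
            f"ROI mask shape {mask.shape} != image shape {stack.shape[1:]}"
        )
    total = int(mask.sum())
    if total == 0:
        raise ValueError(f"ROI {roi.name!r} is empty")
    ca = stack.channel(marker_a)
    cb = stack.channel(marker_b)
    if thresholds is None:
        thresholds = (
            default_positivity_threshold(ca),
            default_positivity_threshold(cb),
        )
    ta, tb = thresholds
    positive = int(np.sum((ca[mask] >= ta) & (cb[mask] >= tb)))
    return DoublePositiveResult(
        region=roi.name, group=roi.group, positive_count=positive, total_count=total
    )


def quantify_rois(
    stack: ChannelStack,
    marker_a: str,
    marker_b: str,
    rois: Sequence[Roi],
    thresholds: tuple[float, float] | None = None,
) -> list[DoublePositiveResult]:
    """Double-positive counts for every ROI under shared thresholds."""
    if thresholds is None:
        thresholds = (
            default_positivity_threshold(stack.channel(marker_a)),
            default_positivity_threshold(stack.channel(marker_b)),
        )
    return [
        count_double_positive(stack, marker_a, marker_b, roi, thresholds)
        for roi in rois
    ]


def mann_whitney_one_tailed(
    group_a: Sequence[float],
    group_b: Sequence[float],
    direction: str = "greater",
) -> MwTestResult:
    """One-tailed Mann–Whitney U test between two groups of fractions.

    ``direction='greater'`` tests whether group_a tends to exceed group_b.
    U uses mid-rank ranking; the p-value is exact (distribution over all
    C(n1+n2, n1) label arrangements) when n1 + n2 ≤ 20 and the pooled
    sample has no ties, else a tie- and continuity-corrected normal
    approximation.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if direction not in {"greater", "less"}:
        raise ValueError("direction must be 'greater' or 'less'")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        # fully tied pooled sample: U sits exactly at its null mean
        return MwTestResult(
            u=a.size * b.size / 2.0,
            p_one_tailed=0.5,
            method="normal-approximation",
            n1=int(a.size),
            n2=int(b.size),
            direction=direction,
        )
    has_ties = np.unique(pooled).size < pooled.size
    exact = (a.size + b.size <= EXACT_MAX_COMBINED_N) and not has_ties
    res = stats.mannwhitneyu(
        a,
        b,
        alternative=direction,
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return MwTestResult(
        u=float(res.statistic),
        p_one_tailed=float(res.pvalue),
        method="exact" if exact else "normal-approximation",
        n1=int(a.size),
        n2=int(b.size),
        direction=direction,
    )


def compare_groups(
    results: Sequence[DoublePositiveResult],
    group_a: str = "LF",
    group_b: str = "non-LF",
    direction: str = "greater",
) -> MwTestResult:
    """Mann–Whitney comparison of double-positive fractions between groups.

    Fractions (not raw counts) normalize for region area, since control
    regions are drawn to a similar but not identical surface area.
    """
    fa = [r.fraction for r in results if r.group == group_a]
    fb = [r.fraction for r in results if r.group == group_b]
    if not fa or not fb:
        raise ValueError(
            f"need results in both groups {group_a!r} and {group_b!r}; "
            f"got {len(fa)} and {len(fb)}"
        )
    return mann_whitney_one_tailed(fa, fb, direction=direction)
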