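"""Per-recording summary statistics and group comparisons.

Reproduces the reporting conventions of the source workflow: per
field-of-view sparklet frequency (events/s), number of active sites,
sites per cell (the cell count may be supplied or estimated from the
field area and a 462 um^2 mean endothelial-cell area), mean per-site
frequency, mean +/- SEM summaries, two-group Student's t-tests (paired or
unpaired) with a rank-based fallback when normality fails, and one-way
ANOVA with Sidak-adjusted pairwise post hoc comparisons for three or
more groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

MEAN_CELL_AREA_UM2 = 462.0

__all__ = [
    "FovSummary",
    "GroupComparison",
    "PairwiseComparison",
    "summarize_fov",
    "compare_groups",
    "mean_sem",
    "sidak_adjust",
    "MEAN_CELL_AREA_UM2",
]


@dataclass
class FovSummary:
    """Sparklet statistics for one recording (field of view)."""

    recording_id: str
    condition: str
    duration_s: float
    n_events: int
    n_sites: int
    n_cells: float
    fov_frequency_hz: float
    site_frequency_hz: float
    sites_per_cell: float

    def to_dict(self) -> dict:
        return {
            "recording_id": self.recording_id,
            "condition": self.condition,
            "duration_s": self.duration_s,
            "n_events": self.n_events,
            "n_sites": self.n_sites,
            "n_cells": self.n_cells,
            "fov_frequency_hz": self.fov_frequency_hz,
            "site_frequency_hz": self.site_frequency_hz,
            "sites_per_cell": self.sites_per_cell,
        }


def summarize_fov(
    events,
    sites,
    duration_s: float,
    n_cells: float | None = None,
    fov_area_um2: float | None = None,
    mean_cell_area_um2: float = MEAN_CELL_AREA_UM2,
    recording_id: str = "",
    condition: str = "",
) -> FovSummary:
    """Per-recording sparklet statistics.

    ``fov_frequency_hz`` is total events over duration; ``site_frequency_hz``
    the mean over active sites of per-site event count over duration;
    ``sites_per_cell`` uses the supplied cell count, falling back to
    field area divided by the mean cell area.
    """
    if duration_s <= 0:
        raise ValueError("recording duration must be positive")
    if n_cells is None:
        if fov_area_um2 is None:
            raise ValueError("supply n_cells or fov_area_um2 to estimate it")
        # a field smaller than one cell still images (part of) one cell
        n_cells = max(1.0, fov_area_um2 / mean_cell_area_um2)
    if n_cells < 1:
        raise ValueError(f"cell count must be >= 1, got {n_cells}")
    n_events = len(events)
    n_sites = len(sites)
    if n_sites:
        per_site = [
            s if isinstance(s, (int, np.integer)) else len(getattr(s, "events", ()))
            for s in sites
        ]
        site_frequency = float(np.mean(per_site)) / duration_s
    else:
        site_frequency = 0.0
    return FovSummary(
        recording_id=recording_id,
        condition=condition,
        duration_s=float(duration_s),
        n_events=n_events,
        n_sites=n_sites,
        n_cells=float(n_cells),
        fov_frequency_hz=n_events / duration_s,
        site_frequency_hz=site_frequency,
        sites_per_cell=n_sites / n_cells,
    )


def mean_sem(values) -> tuple[float, float]:
    """Mean and standard error of the mean (ddof = 1)."""
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise ValueError("SEM requires at least two values")
    return float(x.mean()), float(sps.sem(x, ddof=1))


def sidak_adjust(p_values) -> np.ndarray:
    """Sidak multiple-comparison adjustment: 1 - (1 - p)^m."""
    p = np.asarray(list(p_values), dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.clip(1.0 - (1.0 - p) ** p.size, 0.0, 1.0)


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    statistic: float
    p_raw: float
    p_adjusted: float


@dataclass
class GroupComparison:
    """Result of a two-group test or a k-group ANOVA with post hoc tests."""

    group_labels: list[str]
    group_values: list[np.ndarray]
    test_name: str
    statistic: float
    p_value: float
    paired: bool
    pairwise: list[PairwiseComparison] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0 and not np.isnan(self.p_value):
            raise ValueError("p-value outside [0, 1]")


def _is_normalish(x: np.ndarray, alpha: float) -> bool:
    """Shapiro-Wilk screen; tiny or constant samples pass by default."""
    if x.size < 3 or np.ptp(x) == 0:
        return True
    return bool(sps.shapiro(x).pvalue >= alpha)


def _two_group(
    a: np.ndarray, b: np.ndarray, paired: bool, normal: bool
) -> tuple[str, float, float]:
    if normal:
        if paired:
            res = sps.ttest_rel(a, b)
            name = "paired t-test"
        else:
            res = sps.ttest_ind(a, b)
            name = "unpaired t-test"
    else:
        if paired:
            res = sps.wilcoxon(a, b)
            name = "Wilcoxon signed-rank"
        else:
            res = sps.mannwhitneyu(a, b, alternative="two-sided")
            name = "Mann-Whitney U"
    stat = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(p) and np.array_equal(a, b):
        # identical degenerate groups: no evidence of a difference
        stat, p = 0.0, 1.0
    return name, stat, p


def compare_groups(
    groups,
    labels: list[str] | None = None,
    paired: bool = False,
    normality_alpha: float = 0.05,
) -> GroupComparison:
    """Two-tailed two-group test, or one-way ANOVA with Sidak post hoc.

    ``groups`` is a mapping label -> values or a sequence of value
    arrays.  Two groups get a Student's t-test (paired per the flag);
    three or more get one-way ANOVA plus all pairwise comparisons with
    Sidak-adjusted p-values.  Groups failing a Shapiro-Wilk normality
    screen switch the tests to rank-based alternatives.
    """
    if isinstance(groups, dict):
        labels = list(groups.keys())
        values = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        values = [np.asarray(v, dtype=float) for v in groups]
        if labels is None:
            labels = [f"group{i + 1}" for i in range(len(values))]
    if len(values) < 2:
        raise ValueError("need at least two groups")
    for lab, v in zip(labels, values):
        if v.size < 2:
            raise ValueError(f"group '{lab}' has fewer than two values")
    normal = all(_is_normalish(v, normality_alpha) for v in values)

    if len(values) == 2:
        a, b = values
        if paired and a.size != b.size:
            raise ValueError("paired design requires equal group sizes")
        name, stat, p = _two_group(a, b, paired, normal)
        return GroupComparison(
            group_labels=labels, group_values=values,
            test_name=name, statistic=stat, p_value=p, paired=paired,
        )

    if normal:
        res = sps.f_oneway(*values)
        name = "one-way ANOVA"
    else:
        res = sps.kruskal(*values)
        name = "Kruskal-Wallis"
    pairs = [(i, j) for i in range(len(values)) for j in range(i + 1, len(values))]
    raw = []
    stats_ = []
    for i, j in pairs:
        pname, s, pv = _two_group(values[i], values[j], False, normal)
        raw.append(pv)
        stats_.append(s)
    adjusted = sidak_adjust(raw)
    pairwise = [
        PairwiseComparison(
            group_a=labels[i], group_b=labels[j],
            statistic=stats_[k], p_raw=raw[k], p_adjusted=float(adjusted[k]),
        )
        for k, (i, j) in enumerate(pairs)
    ]
    return GroupComparison(
        group_labels=labels, group_values=values,
        test_name=name + " + Sidak post hoc",
        statistic=float(res.statistic), p_value=float(res.pvalue),
        paired=False, pairwise=pairwise,
    )
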