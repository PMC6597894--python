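"""Cardiac intervals from valve events, and group-level statistics.

Interval definitions (all in ms):

* ICT  = t(Ao) - t(Mc)   isovolumic contraction time
* VET  = t(Ac) - t(Ao)   ventricular ejection time
* IRT  = t(Mo) - t(Ac)   isovolumic relaxation time
* PEP  = EDT + ICT       pre-ejection period (EDT = electromechanical delay,
                         default 25 ms)
* STI  = PEP + VET       systolic time interval

Group comparisons use the nonparametric pair Kruskal-Wallis (omnibus) and
Mann-Whitney-Wilcoxon (pairwise, raw p-values), plus a Spearman correlation
of each interval against gestational age over pooled adjacent groups.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .events import ValveEventSet

INTERVAL_NAMES = ("ict", "vet", "irt", "pep", "sti")

__all__ = [
    "INTERVAL_NAMES",
    "BeatIntervals",
    "SubjectSummary",
    "GroupStatsTable",
    "compute_intervals",
    "aggregate_subject",
    "group_summary",
    "kruskal_wallis",
    "pairwise_mannwhitney",
    "age_correlation",
    "full_group_stats",
]


@dataclass
class BeatIntervals:
    """Per-beat intervals in ms; NaN marks a missing value."""

    beat_index: int
    rr_ms: float
    ict_ms: float = math.nan
    vet_ms: float = math.nan
    irt_ms: float = math.nan
    pep_ms: float = math.nan
    sti_ms: float = math.nan
    flags: dict = field(default_factory=dict)

    def get(self, name: str) -> float:
        return getattr(self, f"{name}_ms")


def compute_intervals(events: ValveEventSet, rr_ms: float, edt_ms: float = 25.0) -> BeatIntervals:
    """Derive ICT/VET/IRT/PEP/STI for one beat from its valve-event times.

    Any interval whose operand is missing is itself missing; a negative
    difference (ordering violation) is set missing and flagged rather than
    propagated.
    """
    if edt_ms < 0:
        raise ValueError("edt_ms must be non-negative")
    out = BeatIntervals(beat_index=events.beat_index, rr_ms=rr_ms)

    def diff(a: float, b: float, name: str) -> float:
        if math.isnan(a) or math.isnan(b):
            return math.nan
        d = a - b
        if d <= 0:
            out.flags[f"{name}_ordering_violation"] = True
            return math.nan
        return d

    out.ict_ms = diff(events.t_ao_ms, events.t_mc_ms, "ict")
    out.vet_ms = diff(events.t_ac_ms, events.t_ao_ms, "vet")
    out.irt_ms = diff(events.t_mo_ms, events.t_ac_ms, "irt")
    out.pep_ms = math.nan if math.isnan(out.ict_ms) else edt_ms + out.ict_ms
    out.sti_ms = (
        math.nan if (math.isnan(out.pep_ms) or math.isnan(out.vet_ms)) else out.pep_ms + out.vet_ms
    )
    return out


@dataclass
class SubjectSummary:
    """Per-subject mean intervals over retained beats."""

    subject_id: str
    group_label: str
    means_ms: dict
    n_beats: int
    n_per_interval: dict = field(default_factory=dict)
    week: float | None = None

    def get(self, name: str) -> float:
        return self.means_ms.get(name, math.nan)


def aggregate_subject(
    beats: list[BeatIntervals],
    subject_id: str,
    group_label: str,
    week: float | None = None,
) -> SubjectSummary:
    """Average each interval over the beats where it is present."""
    if not beats:
        raise ValueError("no beats to aggregate")
    means: dict[str, float] = {}
    counts: dict[str, int] = {}
    means["rr"] = float(np.mean([b.rr_ms for b in beats]))
    counts["rr"] = len(beats)
    for name in INTERVAL_NAMES:
        vals = np.array([b.get(name) for b in beats], dtype=float)
        vals = vals[~np.isnan(vals)]
        counts[name] = int(vals.size)
        means[name] = float(vals.mean()) if vals.size else math.nan
    return SubjectSummary(
        subject_id=subject_id,
        group_label=group_label,
        means_ms=means,
        n_beats=len(beats),
        n_per_interval=counts,
        week=week,
    )


def group_summary(
    subjects: list[SubjectSummary],
    intervals: tuple[str, ...] = INTERVAL_NAMES,
    group_order: list[str] | None = None,
) -> pd.DataFrame:
    """Mean and standard error per group and interval over subject means.

    SE = sd(n-1 denominator) / sqrt(n_subjects); reported NaN for groups with
    fewer than two subjects carrying the interval.
    """
    if group_order is None:
        group_order = sorted({s.group_label for s in subjects})
    rows = []
    for name in intervals:
        for g in group_order:
            vals = np.array(
                [s.get(name) for s in subjects if s.group_label == g], dtype=float
            )
            vals = vals[~np.isnan(vals)]
            n = vals.size
            mean = float(vals.mean()) if n else math.nan
            se = float(np.std(vals, ddof=1) / np.sqrt(n)) if n >= 2 else math.nan
            rows.append(dict(interval=name, group=g, mean=mean, se=se, n=n))
    return pd.DataFrame(rows)


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Rank-based H statistic with tie correction, chi-square p (k-1 df)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sstats.kruskal(*arrays)
    return float(h), float(p)


def pairwise_mannwhitney(groups: list[np.ndarray]) -> dict[tuple[int, int], float]:
    """Two-sided Mann-Whitney-Wilcoxon p-value for every pair of groups.

    Exact distribution when both groups have <= 20 values and no ties span
    the pooled pair; otherwise the normal approximation with tie and
    continuity corrections.  P-values are raw (no multiplicity adjustment).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 values")
    out: dict[tuple[int, int], float] = {}
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            a, b = arrays[i], arrays[j]
            pooled = np.concatenate([a, b])
            if np.all(pooled == pooled[0]):
                out[(i, j)] = 1.0
                continue
            no_ties = np.unique(pooled).size == pooled.size
            method = "exact" if (a.size <= 20 and b.size <= 20 and no_ties) else "asymptotic"
            res = sstats.mannwhitneyu(a, b, alternative="two-sided", method=method)
            out[(i, j)] = float(res.pvalue)
    return out


def age_correlation(
    subjects: list[SubjectSummary],
    interval_name: str,
    pair: tuple[str, str],
) -> float:
    """Spearman correlation of an interval with gestational age over two groups.

    Age is the subject's gestational week when available for every pooled
    subject, else the group rank (0 for the younger group, 1 for the older).
    Returns NaN when undefined (constant values or too few subjects).
    """
    pooled = [s for s in subjects if s.group_label in pair and not math.isnan(s.get(interval_name))]
    if len(pooled) < 3:
        raise ValueError("need at least 3 subjects with the interval present")
    y = np.array([s.get(interval_name) for s in pooled])
    if all(s.week is not None for s in pooled):
        x = np.array([s.week for s in pooled], dtype=float)
    else:
        x = np.array([0.0 if s.group_label == pair[0] else 1.0 for s in pooled])
    if np.unique(y).size == 1 or np.unique(x).size == 1:
        return math.nan
    r, _ = sstats.spearmanr(x, y)
    return float(r)


@dataclass
class GroupStatsTable:
    """Bundle of the group-level report tables."""

    summary: pd.DataFrame
    kruskal: pd.DataFrame
    pairwise: pd.DataFrame
    correlations: pd.DataFrame


def full_group_stats(
    subjects: list[SubjectSummary],
    group_order: list[str],
    intervals: tuple[str, ...] = INTERVAL_NAMES,
) -> GroupStatsTable:
    """Assemble mean±SE, Kruskal-Wallis, pairwise MWW and age correlations."""
    summary = group_summary(subjects, intervals, group_order)
    kw_rows, pw_rows, corr_rows = [], [], []
    for name in intervals:
        groups = []
        for g in group_order:
            vals = np.array([s.get(name) for s in subjects if s.group_label == g], dtype=float)
            groups.append(vals[~np.isnan(vals)])
        if all(g.size >= 2 for g in groups):
            h, p = kruskal_wallis(groups)
            kw_rows.append(dict(interval=name, H=h, p=p))
            for (i, j), p_ij in pairwise_mannwhitney(groups).items():
                pw_rows.append(
                    dict(interval=name, pair=f"{group_order[i]} vs {group_order[j]}", p=p_ij)
                )
        for a, b in zip(group_order[:-1], group_order[1:]):
            try:
                r = age_correlation(subjects, name, (a, b))
            except ValueError:
                r = math.nan
            corr_rows.append(dict(interval=name, pair=f"{a} to {b}", r=r))
    return GroupStatsTable(
        summary=summary,
        kruskal=pd.DataFrame(kw_rows),
        pairwise=pd.DataFrame(pw_rows),
        correlations=pd.DataFrame(corr_rows),
    )
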