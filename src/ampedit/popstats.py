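"""Group-level statistics over per-sample editing outcomes.

Samples (one :class:`~ampedit.classify.OutcomeTable` each, tagged with
population/condition/replicate labels) are summarised as mean +- sample SD
(n-1 denominator) and compared with an unpaired two-tailed Student t test
(pooled variance; Welch available as an option).  Fold changes are ratios of
group means.  No multiple-testing correction is applied; significance tiers
are reported at 0.05 / 0.01 / 0.001.

Undefined HDR/NHEJ ratios (samples with zero NHEJ reads) are excluded from
group summaries and reported in an excluded-count column, never imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import OutcomeTable

METRICS = ("hdr_rate", "nhej_rate", "hdr_nhej_ratio")


@dataclass(frozen=True)
class SampleOutcome:
    """An outcome table tagged with its experimental-design labels."""

    sample_id: str
    population: str
    condition: str
    replicate: str
    outcome: OutcomeTable

    def __post_init__(self) -> None:
        if not (self.sample_id and self.population and self.condition):
            raise ValueError("sample, population and condition labels must be non-empty")

    def metric(self, name: str) -> float:
        if name not in METRICS:
            raise ValueError(f"unknown metric {name!r}; expected one of {METRICS}")
        return getattr(self.outcome, name)


@dataclass(frozen=True)
class GroupSummary:
    """Mean +- sample SD of one metric within one group."""

    group: str
    metric: str
    n: int
    mean: float
    sd: float  # NaN when n < 2 (undefined, flagged)
    n_excluded: int = 0  # samples dropped for an undefined metric value

    @property
    def sd_defined(self) -> bool:
        return not math.isnan(self.sd)


@dataclass(frozen=True)
class GroupComparison:
    """Unpaired two-tailed t test and fold change between two groups."""

    group_a: str
    group_b: str
    metric: str
    n_a: int
    n_b: int
    fold_change: float  # mean(a) / mean(b); NaN when undefined
    t_statistic: float
    p_value: float
    df: float
    stars: str
    note: str = ""

    @property
    def tested(self) -> bool:
        return not math.isnan(self.p_value)


def _values(samples: Sequence[SampleOutcome], metric: str) -> np.ndarray:
    return np.array([s.metric(metric) for s in samples], dtype=float)


def _finite(values: np.ndarray) -> tuple[np.ndarray, int]:
    mask = np.isfinite(values)
    return values[mask], int((~mask).sum())


def significance_stars(p: float) -> str:
    if math.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def summarize(
    samples: Sequence[SampleOutcome], metric: str, group: str = ""
) -> GroupSummary:
    """Sample mean and sample SD (n-1) of *metric* over a group.

    Raises ``ValueError`` on an empty group or a group with no defined values.
    """
    if not samples:
        raise ValueError("empty group")
    values, n_excluded = _finite(_values(samples, metric))
    if values.size == 0:
        raise ValueError(f"all values of {metric!r} are undefined in group {group!r}")
    sd = float(np.std(values, ddof=1)) if values.size >= 2 else math.nan
    return GroupSummary(
        group=group,
        metric=metric,
        n=int(values.size),
        mean=float(values.mean()),
        sd=sd,
        n_excluded=n_excluded,
    )


def compare_groups(
    a: Sequence[SampleOutcome],
    b: Sequence[SampleOutcome],
    metric: str,
    equal_var: bool = True,
    label_a: str = "a",
    label_b: str = "b",
) -> GroupComparison:
    """Unpaired two-tailed t test (pooled variance by default) plus fold change.

    Fold change is ``mean(a) / mean(b)`` and is flagged NaN when the
    denominator mean is not positive.  Groups with fewer than two defined
    values skip the test with a recorded reason rather than raising.
    """
    va, ea = _finite(_values(a, metric))
    vb, eb = _finite(_values(b, metric))
    note = ""
    if vb.size and vb.mean() > 0:
        fold = float(va.mean() / vb.mean()) if va.size else math.nan
    else:
        fold = math.nan
        note = "fold change undefined (non-positive denominator mean); "
    if va.size < 2 or vb.size < 2:
        return GroupComparison(
            label_a, label_b, metric, int(va.size), int(vb.size), fold,
            math.nan, math.nan, math.nan, "",
            note=note + "test skipped: each group needs n >= 2",
        )
    t, p = stats.ttest_ind(va, vb, equal_var=equal_var)
    df = (
        float(va.size + vb.size - 2)
        if equal_var
        else float(_welch_df(va, vb))
    )
    return GroupComparison(
        label_a, label_b, metric, int(va.size), int(vb.size), fold,
        float(t), float(p), df, significance_stars(float(p)), note=note.rstrip("; "),
    )


def _welch_df(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    return (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))


def ratio_table(
    samples: Sequence[SampleOutcome],
    group_by: str = "condition",
    metric: str = "hdr_nhej_ratio",
    equal_var: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format per-group summaries plus all pairwise fold comparisons.

    Returns ``(summaries, comparisons)`` DataFrames.  Groups are formed on the
    ``group_by`` label (``population``, ``condition`` or ``sample_id``);
    comparisons cover every ordered pair of distinct groups once (a vs b).
    """
    if group_by not in ("population", "condition", "replicate", "sample_id"):
        raise ValueError(f"cannot group by {group_by!r}")
    if not samples:
        raise ValueError("no samples")
    groups: dict[str, list[SampleOutcome]] = {}
    for s in samples:
        groups.setdefault(getattr(s, group_by), []).append(s)
    labels = sorted(groups)
    summaries = pd.DataFrame(
        [vars(summarize(groups[g], metric, group=g)) for g in labels]
    )
    rows = []
    for i, ga in enumerate(labels):
        for gb in labels[i + 1 :]:
            cmp_ = compare_groups(
                groups[ga], groups[gb], metric, equal_var, label_a=ga, label_b=gb
            )
            rows.append(vars(cmp_))
    comparisons = pd.DataFrame(
        rows,
        columns=[
            "group_a", "group_b", "metric", "n_a", "n_b", "fold_change",
            "t_statistic", "p_value", "df", "stars", "note",
        ],
    )
    return summaries, comparisons
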