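"""Per-root INDEL/KO scores, group aggregation, the promoter-contrast
Welch test, dominant-indel extraction, pooled spectrum summaries and
transformation-efficiency arithmetic.

The INDEL score of a root is the summed percentage of its significant
indels (editing efficiency); the KO score sums only indels expected to
abolish gene function (frameshifts, or in-frame indels of at least 21 bp).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .core import IndelSpectrum, Thresholds, is_knockout_indel

__all__ = [
    "RootScore",
    "GroupSummary",
    "WelchResult",
    "SpectrumSummary",
    "root_scores",
    "aggregate",
    "welch_test",
    "dominant_indels",
    "spectrum_summary",
    "transformation_efficiency",
]


@dataclass(frozen=True)
class RootScore:
    root_id: str
    indel_score: float
    ko_score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.ko_score <= self.indel_score <= 100.0 + 0.5):
            raise ValueError(
                f"scores out of order for {self.root_id}: "
                f"ko={self.ko_score}, indel={self.indel_score}"
            )


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean_indel: float
    se_indel: float
    mean_ko: float
    se_ko: float
    reportable: bool


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def root_scores(
    spectrum: IndelSpectrum,
    root_id: str = "",
    ko_len: int = Thresholds.ko_len,
) -> RootScore:
    """Scores for one QC-filtered root spectrum: INDEL = sum of all indel
    percentages, KO = sum over likely-null indels only."""
    indel = sum(e.percentage for e in spectrum)
    ko = sum(e.percentage for e in spectrum if is_knockout_indel(e.size, ko_len))
    return RootScore(root_id=root_id, indel_score=indel, ko_score=ko)


def aggregate(
    scores: list[RootScore],
    label: str = "",
    min_roots: int = Thresholds.min_roots,
) -> GroupSummary:
    """Mean and standard error (sample SD / sqrt(n)) of a group's scores.

    Groups below the ``min_roots`` floor are computed but flagged
    non-reportable.
    """
    if not scores:
        raise ValueError(f"empty group {label!r}")
    n = len(scores)
    indel = np.array([s.indel_score for s in scores])
    ko = np.array([s.ko_score for s in scores])
    se = lambda x: float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return GroupSummary(
        label=label,
        n=n,
        mean_indel=float(indel.mean()),
        se_indel=se(indel),
        mean_ko=float(ko.mean()),
        se_ko=se(ko),
        reportable=n >= min_roots,
    )


def welch_test(group_a: list[float], group_b: list[float]) -> WelchResult:
    """Two-sample t-test assuming unequal variances, with the
    Welch-Satterthwaite degrees of freedom and a two-sided p-value."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("at least one group must have nonzero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


def dominant_indels(
    roots: list[IndelSpectrum],
    dominance_pct: float = Thresholds.dominance_pct,
) -> list[tuple[int, str | None]]:
    """Indel keys exceeding the dominance cutoff within at least one root,
    ordered by the maximum observed percentage (descending).

    Dominance is judged per root: one root carrying the indel above the
    cutoff qualifies it for the pooled listing. Keys are (signed size,
    inserted bases or None); decomposed spectra carry size-only keys.
    """
    best: dict[tuple[int, str | None], float] = {}
    for spec in roots:
        for e in spec:
            if e.percentage > dominance_pct:
                best[e.key] = max(best.get(e.key, 0.0), e.percentage)
    return sorted(best, key=lambda k: (-best[k], abs(k[0]), k[0] > 0, k[1] or ""))


@dataclass(frozen=True)
class SpectrumSummary:
    """Pooled mutation spectrum: occurrence count and frequency (%) per
    signed indel size, plus the deletion:insertion event-count ratio
    (None when no insertions were observed)."""

    table: pd.DataFrame
    deletion_insertion_ratio: float | None

    @property
    def ratio_defined(self) -> bool:
        return self.deletion_insertion_ratio is not None


def spectrum_summary(roots: list[IndelSpectrum]) -> SpectrumSummary:
    """Count each indel-event occurrence across roots; frequencies sum to
    100% of events."""
    if not roots:
        raise ValueError("need at least one spectrum")
    counts: dict[int, int] = {}
    for spec in roots:
        for e in spec:
            counts[e.size] = counts.get(e.size, 0) + 1
    total = sum(counts.values())
    rows = [
        {"size": s, "count": c, "frequency_pct": 100.0 * c / total if total else 0.0}
        for s, c in sorted(counts.items())
    ]
    table = pd.DataFrame(rows, columns=["size", "count", "frequency_pct"])
    n_del = sum(c for s, c in counts.items() if s < 0)
    n_ins = sum(c for s, c in counts.items() if s > 0)
    ratio = n_del / n_ins if n_ins > 0 else None
    return SpectrumSummary(table=table, deletion_insertion_ratio=ratio)


def transformation_efficiency(positives: int, total: int) -> float:
    """Percent of explants with transgenic hairy roots, half-up rounded to
    one decimal (e.g. 144/300 -> 48.0)."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not (0 <= positives <= total):
        raise ValueError("positives must be within [0, total]")
    pct = Decimal(100 * positives) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
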