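"""Cohort tabulation: ploidy composition per PN status, FET outcomes, and
group age comparisons.

Percentages are computed by one centralized rule — half-up rounding to one
decimal — which reproduces every printed cohort proportion (e.g. 6/291 ->
2.1, 14/172 -> 8.1). Note the FET table's spontaneous-miscarriage row:
3/74 = 4.054% rounds to 4.1 under any standard rule; this module reports
the computed 4.1.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

FET_OUTCOMES = (
    "negative_bhcg",
    "ongoing_or_live_birth",
    "positive_bhcg",
    "spontaneous_miscarriage",
)

#: classifier output -> coarse ploidy group
PLOIDY_GROUPS: Mapping[str, str] = {
    "haploid": "haploid",
    "23X": "haploid",
    "diploid": "diploid",
    "46XX": "diploid",
    "46XY": "diploid",
    "triploid": "triploid",
    "69XXX": "triploid",
    "69XXY": "triploid",
    "indeterminate": "indeterminate",
}

#: (ploidy group, aneuploidy label) -> joint reporting class
DEFAULT_JOINT_CLASSES: Mapping[Tuple[str, str], str] = {
    ("diploid", "euploid"): "diploid_euploid",
    ("diploid", "aneuploid"): "diploid_aneuploid",
    ("diploid", "unknown"): "diploid",
    ("haploid", "euploid"): "haploid",
    ("haploid", "aneuploid"): "haploid",
    ("haploid", "unknown"): "haploid",
    ("triploid", "euploid"): "triploid",
    ("triploid", "aneuploid"): "triploid_aneuploid",
    ("triploid", "unknown"): "triploid",
    ("indeterminate", "euploid"): "indeterminate",
    ("indeterminate", "aneuploid"): "indeterminate",
    ("indeterminate", "unknown"): "indeterminate",
}


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (2.05 -> 2.1, unlike banker's rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, total: int, ndigits: int = 1) -> float:
    if total == 0:
        raise ZeroDivisionError("percentage of an empty group")
    return round_half_up(100.0 * count / total, ndigits)


@dataclass
class CohortRecord:
    """One biopsy's classification outcome plus clinical metadata."""

    sample_id: str
    pn_status: str  # 0PN / 1PN / 2PN / 3PN
    ploidy_class: str  # classifier output (haploid/diploid/46XX/69XXY/...)
    aneuploidy_label: str = "unknown"  # external PGT-A input
    maternal_age: Optional[float] = None
    paternal_age: Optional[float] = None
    fet_outcome: Optional[str] = None

    def __post_init__(self):
        for age in (self.maternal_age, self.paternal_age):
            if age is not None and age <= 0:
                raise ValueError("ages must be positive when present")


def joint_class(
    ploidy_class: str,
    aneuploidy_label: str,
    mapping: Optional[Mapping[Tuple[str, str], str]] = None,
) -> str:
    mapping = mapping or DEFAULT_JOINT_CLASSES
    group = PLOIDY_GROUPS.get(ploidy_class, ploidy_class)
    try:
        return mapping[(group, aneuploidy_label)]
    except KeyError:
        raise ValueError(
            f"no joint class for ploidy {ploidy_class!r} "
            f"with aneuploidy label {aneuploidy_label!r}"
        ) from None


def tabulate_ploidy(
    records: Sequence[CohortRecord],
    mapping: Optional[Mapping[Tuple[str, str], str]] = None,
) -> pd.DataFrame:
    """Counts and percentages per (pn_status, joint class).

    Percentages are of the PN-status total, half-up rounded to one decimal.
    Empty input yields an empty table.
    """
    rows = []
    if records:
        df = pd.DataFrame(
            {
                "pn_status": [r.pn_status for r in records],
                "joint": [
                    joint_class(r.ploidy_class, r.aneuploidy_label, mapping)
                    for r in records
                ],
            }
        )
        for pn, sub in df.groupby("pn_status", sort=True):
            total = len(sub)
            counts = sub["joint"].value_counts()
            for cls, count in counts.sort_index().items():
                rows.append(
                    {
                        "pn_status": pn,
                        "class": cls,
                        "count": int(count),
                        "total": total,
                        "percent": percent(int(count), total),
                    }
                )
    return pd.DataFrame(rows, columns=["pn_status", "class", "count", "total",
                                       "percent"])


def tabulate_ploidy_counts(
    counts: Mapping[str, Mapping[str, int]]
) -> pd.DataFrame:
    """:func:`tabulate_ploidy` from precomputed ``{pn: {class: count}}``."""
    records = []
    for pn, classes in counts.items():
        for cls, n in classes.items():
            # joint classes pass through PLOIDY_GROUPS untouched for
            # already-merged labels like 'diploid_euploid'
            records.extend(
                CohortRecord(f"{pn}_{cls}_{i}", pn, cls, "unknown")
                for i in range(n)
            )
    mapping = dict(DEFAULT_JOINT_CLASSES)
    for pn, classes in counts.items():
        for cls in classes:
            mapping[(cls, "unknown")] = cls
    return tabulate_ploidy(records, mapping)


def tabulate_fet(records: Sequence[CohortRecord]) -> pd.DataFrame:
    """FET outcome table: overall counts/percentages plus per-PN ``k/n``
    fraction strings, over records with a non-missing outcome."""
    with_outcome = [r for r in records if r.fet_outcome]
    bad = {r.fet_outcome for r in with_outcome} - set(FET_OUTCOMES)
    if bad:
        raise ValueError(f"unknown FET outcomes: {sorted(bad)}")
    total = len(with_outcome)
    pn_statuses = sorted({r.pn_status for r in with_outcome})
    pn_totals = {
        pn: sum(r.pn_status == pn for r in with_outcome) for pn in pn_statuses
    }
    rows = []
    for outcome in FET_OUTCOMES:
        hits = [r for r in with_outcome if r.fet_outcome == outcome]
        row = {
            "fet_outcome": outcome,
            "count": len(hits),
            "percent": percent(len(hits), total) if total else float("nan"),
        }
        for pn in pn_statuses:
            k = sum(r.pn_status == pn for r in hits)
            row[pn] = f"{k}/{pn_totals[pn]}"
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class AgeComparison:
    method: str  # 'ttest' or 'anova'
    statistic: float
    df: Tuple[float, ...]
    pvalue: float


def compare_ages(groups: Sequence[Tuple[str, Sequence[float]]]) -> AgeComparison:
    """Compare group ages: two groups -> two-sided unpaired (pooled-variance)
    Student t-test; more -> one-way ANOVA."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = []
    for label, ages in groups:
        a = np.asarray(list(ages), dtype=float)
        if a.size < 2:
            raise ValueError(f"group {label!r} has n < 2")
        arrays.append(a)
    if len(arrays) == 2:
        t, p = stats.ttest_ind(arrays[0], arrays[1], equal_var=True)
        df = arrays[0].size + arrays[1].size - 2
        return AgeComparison("ttest", float(t), (float(df),), float(p))
    f, p = stats.f_oneway(*arrays)
    k = len(arrays)
    n = sum(a.size for a in arrays)
    return AgeComparison("anova", float(f), (float(k - 1), float(n - k)), float(p))
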