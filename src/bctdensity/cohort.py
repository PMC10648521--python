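"""Cohort-level aggregation of per-breast composition features.

The analysis unit is the breast examination (left and right breasts of one
woman are separate records, as in the source cohort of 1027 breasts from 517
women). Records are grouped into the seven five-year age bins 40-44 ... 70-74;
each bin is summarised by n, mean and sample SD (n-1 denominator) of age and
of the composition features, and bins are compared with a two-sample pooled
Student t-test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .reference import AGE_BINS, AGE_BIN_LABELS

log = logging.getLogger(__name__)

AGE_MIN, AGE_MAX = 40, 74

#: Feature columns a cohort record table is expected to carry (long format);
#: quadrant share columns are optional.
FEATURE_COLUMNS = ("btv", "mgv", "pbd")
QUADRANTS = ("UOQ", "UIQ", "LOQ", "LIQ")


class RunningStats:
    """Single-pass (Welford) mean/variance accumulator.

    Used for streaming feature summaries over large cohorts; agrees with the
    two-pass sample SD to ~1e-9 relative.
    """

    def __init__(self) -> None:
        self.n = 0
        self._mean = 0.0
        self._m2 = 0.0

    def push(self, x: float) -> None:
        self.n += 1
        delta = x - self._mean
        self._mean += delta / self.n
        self._m2 += delta * (x - self._mean)

    @property
    def mean(self) -> float:
        if self.n == 0:
            raise ValueError("no data")
        return self._mean

    @property
    def sd(self) -> float:
        """Sample SD (n-1 denominator); 0.0 for n == 1."""
        if self.n == 0:
            raise ValueError("no data")
        if self.n == 1:
            return 0.0
        return math.sqrt(self._m2 / (self.n - 1))


@dataclass
class AgeGroupSummary:
    """Summary of one five-year age bin."""

    bin_label: str
    n: int
    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)


def _bin_label_for_age(age: int) -> str | None:
    for (lo, hi), label in zip(AGE_BINS, AGE_BIN_LABELS):
        if lo <= age <= hi:
            return label
    return None


def summarize_by_age(records: pd.DataFrame, columns=None) -> list[AgeGroupSummary]:
    """Summarise cohort records by five-year age bin.

    Parameters
    ----------
    records : DataFrame
        One row per breast with an integer ``age`` column plus feature
        columns (by default every numeric column other than ``age``).
    columns : sequence of str, optional
        Explicit subset of feature columns to summarise.

    Returns seven :class:`AgeGroupSummary` in bin order (empty bins have
    n = 0). Records outside 40-74 are excluded and the count is logged —
    never silently dropped.
    """
    if len(records) == 0:
        raise ValueError("empty cohort")
    if "age" not in records.columns:
        raise ValueError("records must have an 'age' column")
    ages = records["age"].to_numpy()
    in_range = (ages >= AGE_MIN) & (ages <= AGE_MAX)
    n_excluded = int((~in_range).sum())
    if n_excluded:
        log.warning("excluded %d record(s) with age outside %d-%d", n_excluded, AGE_MIN, AGE_MAX)
    kept = records.loc[in_range]
    if columns is None:
        columns = [
            c
            for c in kept.columns
            if c != "age" and pd.api.types.is_numeric_dtype(kept[c])
        ]
    columns = ["age", *columns]

    summaries = []
    labels = kept["age"].map(_bin_label_for_age)
    for label in AGE_BIN_LABELS:
        grp = kept.loc[labels == label]
        s = AgeGroupSummary(bin_label=label, n=len(grp))
        for c in columns:
            vals = grp[c].dropna().to_numpy(dtype=float)
            if vals.size:
                s.means[c] = float(vals.mean())
                s.sds[c] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        summaries.append(s)
    return summaries


def summaries_to_frame(summaries: list[AgeGroupSummary]) -> pd.DataFrame:
    """Flatten summaries into a table mirroring published demographics."""
    rows = []
    for s in summaries:
        row = {"bin": s.bin_label, "n": s.n}
        for c, m in s.means.items():
            row[f"{c}_mean"] = m
            row[f"{c}_sd"] = s.sds[c]
        rows.append(row)
    return pd.DataFrame(rows)


def pooled_t_from_stats(mean1, sd1, n1, mean2, sd2, n2) -> tuple[float, float]:
    """Two-sample pooled-variance Student t-test from summary statistics.

    Returns ``(t, two-sided p)`` with ``df = n1 + n2 - 2``. Degenerate
    zero-variance cases: equal means -> (0, 1); unequal -> (±inf, 0).
    """
    n1, n2 = int(n1), int(n2)
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    diff = mean1 - mean2
    if sp2 == 0:
        if diff == 0:
            return 0.0, 1.0
        return math.copysign(math.inf, diff), 0.0
    t = diff / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return float(t), p


def compare_groups(a, b, welch: bool = False) -> tuple[float, float]:
    """Student t-test between two groups of raw values.

    Pooled-variance Student t by default (the convention of the source
    analysis); ``welch=True`` switches to the unequal-variance Welch test.
    Returns ``(t, two-sided p)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 per group")
    if welch:
        t, p = stats.ttest_ind(a, b, equal_var=False)
        return float(t), float(p)
    return pooled_t_from_stats(
        a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
    )


def quadrant_share_table(records: pd.DataFrame, by_age: bool = True) -> pd.DataFrame:
    """Group means/SDs of quadrant shares (and PBD ratios).

    Expects columns ``share_btv_<Q>``, ``share_mgv_<Q>``, ``pbd_ratio_<Q>``
    for Q in UOQ/UIQ/LOQ/LIQ (missing column families are skipped). Records
    whose MGV-share columns are all-NaN (zero whole-breast MGV upstream) are
    excluded from MGV-share averaging with a logged count.

    ``by_age=False`` collapses to a single all-ages row.
    """
    share_cols = [c for c in records.columns if c.startswith(("share_", "pbd_ratio_"))]
    if not share_cols:
        raise ValueError("records carry no quadrant share columns")
    mgv_cols = [c for c in share_cols if c.startswith("share_mgv_")]
    if mgv_cols:
        n_missing = int(records[mgv_cols].isna().all(axis=1).sum())
        if n_missing:
            log.warning(
                "excluded %d record(s) with undefined MGV shares from MGV-share averaging",
                n_missing,
            )
    work = records.copy()
    if by_age:
        work["bin"] = work["age"].map(_bin_label_for_age)
        work = work.dropna(subset=["bin"])
        grouped = work.groupby("bin", sort=False)
    else:
        work["bin"] = "all"
        grouped = work.groupby("bin")
    agg = grouped[share_cols].agg(["mean", lambda v: v.std(ddof=1)])
    agg.columns = [f"{col}_{'sd' if fn == '<lambda_0>' else fn}" for col, fn in agg.columns]
    agg.insert(0, "n", grouped.size())
    if by_age:
        agg = agg.reindex([b for b in AGE_BIN_LABELS if b in agg.index])
    return agg.reset_index()
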