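"""Ordinal tumour grading and small-sample statistics.

Implements the endoscopic 0-5 visual grading scale (grade by fraction of the
colonic circumference covered), an exact Mann-Whitney U test suited to tiny,
heavily tied ordinal samples, per-day group comparisons, Pearson correlation
with its t-based p-value, implantation success-rate summaries, and a
median-based tumour growth-delay estimate.

Sidedness note: group comparisons default to the one-sided alternative
"irradiated grades are lower than control grades", the direction the therapy
is expected to act in; the two-sided test is available throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GRADE_SERIES_COLUMNS",
    "GradeSeries",
    "MethodOutcomeTable",
    "MannWhitneyResult",
    "PearsonResult",
    "DelayEstimate",
    "grade_from_fraction",
    "exact_mann_whitney",
    "daily_group_comparison",
    "pearson_with_p",
    "implantation_summary",
    "growth_delay_estimate",
]

GRADE_SERIES_COLUMNS = ["mouse_id", "group", "day", "grade",
                        "fluorescence_detected"]
GROUPS = ("control", "irradiated")


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GradeSeries:
    """Per-mouse ordinal grade records, one row per mouse per day."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in GRADE_SERIES_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"grade table missing columns: {missing}")
        if not df["group"].isin(GROUPS).all():
            bad = sorted(set(df["group"]) - set(GROUPS))
            raise ValueError(f"unknown group labels: {bad}")
        if ((df["day"] < 0) | (df["day"] != df["day"].astype(int))).any():
            raise ValueError("day must be a non-negative integer")
        if (~df["grade"].isin(range(6))).any():
            raise ValueError("grade must be an integer in 0..5")
        zero = df["grade"] == 0
        if (~df.loc[zero, "fluorescence_detected"].astype(bool)).any():
            raise ValueError("grade 0 requires fluorescence_detected = True")
        if df.duplicated(subset=["mouse_id", "day"]).any():
            raise ValueError("one record per mouse per day required")
        for mouse, sub in df.groupby("mouse_id"):
            days = np.sort(sub["day"].to_numpy())
            if days.size and days[-1] - days[0] + 1 != days.size:
                raise ValueError(
                    f"mouse {mouse!r}: observed days are not contiguous")
        object.__setattr__(self, "df", df.reset_index(drop=True))

    @classmethod
    def from_records(cls, records) -> "GradeSeries":
        return cls(pd.DataFrame.from_records(
            records, columns=GRADE_SERIES_COLUMNS))

    @property
    def days(self) -> np.ndarray:
        return np.sort(self.df["day"].unique())

    def grades_on(self, day: int, group: str) -> np.ndarray:
        sel = (self.df["day"] == day) & (self.df["group"] == group)
        return self.df.loc[sel, "grade"].to_numpy()


@dataclass(frozen=True)
class MethodOutcomeTable:
    """Per implantation method: success count, total mice, last follow-up."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        required = ["method", "successes", "total", "last_follow_up_days"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"outcome table missing columns: {missing}")
        if (df["total"] <= 0).any():
            raise ValueError("total must be > 0 for every method")
        if ((df["successes"] < 0) | (df["successes"] > df["total"])).any():
            raise ValueError("successes must satisfy 0 <= successes <= total")
        object.__setattr__(self, "df", df.reset_index(drop=True))


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float        # mid-rank U statistic for the first sample
    p: float
    exact: bool = True


@dataclass(frozen=True)
class PearsonResult:
    r: float
    p: float
    r_squared: float


@dataclass(frozen=True)
class DelayEstimate:
    delay_days: float
    threshold_grade: int
    n_censored_control: int
    n_censored_irradiated: int
    group_fully_censored: bool
    first_days: pd.DataFrame     # per-mouse first day at/over threshold


# ---------------------------------------------------------------------------
# Grading scale
# ---------------------------------------------------------------------------

def grade_from_fraction(circumference_fraction: float,
                        detectable_white_light: bool,
                        fluorescence_detected: bool, *,
                        grade1_max_fraction: float = 0.02) -> int:
    """Map a covered circumference fraction to the 0-5 endoscopic grade.

    Grade 0: invisible under white light but fluorescent.  Grades 1-5 use
    inclusive "up to" boundaries: grade1_max_fraction (very small but
    detectable), 1/8, 1/4, 1/2, and above 1/2.
    """
    f = float(circumference_fraction)
    if not 0.0 <= f <= 1.0:
        raise ValueError("circumference fraction must lie in [0, 1]")
    if not detectable_white_light:
        if not fluorescence_detected:
            raise ValueError(
                "no tumour: neither white-light detectable nor fluorescent")
        return 0
    if f <= grade1_max_fraction:
        return 1
    if f <= 0.125:
        return 2
    if f <= 0.25:
        return 3
    if f <= 0.5:
        return 4
    return 5


# ---------------------------------------------------------------------------
# Exact Mann-Whitney U
# ---------------------------------------------------------------------------

def _midrank_u(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x: pairwise wins plus half-ties (equals R_x - n1(n1+1)/2)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    return float(ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0)


def _exact_null_counts(ranks2: np.ndarray, n1: int) -> np.ndarray:
    """Number of labelings per doubled rank-sum, by generating-function DP.

    ``ranks2`` are doubled mid-ranks (integers even under ties), so the whole
    computation is exact integer arithmetic.
    """
    total = int(ranks2.sum())
    # object dtype keeps Python integers exact; the table is tiny (n <= 25)
    counts = np.zeros((n1 + 1, total + 1), dtype=object)
    counts[0, 0] = 1
    for r in ranks2:
        r = int(r)
        for c in range(n1, 0, -1):
            counts[c, r:] = counts[c, r:] + counts[c - 1, : total + 1 - r]
    return counts[n1]


def exact_mann_whitney(x, y, alternative: str = "two-sided", *,
                       max_exact_n: int = 25, n_resamples: int = 200_000,
                       seed: int = 0) -> MannWhitneyResult:
    """Exact Mann-Whitney U test by complete enumeration of group labelings.

    Ties are handled naturally: the permutation null is built on the observed
    pooled values with mid-rank U contributions (1/2 per tied pair).  For
    pooled sizes above ``max_exact_n`` a seeded Monte-Carlo permutation
    p-value is returned instead (``exact=False``).

    ``alternative`` refers to the first sample: "less" tests whether x tends
    to be smaller than y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("less", "greater", "two-sided"):
        raise ValueError("alternative must be less, greater or two-sided")
    n1, n2 = x.size, y.size
    u_obs = _midrank_u(x, y)

    if n1 + n2 <= max_exact_n:
        pooled = np.concatenate([x, y])
        ranks2 = np.rint(2.0 * sps.rankdata(pooled)).astype(int)
        counts = _exact_null_counts(ranks2, n1)
        # doubled U for each doubled rank sum s: u2 = s - n1 (n1 + 1)
        u2 = np.arange(counts.size) - n1 * (n1 + 1)
        u2_obs = int(round(2.0 * u_obs))
        n_total = comb(n1 + n2, n1)
        mask = {
            "less": u2 <= u2_obs,
            "greater": u2 >= u2_obs,
            "two-sided": np.abs(u2 - n1 * n2) >= abs(u2_obs - n1 * n2),
        }[alternative]
        p = Fraction(int(sum(counts[mask])), n_total)
        return MannWhitneyResult(U=u_obs, p=float(min(p, Fraction(1))),
                                 exact=True)

    rng = np.random.default_rng(seed)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    mu = n1 * n2 / 2.0
    hits = 0
    for _ in range(n_resamples):
        perm = rng.permutation(ranks.size)[:n1]
        u = ranks[perm].sum() - n1 * (n1 + 1) / 2.0
        if alternative == "less":
            hits += u <= u_obs
        elif alternative == "greater":
            hits += u >= u_obs
        else:
            hits += abs(u - mu) >= abs(u_obs - mu) - 1e-12
    p = (hits + 1) / (n_resamples + 1)
    return MannWhitneyResult(U=u_obs, p=float(min(p, 1.0)), exact=False)


def daily_group_comparison(series: GradeSeries,
                           alternative: str = "less") -> pd.DataFrame:
    """Per-day exact Mann-Whitney comparison of irradiated vs control grades.

    Days on which a group is missing are reported with ``comparable = False``
    (U and p are NaN), never silently dropped.  ``alternative`` applies to the
    irradiated sample ("less": irradiated grades lower than control).
    """
    rows = []
    for day in series.days:
        treated = series.grades_on(day, "irradiated")
        control = series.grades_on(day, "control")
        if treated.size == 0 or control.size == 0:
            rows.append(dict(day=int(day), n_control=control.size,
                             n_irradiated=treated.size, U=np.nan, p=np.nan,
                             comparable=False))
            continue
        res = exact_mann_whitney(treated, control, alternative)
        rows.append(dict(day=int(day), n_control=control.size,
                         n_irradiated=treated.size, U=res.U, p=res.p,
                         comparable=True))
    if not any(r["comparable"] for r in rows):
        raise ValueError("no day has both groups represented")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Correlation, success rates, growth delay
# ---------------------------------------------------------------------------

def pearson_with_p(x, y) -> PearsonResult:
    """Sample Pearson r with the two-sided t-transform p (n - 2 dof)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the samples")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return PearsonResult(r=r, p=float(res.pvalue), r_squared=r * r)


def _round_half_up_1dp(value: Fraction) -> float:
    return float((value * 10 + Fraction(1, 2)).__floor__()) / 10.0


def implantation_summary(table: MethodOutcomeTable) -> pd.DataFrame:
    """Success percentage per method, rounded half-up to one decimal."""
    df = table.df.copy()
    df["success_pct"] = [
        _round_half_up_1dp(Fraction(100 * int(s), int(t)))
        for s, t in zip(df["successes"], df["total"])
    ]
    return df[["method", "successes", "total", "success_pct",
               "last_follow_up_days"]]


def growth_delay_estimate(series: GradeSeries, *,
                          threshold_grade: int = 3) -> DelayEstimate:
    """Median difference in the first day each group reaches the threshold.

    Mice that never reach the threshold are right-censored: they enter the
    median at last observed day + 1 and are flagged.  If an entire group is
    censored the returned estimate carries ``group_fully_censored = True``
    rather than being a bare number.
    """
    df = series.df
    if df[df["group"] == "control"].empty or \
            df[df["group"] == "irradiated"].empty:
        raise ValueError("both groups must be present")
    rows = []
    for (mouse, group), sub in df.groupby(["mouse_id", "group"]):
        hit = sub.loc[sub["grade"] >= threshold_grade, "day"]
        if hit.empty:
            rows.append(dict(mouse_id=mouse, group=group,
                             first_day=int(sub["day"].max()) + 1,
                             censored=True))
        else:
            rows.append(dict(mouse_id=mouse, group=group,
                             first_day=int(hit.min()), censored=False))
    per_mouse = pd.DataFrame(rows)
    med = per_mouse.groupby("group")["first_day"].median()
    cens = per_mouse.groupby("group")["censored"]
    fully = bool(cens.all().any())
    return DelayEstimate(
        delay_days=float(med["irradiated"] - med["control"]),
        threshold_grade=threshold_grade,
        n_censored_control=int(cens.sum()["control"]),
        n_censored_irradiated=int(cens.sum()["irradiated"]),
        group_fully_censored=fully,
        first_days=per_mouse,
    )
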