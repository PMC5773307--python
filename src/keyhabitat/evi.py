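"""Vegetation-index (EVI) time-series analysis.

Quality-filters 16-day composite series, locates the single most likely
change point in mean and variance under a two-segment Gaussian likelihood,
contrasts prior/current segment means, and computes post-change phenology
(per-period multi-year medians, 23 periods per year).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

QA_HIGH, QA_MEDIAN, QA_POOR = 0, 1, 2
QA_NAMES = {QA_HIGH: "high", QA_MEDIAN: "median", QA_POOR: "poor"}
QA_CODES = {v: k for k, v in QA_NAMES.items()}

N_PERIODS = 23
VAR_FLOOR = 1e-12


def period_of_year(dates: np.ndarray | pd.DatetimeIndex) -> np.ndarray:
    """16-day period index in 1..23: ``min(floor(doy/16) + 1, 23)``."""
    doy = pd.DatetimeIndex(dates).dayofyear.to_numpy()
    return np.minimum(doy // 16 + 1, N_PERIODS)


def composite_dates(start: str, end: str) -> pd.DatetimeIndex:
    """All 16-day composite dates (day-of-year 1, 17, ..., 353) in
    [start, end]. Spacing is 16 days except at the year boundary, where the
    lattice restarts on 1 January."""
    start_ts, end_ts = pd.Timestamp(start), pd.Timestamp(end)
    dates = []
    for year in range(start_ts.year, end_ts.year + 1):
        base = pd.Timestamp(year=year, month=1, day=1)
        dates.extend(base + pd.Timedelta(days=16 * k) for k in range(23))
    idx = pd.DatetimeIndex(dates)
    return idx[(idx >= start_ts) & (idx <= end_ts)]


@dataclass
class EviSeries:
    """One location's dated EVI observations with QA ranks."""

    dates: pd.DatetimeIndex
    values: np.ndarray
    qa: np.ndarray
    location_id: int | str = 0

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.values = np.asarray(self.values, dtype=float)
        qa = np.asarray(self.qa)
        if qa.dtype.kind in "US":
            qa = np.array([QA_CODES[str(q)] for q in qa])
        self.qa = qa.astype(int)
        if not (len(self.dates) == len(self.values) == len(self.qa)):
            raise ValueError("dates, values, qa must have equal length")
        if len(self.values) and (
                (self.values < 0).any() or (self.values > 1).any()):
            raise ValueError("EVI values must lie in [0, 1]")
        if not np.isin(self.qa, (QA_HIGH, QA_MEDIAN, QA_POOR)).all():
            raise ValueError("qa ranks must be high/median/poor")

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "location_id": self.location_id,
            "date": self.dates.strftime("%Y-%m-%d"),
            "evi": self.values,
            "qa_rank": [QA_NAMES[q] for q in self.qa],
        })


def series_from_frame(df: pd.DataFrame) -> list[EviSeries]:
    """Parse a long-format table (location_id, date, evi, qa_rank)."""
    out = []
    for loc, grp in df.groupby("location_id", sort=True):
        grp = grp.sort_values("date")
        out.append(EviSeries(pd.to_datetime(grp["date"]),
                             grp["evi"].to_numpy(),
                             grp["qa_rank"].to_numpy(), loc))
    return out


# ---------------------------------------------------------------------------
# QA filtering

def filter_by_qa(series: EviSeries) -> EviSeries:
    """Per composite date, keep the best available QA rank and average its
    observations; poor-quality observations are used only when nothing
    better exists at that date."""
    if len(series) == 0:
        raise ValueError("empty EVI series")
    df = pd.DataFrame({"date": series.dates, "evi": series.values,
                       "qa": series.qa})
    best = df.groupby("date")["qa"].transform("min")
    kept = df[df["qa"] == best]
    agg = kept.groupby("date").agg(evi=("evi", "mean"), qa=("qa", "first"))
    agg = agg.sort_index()
    return EviSeries(agg.index, agg["evi"].to_numpy(), agg["qa"].to_numpy(),
                     series.location_id)


# ---------------------------------------------------------------------------
# change point in mean and variance

@dataclass
class ChangePointResult:
    tau: int | None
    prior_mean: float
    current_mean: float
    prior_var: float
    current_var: float
    test_statistic: float
    significant: bool
    penalty: float
    location_id: int | str = 0


def _seg_loglik_terms(values: np.ndarray, min_seg: int
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """MLE mean/variance of every admissible (left, right) split, vectorized
    via cumulative sums. tau indexes the last observation of the left
    segment (0-based)."""
    n = len(values)
    cs = np.cumsum(values)
    cs2 = np.cumsum(values**2)
    taus = np.arange(min_seg - 1, n - min_seg)
    m1 = taus + 1.0
    m2 = n - m1
    s1, s2 = cs[taus], cs[-1] - cs[taus]
    q1, q2 = cs2[taus], cs2[-1] - cs2[taus]
    mu1, mu2 = s1 / m1, s2 / m2
    v1 = np.maximum(q1 / m1 - mu1**2, VAR_FLOOR)
    v2 = np.maximum(q2 / m2 - mu2**2, VAR_FLOOR)
    return taus, np.column_stack([mu1, mu2]), np.column_stack([v1, v2]), \
        np.column_stack([m1, m2])


def changepoint_penalty(rule: str | float, n: int, p_extra: int = 3) -> float:
    """Significance penalty for the likelihood-ratio statistic. Default
    MBIC-style ``(p_extra + 1) * log n`` (a change adds one mean, one
    variance and one location parameter)."""
    if isinstance(rule, (int, float)):
        return float(rule)
    if rule == "mbic":
        return (p_extra + 1) * np.log(n)
    if rule == "bic":
        return p_extra * np.log(n)
    raise ValueError(f"unknown penalty rule {rule!r}")


def detect_changepoint(
    series: EviSeries | np.ndarray,
    min_seg: int = 4,
    penalty: str | float = "mbic",
) -> ChangePointResult:
    """At-most-one-change detector for a shift in mean and variance.

    For each admissible split after index tau the statistic is
    ``2*(l1 + l2 - l0)`` with segmentwise Gaussian MLEs; the argmax split is
    significant iff the statistic exceeds the penalty. Zero segment
    variances are floored at 1e-12 (with a warning).
    """
    loc = getattr(series, "location_id", 0)
    values = series.values if isinstance(series, EviSeries) else \
        np.asarray(series, dtype=float)
    n = len(values)
    if n < 2 * min_seg:
        raise ValueError(f"series of length {n} shorter than 2*min_seg")
    mu0 = values.mean()
    v0_raw = values.var()
    if v0_raw < VAR_FLOOR or np.var(values) == 0:
        warnings.warn("segment variance floored at 1e-12", stacklevel=2)
    v0 = max(v0_raw, VAR_FLOOR)
    taus, mus, vs, ms = _seg_loglik_terms(values, min_seg)
    if (vs <= VAR_FLOOR).any():
        warnings.warn("segment variance floored at 1e-12", stacklevel=2)
    # 2*(l1+l2-l0) = n log v0 - m1 log v1 - m2 log v2 for Gaussian MLEs
    stat_all = n * np.log(v0) - (ms * np.log(vs)).sum(axis=1)
    i = int(np.argmax(stat_all))
    stat = float(stat_all[i])
    pen = changepoint_penalty(penalty, n)
    if stat > pen:
        tau = int(taus[i])
        return ChangePointResult(
            tau=tau, prior_mean=float(mus[i, 0]), current_mean=float(mus[i, 1]),
            prior_var=float(vs[i, 0]), current_var=float(vs[i, 1]),
            test_statistic=stat, significant=True, penalty=pen,
            location_id=loc)
    return ChangePointResult(
        tau=None, prior_mean=float(mu0), current_mean=float(mu0),
        prior_var=float(v0), current_var=float(v0),
        test_statistic=stat, significant=False, penalty=pen, location_id=loc)


# ---------------------------------------------------------------------------
# phenology

@dataclass
class Phenology:
    """23 per-period medians of post-change observations; NaN marks a period
    with no post-change data."""

    values: np.ndarray
    location_id: int | str = 0
    n_missing: int = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_PERIODS,):
            raise ValueError(f"phenology must have {N_PERIODS} values")
        self.n_missing = int(np.isnan(self.values).sum())


def phenology(series: EviSeries, cp: ChangePointResult | None = None
              ) -> Phenology:
    """Median EVI per 16-day period over the post-change ("current")
    observations; all observations when no change point is given or the
    change is not significant."""
    start = 0
    if cp is not None and cp.tau is not None:
        start = cp.tau + 1
    dates = series.dates[start:]
    vals = series.values[start:]
    periods = period_of_year(dates)
    out = np.full(N_PERIODS, np.nan)
    for p in range(1, N_PERIODS + 1):
        sel = periods == p
        if sel.any():
            out[p - 1] = np.median(vals[sel])
    ph = Phenology(out, series.location_id)
    if ph.n_missing:
        log.warning("location %s: %d of %d phenology periods missing",
                    series.location_id, ph.n_missing, N_PERIODS)
    return ph


def phenology_matrix(phenologies: list[Phenology]) -> pd.DataFrame:
    """Rows = locations, 23 period columns."""
    return pd.DataFrame(
        [p.values for p in phenologies],
        index=[p.location_id for p in phenologies],
        columns=[f"p{i:02d}" for i in range(1, N_PERIODS + 1)])


# ---------------------------------------------------------------------------
# degradation summary

@dataclass
class DegradationSummary:
    reduced: pd.Series
    pct_reduced: float
    contingency: pd.DataFrame
    chi2: float
    df: int
    p_value: float


def summarize_degradation(results: list[ChangePointResult],
                          labels: list[str] | pd.Series) -> DegradationSummary:
    """Flag each location as 'reduced' iff its change point is significant
    with a lower current mean; report overall percent reduced and the
    Pearson chi-square of reduced x category (df = n_categories - 1)."""
    if len(results) != len(labels):
        raise ValueError("results and labels must align one-to-one")
    labels = pd.Series(list(labels), index=[r.location_id for r in results])
    reduced = pd.Series(
        [r.significant and r.current_mean < r.prior_mean for r in results],
        index=labels.index)
    pct = 100.0 * reduced.mean()
    cats = sorted(labels.unique())
    table = pd.crosstab(reduced, labels).reindex(
        index=[False, True], columns=cats, fill_value=0)
    nonzero_rows = (table.sum(axis=1) > 0).sum()
    if nonzero_rows < 2 or len(cats) < 2:
        return DegradationSummary(reduced, pct, table,
                                  float("nan"), len(cats) - 1, float("nan"))
    chi2, p, df, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return DegradationSummary(reduced, pct, table, float(chi2), int(df),
                              float(p))
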