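"""Kaplan-Meier estimation, two-group log-rank testing, and the median-split
survival screen that selects tumor-suppressor candidates.

The product-limit estimator and the log-rank statistic are implemented
directly (S(t) = prod(1 - d_i/n_i); (O-E)^2/V with hypergeometric variance)
so they can be checked against independent library implementations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataFormatError, DegenerateStatisticsError


@dataclass
class KMCurve:
    """Product-limit survival estimate over the distinct observed times."""

    times: np.ndarray  # distinct observed times, ascending
    at_risk: np.ndarray  # n_i just before each time
    events: np.ndarray  # d_i events at each time
    survival: np.ndarray  # S(t_i)

    def at(self, t: float) -> float:
        """Step-function value S(t) (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.survival[idx])


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier estimate from follow-up times and event indicators.

    Censored-only times reduce the risk set but leave S unchanged.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise DataFormatError("empty survival input")
    if (times <= 0).any():
        raise DataFormatError("follow-up times must be positive")
    if not np.isin(events, [0, 1]).all():
        raise DataFormatError("event indicators must be 0/1")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    uniq, idx = np.unique(times, return_index=True)
    d = np.add.reduceat(events, idx)  # events at each distinct time
    c = np.add.reduceat(1 - events, idx)  # censorings at each distinct time
    removed = d + c
    n_at_risk = times.size - np.concatenate(([0], np.cumsum(removed)[:-1]))
    with np.errstate(invalid="ignore"):
        surv = np.cumprod(1.0 - d / n_at_risk)
    return KMCurve(times=uniq, at_risk=n_at_risk, events=d, survival=surv)


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (statistic, p) with chi-square df=1.

    Statistic is (O_A - E_A)^2 / V summed over distinct event times, with
    the hypergeometric variance at each time.
    """
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    eb = np.asarray(events_b, dtype=int)
    if ta.size == 0 or tb.size == 0:
        raise DataFormatError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise DegenerateStatisticsError("log-rank undefined with no events")

    all_t = np.concatenate([ta, tb])
    all_e = np.concatenate([ea, eb])

    event_times = np.unique(all_t[all_e == 1])
    sa, sb = np.sort(ta), np.sort(tb)
    n_a = ta.size - np.searchsorted(sa, event_times, side="left")
    n_b = tb.size - np.searchsorted(sb, event_times, side="left")
    n = n_a + n_b
    ea_t = np.sort(ta[ea == 1])
    all_e_t = np.sort(all_t[all_e == 1])
    d_a = np.searchsorted(ea_t, event_times, side="right") - np.searchsorted(
        ea_t, event_times, side="left"
    )
    d = np.searchsorted(all_e_t, event_times, side="right") - np.searchsorted(
        all_e_t, event_times, side="left"
    )
    ok = n > 1
    n_a, n, d, d_a = n_a[ok], n[ok], d[ok], d_a[ok]
    frac_a = n_a / n
    o_minus_e = float((d_a - d * frac_a).sum())
    var = float((d * frac_a * (1 - frac_a) * (n - d) / (n - 1)).sum())
    if var == 0:
        raise DegenerateStatisticsError("log-rank variance is zero")
    statistic = o_minus_e**2 / var
    p = float(stats.chi2.sf(statistic, 1))
    return float(statistic), p


def median_split(expression: np.ndarray) -> np.ndarray:
    """Boolean low-group mask: expression <= median (ties go low)."""
    expression = np.asarray(expression, dtype=float)
    low = expression <= np.median(expression)
    if low.all() or not low.any():
        raise DegenerateStatisticsError("median split is degenerate (constant expression)")
    return low


def screen_genes(
    survival: pd.DataFrame, gene_list: list[str], alpha: float = 0.05
) -> pd.DataFrame:
    """Median-split log-rank screen of *gene_list* against overall survival.

    *survival* is the standard table (sample_id, time_days, event, one
    column per gene). Per gene: split samples at median expression (ties to
    the low group), log-rank the two groups, flag ``selected`` when
    p < alpha (strict), and call the risk direction from the KM curves at
    the largest time common to both groups. Genes whose split or test is
    degenerate are reported with an ``error`` and not selected.
    """
    missing = [g for g in gene_list if g not in survival.columns]
    if missing:
        raise DataFormatError(f"gene(s) absent from survival table: {missing[:5]}")
    times = survival["time_days"].to_numpy(dtype=float)
    events = survival["event"].to_numpy(dtype=int)
    rows = []
    for gene in gene_list:
        expr = survival[gene].to_numpy(dtype=float)
        row: dict = {"gene_id": gene, "median_expression": float(np.median(expr))}
        try:
            low = median_split(expr)
            stat, p = logrank_test(times[low], events[low], times[~low], events[~low])
            km_low = km_estimate(times[low], events[low])
            km_high = km_estimate(times[~low], events[~low])
            t_common = min(times[low].max(), times[~low].max())
            s_low, s_high = km_low.at(t_common), km_high.at(t_common)
            if s_low < s_high:
                direction = "low_expression_worse"
            elif s_high < s_low:
                direction = "high_expression_worse"
            else:
                direction = "none"
            row.update(
                n_low=int(low.sum()),
                n_high=int((~low).sum()),
                statistic=stat,
                p=p,
                direction_of_risk=direction,
                selected=bool(p < alpha),
                error="",
            )
        except DegenerateStatisticsError as exc:
            row.update(
                n_low=0,
                n_high=0,
                statistic=np.nan,
                p=np.nan,
                direction_of_risk="none",
                selected=False,
                error=str(exc),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def select_tsg_candidates(
    screen_results: pd.DataFrame, de_results: pd.DataFrame
) -> list[str]:
    """Tumor-suppressor candidates: survival-selected genes that are
    down-regulated in tumor and whose low expression carries the worse
    prognosis."""
    de_dir = pd.Series(
        de_results["de_direction"].to_numpy(), index=de_results["gene_id"].to_numpy()
    )
    out = []
    for row in screen_results.itertuples():
        if not row.selected:
            continue
        if de_dir.get(row.gene_id) != "down":
            continue
        if row.direction_of_risk != "low_expression_worse":
            continue
        out.append(row.gene_id)
    return out
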