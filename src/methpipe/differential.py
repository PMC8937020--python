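"""Differential methylation-site calling on paired tumor/normal score tables.

A site is called *up* (tumor relative to normal) when the tumor score exceeds
the normal score by strictly more than ``fold_threshold`` (default 2), and
*down* symmetrically. When exactly one of the two aggregated scores is zero,
the site is rescued as differential only if the nonzero score strictly
exceeds ``zero_rescue_threshold`` (default 0.6). Sites scoring zero in every
sample are dropped before calling. All thresholds are strict inequalities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, MethpipeError
from .io_formats import DIFF_SITE_COLUMNS, SiteScoreTable, sort_genomic

logger = logging.getLogger(__name__)

#: supported multi-pair aggregation policies
AGGREGATION_POLICIES = ("mean_by_condition", "per_pair_consensus")

DEFAULT_FOLD = 2.0
DEFAULT_ZERO_RESCUE = 0.6


@dataclass(frozen=True)
class SiteCall:
    direction: str | None  # "up", "down" or None
    rule: str | None  # "fold_change", "zero_rescue" or None


def drop_all_zero_sites(table: SiteScoreTable) -> SiteScoreTable:
    """Remove sites whose score is zero in every sample."""
    if len(table) == 0:
        return table
    keep = (table.scores() != 0).any(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d all-zero %s sites", dropped, table.mark)
    return SiteScoreTable(
        mark=table.mark,
        data=table.data.loc[keep].reset_index(drop=True),
        samples=table.samples,
    )


def aggregate_scores(table: SiteScoreTable) -> tuple[np.ndarray, np.ndarray]:
    """Per-site mean score over the samples of each condition.

    Returns ``(tumor_score, normal_score)`` arrays.
    """
    tumor = table.samples_for("tumor")
    normal = table.samples_for("normal")
    if not tumor or not normal:
        raise ConfigurationError("aggregation requires >=1 sample per condition")
    t = table.data[tumor].to_numpy(dtype=float).mean(axis=1)
    n = table.data[normal].to_numpy(dtype=float).mean(axis=1)
    return t, n


def call_site(
    tumor_score: float,
    normal_score: float,
    fold_threshold: float = DEFAULT_FOLD,
    zero_rescue_threshold: float = DEFAULT_ZERO_RESCUE,
) -> SiteCall:
    """Call a single site from its two aggregated scores.

    Both-positive scores go through the strict fold-change rule; an exact
    zero on one side goes through the strict zero-rescue rule; a double zero
    is never differential.
    """
    if not (0 <= tumor_score <= 1 and 0 <= normal_score <= 1):
        raise MethpipeError(
            f"scores must lie in [0,1], got ({tumor_score}, {normal_score})"
        )
    if tumor_score > 0 and normal_score > 0:
        if tumor_score / normal_score > fold_threshold:
            return SiteCall("up", "fold_change")
        if normal_score / tumor_score > fold_threshold:
            return SiteCall("down", "fold_change")
        return SiteCall(None, "fold_change")
    if tumor_score == 0 and normal_score == 0:
        return SiteCall(None, None)
    nonzero = tumor_score if normal_score == 0 else normal_score
    if nonzero > zero_rescue_threshold:
        return SiteCall("up" if normal_score == 0 else "down", "zero_rescue")
    return SiteCall(None, "zero_rescue")


def _call_vectorized(
    t: np.ndarray, n: np.ndarray, fold: float, zero: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized version of :func:`call_site` over aggregated score arrays."""
    direction = np.full(t.shape, "", dtype=object)
    rule = np.full(t.shape, "", dtype=object)

    both = (t > 0) & (n > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        up = both & (t / np.where(n > 0, n, 1) > fold)
        down = both & (n / np.where(t > 0, t, 1) > fold)
    direction[up] = "up"
    direction[down] = "down"
    rule[up | down] = "fold_change"

    one_zero = (t == 0) ^ (n == 0)
    rescue_up = one_zero & (n == 0) & (t > zero)
    rescue_down = one_zero & (t == 0) & (n > zero)
    direction[rescue_up] = "up"
    direction[rescue_down] = "down"
    rule[rescue_up | rescue_down] = "zero_rescue"
    return direction, rule


def call_differential_sites(
    table: SiteScoreTable,
    policy: str = "mean_by_condition",
    fold_threshold: float = DEFAULT_FOLD,
    zero_rescue_threshold: float = DEFAULT_ZERO_RESCUE,
) -> pd.DataFrame:
    """Call differential sites for one mark.

    ``mean_by_condition`` applies the rules to condition-mean scores.
    ``per_pair_consensus`` applies them within every tumor/normal pair and
    reports a site only when all pairs agree on the same direction; reported
    scores are still the condition means.

    Returns a DataFrame with columns chrom, pos0, end, mark, direction,
    tumor_score, normal_score, rule, sorted genomically.
    """
    if policy not in AGGREGATION_POLICIES:
        raise ConfigurationError(
            f"unknown aggregation policy {policy!r}; expected one of {AGGREGATION_POLICIES}"
        )
    table = drop_all_zero_sites(table)
    if len(table) == 0:
        return pd.DataFrame(columns=DIFF_SITE_COLUMNS)

    t_mean, n_mean = aggregate_scores(table)

    if policy == "mean_by_condition":
        direction, rule = _call_vectorized(
            t_mean, n_mean, fold_threshold, zero_rescue_threshold
        )
    else:
        pairs: dict[str, dict[str, str]] = {}
        for sample, (pair, cond) in table.samples.items():
            pairs.setdefault(pair, {})[cond] = sample
        incomplete = [p for p, d in pairs.items() if set(d) != set(("tumor", "normal"))]
        if incomplete:
            raise ConfigurationError(
                f"per_pair_consensus requires complete tumor/normal pairs; incomplete: {incomplete}"
            )
        per_pair = []
        for pair, d in sorted(pairs.items()):
            t = table.data[d["tumor"]].to_numpy(dtype=float)
            n = table.data[d["normal"]].to_numpy(dtype=float)
            per_pair.append(_call_vectorized(t, n, fold_threshold, zero_rescue_threshold)[0])
        stacked = np.stack(per_pair)
        agree_up = (stacked == "up").all(axis=0)
        agree_down = (stacked == "down").all(axis=0)
        direction = np.full(len(table), "", dtype=object)
        direction[agree_up] = "up"
        direction[agree_down] = "down"
        # rule recorded from the zero pattern of the reported (mean) scores
        rule = np.where((t_mean == 0) ^ (n_mean == 0), "zero_rescue", "fold_change")
        rule = rule.astype(object)

    called = direction != ""
    out = pd.DataFrame(
        {
            "chrom": table.data["chrom"].to_numpy()[called],
            "pos0": table.data["pos0"].to_numpy()[called],
            "end": table.data["pos0"].to_numpy()[called] + 1,
            "mark": table.mark,
            "direction": direction[called],
            "tumor_score": t_mean[called],
            "normal_score": n_mean[called],
            "rule": rule[called],
        }
    )
    if len(out):
        out = sort_genomic(out, extra=["mark"])
    for (mark, d), cnt in out.groupby(["mark", "direction"]).size().items():
        logger.info("called %d %s %s sites", cnt, mark, d)
    return out
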