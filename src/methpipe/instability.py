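"""Gene-level methylation-instability statistics.

Classifies genes by which direction x mark site categories they carry,
computes the dual-mark "unstable" set (all four categories non-empty), the
4-set Venn region counts, biotype composition against the genome background,
per-mark Pearson correlation of up/down site counts, and the ranked top-N
unstable gene list.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataFormatError, DegenerateStatisticsError

FLAG_COLUMNS = ["has_5mC_up", "has_5mC_down", "has_6mA_up", "has_6mA_down"]

_FLAG_SOURCE = {
    "has_5mC_up": "n_up_5mC",
    "has_5mC_down": "n_down_5mC",
    "has_6mA_up": "n_up_6mA",
    "has_6mA_down": "n_down_6mA",
}

RANKING_KEYS = ("total", "total_5mC", "total_6mA", "max_mark")


def classify_genes(profiles: pd.DataFrame) -> pd.DataFrame:
    """Label each profiled gene with the four category flags and the
    dual-mark unstable flag (conjunction of all four)."""
    labels = pd.DataFrame({"gene_id": profiles["gene_id"]})
    for flag, col in _FLAG_SOURCE.items():
        labels[flag] = profiles[col].to_numpy() > 0
    labels["unstable"] = labels[FLAG_COLUMNS].all(axis=1)
    return labels


def venn_counts(labels: pd.DataFrame) -> dict[str, int]:
    """Region counts of the 4-set Venn over the category flags.

    Keys are '+'-joined flag subsets (e.g. ``"has_5mC_up+has_6mA_down"``);
    each gene with at least one flag lands in exactly one region, so the 15
    region counts sum to the number of flagged genes.
    """
    flags = labels[FLAG_COLUMNS].to_numpy(dtype=bool)
    counts: dict[str, int] = {}
    for pattern in product([False, True], repeat=4):
        if not any(pattern):
            continue
        key = "+".join(f for f, p in zip(FLAG_COLUMNS, pattern) if p)
        counts[key] = int((flags == np.array(pattern)).all(axis=1).sum())
    return counts


def biotype_composition(
    gene_set: list[str] | pd.Index, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Per-biotype fraction within *gene_set* and within the whole annotation.

    Returns a DataFrame indexed by biotype with columns ``set_fraction`` and
    ``background_fraction`` (each summing to 1).
    """
    ann = annotation.set_index("gene_id")
    missing = [g for g in gene_set if g not in ann.index]
    if missing:
        raise DataFormatError(f"gene(s) absent from annotation: {missing[:5]}")
    background = ann["biotype"].value_counts(normalize=True)
    if len(gene_set) == 0:
        raise DataFormatError("empty gene set for biotype composition")
    in_set = ann.loc[list(gene_set), "biotype"].value_counts(normalize=True)
    out = pd.DataFrame(
        {
            "set_fraction": in_set.reindex(background.index, fill_value=0.0),
            "background_fraction": background,
        }
    )
    out.index.name = "biotype"
    return out.sort_index()


def updown_correlation(
    profiles: pd.DataFrame, mark: str, include_zero_genes: bool = False
) -> tuple[float, int]:
    """Pearson correlation between per-gene up and down site counts of *mark*.

    By default only genes carrying at least one differential site of the
    mark are used (the profiles' support for that mark); set
    ``include_zero_genes`` to keep all profiled genes.

    Returns ``(r, n_genes_used)``.
    """
    up = profiles[f"n_up_{mark}"].to_numpy(dtype=float)
    down = profiles[f"n_down_{mark}"].to_numpy(dtype=float)
    if not include_zero_genes:
        keep = (up + down) > 0
        up, down = up[keep], down[keep]
    n = len(up)
    if n < 3:
        raise DegenerateStatisticsError(
            f"need >=3 genes to correlate up/down counts for {mark}, got {n}"
        )
    if np.ptp(up) == 0 or np.ptp(down) == 0:
        raise DegenerateStatisticsError(
            f"up/down counts for {mark} are constant; correlation undefined"
        )
    r = float(stats.pearsonr(up, down).statistic)
    return r, n


def rank_unstable_genes(
    profiles: pd.DataFrame,
    labels: pd.DataFrame,
    n: int,
    key: str = "total",
) -> list[str]:
    """Top-*n* unstable genes by site burden, ties broken by gene_id.

    ``key`` selects the ranking statistic: total sites over both marks
    (default), one mark's total, or the larger of the two marks.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if key not in RANKING_KEYS:
        raise ValueError(f"unknown ranking key {key!r}; expected one of {RANKING_KEYS}")
    unstable_ids = set(labels.loc[labels["unstable"], "gene_id"])
    sub = profiles[profiles["gene_id"].isin(unstable_ids)].copy()
    t5 = sub["n_up_5mC"] + sub["n_down_5mC"]
    t6 = sub["n_up_6mA"] + sub["n_down_6mA"]
    if key == "total":
        score = sub["total"]
    elif key == "total_5mC":
        score = t5
    elif key == "total_6mA":
        score = t6
    else:
        score = np.maximum(t5, t6)
    sub = sub.assign(_score=score).sort_values(
        ["_score", "gene_id"], ascending=[False, True], kind="stable"
    )
    return sub["gene_id"].head(n).tolist()


def per_chromosome_site_counts(diff_sites: pd.DataFrame) -> pd.DataFrame:
    """Plain per-chromosome differential-site tally (mark x direction)."""
    if len(diff_sites) == 0:
        return pd.DataFrame(columns=["chrom", "mark", "direction", "n_sites"])
    return (
        diff_sites.groupby(["chrom", "mark", "direction"], sort=False)
        .size()
        .reset_index(name="n_sites")
    )
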