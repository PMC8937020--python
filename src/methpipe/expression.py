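"""RPKM normalization, fold-change DE calling, and chi-square association of
methylation gene classes with differential expression.

RPKM is ``count * 1e9 / (library_size * length_bp)``; a gene is called
differentially expressed when the pseudocounted tumor/normal mean-RPKM ratio
strictly exceeds the fold threshold in either direction. Association is a
Pearson chi-square on a 2x2 class-membership x DE table over a configurable
gene universe.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataFormatError

logger = logging.getLogger(__name__)

CLASS_SPECS = ("mark_up_specific", "mark_down_specific", "mark_both_updown")
UNIVERSES = ("annotated_genes", "genes_with_any_signal")

DEFAULT_DE_FOLD = 2.0
DEFAULT_PSEUDOCOUNT = 0.01


def compute_rpkm(
    counts: pd.DataFrame, library_sizes: dict[str, float] | None = None
) -> pd.DataFrame:
    """Per-sample RPKM from a count table (gene_id, length_bp, sample cols).

    ``library_sizes`` defaults to the column sums of the count matrix.
    Returns a DataFrame gene_id + one RPKM column per sample.
    """
    sample_cols = [c for c in counts.columns if c not in ("gene_id", "length_bp")]
    mat = counts[sample_cols].to_numpy(dtype=float)
    lengths = counts["length_bp"].to_numpy(dtype=float)
    if (lengths <= 0).any():
        raise DataFormatError("gene lengths must be positive")
    if library_sizes is None:
        libs = mat.sum(axis=0)
    else:
        libs = np.array([library_sizes[c] for c in sample_cols], dtype=float)
    if (libs <= 0).any():
        bad = sample_cols[int(np.argwhere(libs <= 0)[0][0])]
        raise DataFormatError(f"zero library size for sample {bad!r}")
    rpkm = mat * 1e9 / (libs[None, :] * lengths[:, None])
    out = pd.DataFrame(rpkm, columns=sample_cols)
    out.insert(0, "gene_id", counts["gene_id"].to_numpy())
    return out


def call_de_genes(
    rpkm: pd.DataFrame,
    samples: dict[str, tuple[str, str]],
    fold_threshold: float = DEFAULT_DE_FOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Call DE genes from per-sample RPKM by strict fold change on
    pseudocounted condition means.

    Returns gene_id, mean_rpkm_tumor, mean_rpkm_normal, fold_change, de,
    de_direction (up = higher in tumor).
    """
    tumor = [s for s, (_, c) in samples.items() if c == "tumor"]
    normal = [s for s, (_, c) in samples.items() if c == "normal"]
    if not tumor or not normal:
        raise ConfigurationError("DE calling requires >=1 tumor and >=1 normal sample")
    missing = [s for s in tumor + normal if s not in rpkm.columns]
    if missing:
        raise ConfigurationError(f"sample column(s) {missing} absent from RPKM table")
    mt = rpkm[tumor].to_numpy(dtype=float).mean(axis=1)
    mn = rpkm[normal].to_numpy(dtype=float).mean(axis=1)
    fc = (mt + pseudocount) / (mn + pseudocount)
    de_up = fc > fold_threshold
    de_down = fc < 1.0 / fold_threshold
    direction = np.where(de_up, "up", np.where(de_down, "down", "none"))
    return pd.DataFrame(
        {
            "gene_id": rpkm["gene_id"].to_numpy(),
            "mean_rpkm_tumor": mt,
            "mean_rpkm_normal": mn,
            "fold_change": fc,
            "de": de_up | de_down,
            "de_direction": direction,
        }
    )


@dataclass
class ContingencyTable:
    """2x2 class-membership x DE-status counts with provenance."""

    table: np.ndarray  # rows: in-class / not-in-class, cols: DE / not-DE
    class_spec: str
    mark: str
    universe: str
    n_universe: int
    degenerate_margin: bool

    def odds_ratio(self) -> float:
        a, b = self.table[0]
        c, d = self.table[1]
        if b == 0 or c == 0:
            return float("inf") if a * d > 0 else float("nan")
        return float(a * d) / float(b * c)


def class_membership(labels: pd.DataFrame, mark: str, class_spec: str) -> pd.Series:
    """Boolean membership of each labelled gene in the requested class.

    ``mark_up_specific``: up sites but no down sites of the mark;
    ``mark_down_specific``: the reverse; ``mark_both_updown``: both.
    """
    if class_spec not in CLASS_SPECS:
        raise ConfigurationError(f"unknown class_spec {class_spec!r}")
    up = labels[f"has_{mark}_up"]
    down = labels[f"has_{mark}_down"]
    if class_spec == "mark_up_specific":
        member = up & ~down
    elif class_spec == "mark_down_specific":
        member = ~up & down
    else:
        member = up & down
    return pd.Series(member.to_numpy(), index=labels["gene_id"].to_numpy())


def build_contingency(
    labels: pd.DataFrame,
    de_results: pd.DataFrame,
    mark: str,
    class_spec: str,
    universe: list[str] | pd.Index,
) -> ContingencyTable:
    """Count class membership against DE status over *universe* genes.

    Genes in the universe absent from the labels count as not-in-class;
    genes absent from the DE results count as not-DE.
    """
    universe = pd.Index(universe)
    if len(universe) == 0:
        raise DataFormatError("empty gene universe for contingency table")
    member = class_membership(labels, mark, class_spec).reindex(universe, fill_value=False)
    de = (
        pd.Series(de_results["de"].to_numpy(), index=de_results["gene_id"].to_numpy())
        .reindex(universe, fill_value=False)
        .astype(bool)
    )
    a = int((member & de).sum())
    b = int((member & ~de).sum())
    c = int((~member & de).sum())
    d = int((~member & ~de).sum())
    table = np.array([[a, b], [c, d]], dtype=np.int64)
    degenerate = bool((table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any())
    if degenerate:
        logger.warning(
            "degenerate contingency margin for %s/%s over %d genes", mark, class_spec, len(universe)
        )
    return ContingencyTable(
        table=table,
        class_spec=class_spec,
        mark=mark,
        universe="custom",
        n_universe=len(universe),
        degenerate_margin=degenerate,
    )


def chi_square_test(
    table: np.ndarray, yates: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table.

    Returns ``(statistic, df, p)``. No continuity correction by default;
    ``yates`` applies the standard |O-E|-0.5 correction. Expected cells of
    zero raise; expected cells below 5 warn.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise DataFormatError(f"contingency table must be at least 2x2, got shape {obs.shape}")
    if (obs < 0).any():
        raise DataFormatError("negative cell count")
    n = obs.sum()
    if n == 0:
        raise DataFormatError("empty contingency table")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    if (expected == 0).any():
        raise DataFormatError("expected cell count of zero (degenerate margin)")
    if (expected < 5).any():
        warnings.warn("expected cell count below 5; chi-square approximation is poor")
    dev = np.abs(obs - expected)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    statistic = float((dev**2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(statistic, df))
    return statistic, df, p


def association_report(
    labels: pd.DataFrame,
    de_results: pd.DataFrame,
    universe: list[str] | pd.Index,
    yates: bool = False,
) -> dict:
    """Chi-square association of each mark's gene classes with DE status.

    Runs every (mark, class_spec) combination over the shared *universe*
    and also reports the fraction of dual-mark unstable genes that are DE.
    Degenerate tables are reported with ``error`` instead of a p-value.
    """
    report: dict = {"tests": [], "n_universe": len(pd.Index(universe))}
    for mark in ("5mC", "6mA"):
        for spec in CLASS_SPECS:
            entry: dict = {"mark": mark, "class_spec": spec}
            try:
                ct = build_contingency(labels, de_results, mark, spec, universe)
                statistic, df, p = chi_square_test(ct.table, yates=yates)
                entry.update(
                    table=ct.table.tolist(),
                    statistic=statistic,
                    df=df,
                    p=p,
                    odds_ratio=ct.odds_ratio(),
                    degenerate_margin=ct.degenerate_margin,
                )
            except (DataFormatError,) as exc:
                entry["error"] = str(exc)
            report["tests"].append(entry)

    unstable_ids = labels.loc[labels["unstable"], "gene_id"]
    de_by_gene = pd.Series(
        de_results["de"].to_numpy(), index=de_results["gene_id"].to_numpy()
    )
    if len(unstable_ids):
        de_flags = de_by_gene.reindex(unstable_ids, fill_value=False).astype(bool)
        report["unstable_de_fraction"] = float(de_flags.mean())
        report["n_unstable"] = int(len(unstable_ids))
    else:
        report["unstable_de_fraction"] = None
        report["n_unstable"] = 0
    return report
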