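"""Assign differential sites to genes by interval overlap and build
per-gene up/down site-count profiles for both marks.

Overlap semantics follow ``bedtools intersect`` defaults: a 1-bp site
interval ``[pos0, pos0+1)`` is assigned to every gene it overlaps by at
least one base, strand ignored; a site overlapping k genes contributes to
all k profiles. Sites in no gene are intergenic and excluded.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pyranges as pr

from .io_formats import MARKS

logger = logging.getLogger(__name__)

PROFILE_COLUMNS = [
    "gene_id",
    "n_up_5mC",
    "n_down_5mC",
    "n_up_6mA",
    "n_down_6mA",
    "total",
]

_COUNT_COL = {
    ("5mC", "up"): "n_up_5mC",
    ("5mC", "down"): "n_down_5mC",
    ("6mA", "up"): "n_up_6mA",
    ("6mA", "down"): "n_down_6mA",
}


def assign_sites_to_genes(
    sites: pd.DataFrame, genes: pd.DataFrame, flank: int = 0
) -> pd.DataFrame:
    """Map each differential site to the gene(s) whose body it overlaps.

    *sites* needs columns chrom, pos0 (plus any carried along, e.g. mark and
    direction); *genes* needs gene_id, chrom, start, end. ``flank`` extends
    every gene symmetrically by that many bp (default 0 = gene body only).

    Returns the site rows replicated once per overlapping gene with a
    ``gene_id`` column appended; intergenic sites are absent from the result.
    """
    if len(sites) == 0 or len(genes) == 0:
        return sites.iloc[0:0].assign(gene_id=pd.Series(dtype=str))

    missing_chroms = set(sites["chrom"]) - set(genes["chrom"])
    if missing_chroms:
        logger.warning(
            "%d site chromosome(s) absent from annotation, treated as intergenic: %s",
            len(missing_chroms),
            sorted(missing_chroms),
        )

    site_pr = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": sites["chrom"].to_numpy(),
                "Start": sites["pos0"].to_numpy(),
                "End": sites["pos0"].to_numpy() + 1,
                "_row": np.arange(len(sites)),
            }
        )
    )
    gene_pr = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": genes["chrom"].to_numpy(),
                "Start": np.maximum(genes["start"].to_numpy() - flank, 0),
                "End": genes["end"].to_numpy() + flank,
                "gene_id": genes["gene_id"].to_numpy(),
            }
        )
    )
    joined = site_pr.join(gene_pr).df
    if len(joined) == 0:
        return sites.iloc[0:0].assign(gene_id=pd.Series(dtype=str))
    out = sites.iloc[joined["_row"].to_numpy()].reset_index(drop=True)
    out["gene_id"] = joined["gene_id"].to_numpy()
    return out


def build_profiles(assigned: pd.DataFrame) -> pd.DataFrame:
    """Tally assigned differential sites into per-gene direction x mark counts.

    *assigned* is the output of :func:`assign_sites_to_genes` for one or both
    marks (concatenated); it needs columns gene_id, mark, direction. Genes
    with no assigned site do not appear.
    """
    if len(assigned) == 0:
        return pd.DataFrame(columns=PROFILE_COLUMNS)
    counts = (
        assigned.groupby(["gene_id", "mark", "direction"], sort=False)
        .size()
        .reset_index(name="n")
    )
    wide = pd.DataFrame(index=pd.Index(sorted(assigned["gene_id"].unique()), name="gene_id"))
    for (mark, direction), col in _COUNT_COL.items():
        sub = counts[(counts["mark"] == mark) & (counts["direction"] == direction)]
        wide[col] = pd.Series(sub["n"].to_numpy(), index=sub["gene_id"]).reindex(
            wide.index, fill_value=0
        )
    wide = wide.fillna(0).astype(int)
    wide["total"] = wide[[c for c in _COUNT_COL.values()]].sum(axis=1)
    return wide.reset_index()[PROFILE_COLUMNS]


def profiles_from_diff_sites(
    diff_sites: pd.DataFrame, genes: pd.DataFrame, flank: int = 0
) -> pd.DataFrame:
    """Convenience: assign then tally in one step.

    *diff_sites* may contain both marks; unknown marks raise.
    """
    unknown = set(diff_sites["mark"].unique()) - set(MARKS) if len(diff_sites) else set()
    if unknown:
        raise ValueError(f"unknown mark(s) in differential sites: {sorted(unknown)}")
    assigned = assign_sites_to_genes(diff_sites, genes, flank=flank)
    return build_profiles(assigned)
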