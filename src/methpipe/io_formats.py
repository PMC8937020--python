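"""Readers and writers for every on-disk format the pipeline touches.

All genomic coordinates are 0-based half-open (BED convention) everywhere
inside the package; conversion from 1-based closed (GFF3) happens here and
only here. Chromosomes are ordered naturally (chr1 < chr2 < ... < chr10 <
chrX < chrY), never lexicographically.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataFormatError

logger = logging.getLogger(__name__)

MARKS = ("5mC", "6mA")
CONDITIONS = ("tumor", "normal")

#: columns of the differential-site TSV, in order
DIFF_SITE_COLUMNS = [
    "chrom",
    "pos0",
    "end",
    "mark",
    "direction",
    "tumor_score",
    "normal_score",
    "rule",
]

_CHROM_RE = re.compile(r"^(chr)?(\d+|X|Y|M|MT)$", re.IGNORECASE)


def natural_chrom_key(chrom: str):
    """Sort key placing chr2 before chr10 and numeric chromosomes before X/Y/M."""
    m = _CHROM_RE.match(chrom)
    if m:
        body = m.group(2).upper()
        if body.isdigit():
            return (0, int(body), "")
        return (1, {"X": 0, "Y": 1, "M": 2, "MT": 2}[body], "")
    return (2, 0, chrom)


def sort_genomic(df: pd.DataFrame, extra: list[str] | None = None) -> pd.DataFrame:
    """Stable sort by natural chromosome order, position, then *extra* columns."""
    key = df["chrom"].map(natural_chrom_key)
    order = (
        df.assign(_k=key)
        .sort_values(["_k", "pos0"] + (extra or []), kind="stable")
        .drop(columns="_k")
    )
    return order.reset_index(drop=True)


# ---------------------------------------------------------------------------
# sample sheets
# ---------------------------------------------------------------------------


def read_sample_sheet(path) -> dict[str, tuple[str, str]]:
    """Read a sample sheet TSV (column_name, pair_id, condition).

    Returns a mapping ``sample_column -> (pair_id, condition)``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"column_name", "pair_id", "condition"}
    if not required.issubset(df.columns):
        raise DataFormatError(
            f"sample sheet {path} must have columns {sorted(required)}, got {list(df.columns)}"
        )
    bad = df.loc[~df["condition"].isin(CONDITIONS), "condition"]
    if len(bad):
        raise DataFormatError(
            f"sample sheet {path}: condition must be one of {CONDITIONS}, got {bad.iloc[0]!r}"
        )
    if df["column_name"].duplicated().any():
        dup = df.loc[df["column_name"].duplicated(), "column_name"].iloc[0]
        raise DataFormatError(f"sample sheet {path}: duplicate column_name {dup!r}")
    return {r.column_name: (r.pair_id, r.condition) for r in df.itertuples()}


def write_sample_sheet(samples: dict[str, tuple[str, str]], path) -> None:
    rows = [
        {"column_name": name, "pair_id": pair, "condition": cond}
        for name, (pair, cond) in samples.items()
    ]
    pd.DataFrame(rows, columns=["column_name", "pair_id", "condition"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# per-site methylation score tables
# ---------------------------------------------------------------------------


@dataclass
class SiteScoreTable:
    """Per-site, per-sample methylation scores for a single mark.

    ``data`` holds columns ``chrom``, ``pos0`` then one float column per
    sample; ``samples`` maps each sample column to ``(pair_id, condition)``.
    """

    mark: str
    data: pd.DataFrame
    samples: dict[str, tuple[str, str]] = field(default_factory=dict)

    @property
    def sample_names(self) -> list[str]:
        return list(self.samples)

    def samples_for(self, condition: str) -> list[str]:
        return [s for s, (_, c) in self.samples.items() if c == condition]

    def scores(self) -> np.ndarray:
        """Score matrix, shape (n_sites, n_samples), sample order = sample_names."""
        return self.data[self.sample_names].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)

    def validate(self) -> "SiteScoreTable":
        if self.mark not in MARKS:
            raise DataFormatError(f"unknown mark {self.mark!r}; expected one of {MARKS}")
        for cond in CONDITIONS:
            if not self.samples_for(cond):
                raise DataFormatError(f"site table has no {cond} sample")
        mat = self.scores()
        if len(mat) and ((mat < 0) | (mat > 1)).any():
            i = int(np.argwhere((mat < 0) | (mat > 1))[0][0])
            raise DataFormatError(
                f"score outside [0,1] at site row {i} "
                f"({self.data['chrom'].iat[i]}:{self.data['pos0'].iat[i]})"
            )
        dup = self.data.duplicated(subset=["chrom", "pos0"])
        if dup.any():
            i = int(np.flatnonzero(dup.to_numpy())[0])
            raise DataFormatError(
                f"duplicate site {self.data['chrom'].iat[i]}:{self.data['pos0'].iat[i]}"
            )
        return self


def read_site_scores(path, mark: str, sample_sheet: dict[str, tuple[str, str]]) -> SiteScoreTable:
    """Read a per-site score TSV (chrom, pos0, mark, one column per sample).

    Malformed rows are rejected with 1-based file line numbers (header is
    line 1). Sample columns not present in *sample_sheet* raise
    :class:`ConfigurationError`.
    """
    df = pd.read_csv(path, sep="\t")
    expected_fixed = ["chrom", "pos0", "mark"]
    if list(df.columns[:3]) != expected_fixed:
        raise DataFormatError(
            f"{path}: first three columns must be {expected_fixed}, got {list(df.columns[:3])}"
        )
    sample_cols = [c for c in df.columns[3:]]
    unmapped = [c for c in sample_cols if c not in sample_sheet]
    if unmapped:
        raise ConfigurationError(
            f"{path}: sample column(s) {unmapped} not present in the sample sheet"
        )
    if len(df) == 0:
        logger.warning("%s: empty site table (header only)", path)
    else:
        wrong_mark = df.index[df["mark"].astype(str) != mark]
        if len(wrong_mark):
            raise DataFormatError(
                f"{path} line {wrong_mark[0] + 2}: mark {df['mark'].iloc[wrong_mark[0]]!r}, expected {mark!r}"
            )
        scores = df[sample_cols].to_numpy(dtype=float)
        bad = np.argwhere(~np.isfinite(scores) | (scores < 0) | (scores > 1))
        if len(bad):
            r, c = bad[0]
            raise DataFormatError(
                f"{path} line {r + 2}: score {scores[r, c]!r} in column "
                f"{sample_cols[c]!r} outside [0,1]"
            )
        dup = df.duplicated(subset=["chrom", "pos0"])
        if dup.any():
            r = int(np.flatnonzero(dup.to_numpy())[0])
            raise DataFormatError(
                f"{path} line {r + 2}: duplicate site {df['chrom'].iat[r]}:{df['pos0'].iat[r]}"
            )
    data = df[["chrom", "pos0"] + sample_cols].copy()
    data["pos0"] = data["pos0"].astype(np.int64) if len(data) else data["pos0"]
    samples = {c: sample_sheet[c] for c in sample_cols}
    return SiteScoreTable(mark=mark, data=data, samples=samples).validate()


def write_site_scores(table: SiteScoreTable, path) -> None:
    out = table.data.copy()
    out.insert(2, "mark", table.mark)
    out = sort_genomic(out)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "biotype"]

_GFF3_ATTR_RE = re.compile(r"(\w+)=([^;]+)")


def _validate_genes(df: pd.DataFrame, path) -> pd.DataFrame:
    if len(df):
        bad = df.index[df["start"] >= df["end"]]
        if len(bad):
            row = df.loc[bad[0]]
            raise DataFormatError(
                f"{path}: gene {row.gene_id!r} has start {row.start} >= end {row.end}"
            )
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise DataFormatError(f"{path}: duplicate gene_id {dup!r}")
    return df.reset_index(drop=True)


def read_gene_annotation(path) -> pd.DataFrame:
    """Read gene models from BED6+biotype or GFF3 (gene features only).

    The dialect is chosen by extension (``.bed`` vs ``.gff``/``.gff3``).
    Returns a DataFrame with columns ``gene_id, chrom, start, end, strand,
    biotype`` in 0-based half-open coordinates.
    """
    spath = str(path)
    if spath.endswith((".gff", ".gff3")):
        return _read_gff3_genes(path)
    return _read_bed_genes(path)


def _read_bed_genes(path) -> pd.DataFrame:
    names = ["chrom", "start", "end", "gene_id", "score", "strand", "biotype"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] < 7:
        raise DataFormatError(
            f"{path}: BED annotation needs 7 columns (BED6 + biotype), got {df.shape[1]}"
        )
    df = df.iloc[:, :7]
    df.columns = names
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return _validate_genes(df[GENE_COLUMNS], path)


def _read_gff3_genes(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise DataFormatError(f"{path} line {lineno}: expected 9 GFF3 columns")
            chrom, _src, feat, start, end, _score, strand, _frame, attrs = parts
            if feat != "gene":
                continue
            a = dict(_GFF3_ATTR_RE.findall(attrs))
            gene_id = a.get("ID") or a.get("gene_id")
            if gene_id is None:
                raise DataFormatError(f"{path} line {lineno}: gene feature without ID")
            biotype = a.get("biotype") or a.get("gene_biotype")
            if biotype is None:
                raise DataFormatError(f"{path} line {lineno}: gene {gene_id!r} missing biotype")
            # GFF3 is 1-based closed; convert to 0-based half-open
            rows.append(
                {
                    "gene_id": gene_id,
                    "chrom": chrom,
                    "start": int(start) - 1,
                    "end": int(end),
                    "strand": strand if strand in "+-" else ".",
                    "biotype": biotype,
                }
            )
    df = pd.DataFrame(rows, columns=GENE_COLUMNS)
    return _validate_genes(df, path)


def write_gene_annotation(genes: pd.DataFrame, path) -> None:
    """Write genes as BED6 + biotype (7 columns, no header)."""
    out = genes.copy()
    out["score"] = 0
    key = out["chrom"].map(natural_chrom_key)
    out = out.assign(_k=key).sort_values(["_k", "start"], kind="stable").drop(columns="_k")
    out[["chrom", "start", "end", "gene_id", "score", "strand", "biotype"]].to_csv(
        path, sep="\t", index=False, header=False
    )


# ---------------------------------------------------------------------------
# differential sites
# ---------------------------------------------------------------------------


def write_differential_sites(sites: pd.DataFrame, path) -> None:
    """Write called differential sites as a BED-like 8-column TSV with header."""
    out = sites.copy()
    if "end" not in out.columns:
        out["end"] = out["pos0"] + 1
    out = out[DIFF_SITE_COLUMNS] if len(out) else pd.DataFrame(columns=DIFF_SITE_COLUMNS)
    if len(out):
        out = sort_genomic(out, extra=["mark"])
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_differential_sites(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "chrom": str,
            "mark": str,
            "direction": str,
            "rule": str,
        },
    )
    missing = [c for c in DIFF_SITE_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"{path}: missing differential-site columns {missing}")
    if len(df):
        df["pos0"] = df["pos0"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
    return df[DIFF_SITE_COLUMNS]


# ---------------------------------------------------------------------------
# counts / survival / truth
# ---------------------------------------------------------------------------


def read_counts(path) -> pd.DataFrame:
    """Read a gene-level count table: gene_id, length_bp, one column per sample."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["gene_id", "length_bp"]:
        raise DataFormatError(
            f"{path}: first two columns must be gene_id, length_bp, got {list(df.columns[:2])}"
        )
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise DataFormatError(f"{path}: duplicate gene_id {dup!r}")
    if len(df) and (df["length_bp"] <= 0).any():
        bad = df.loc[df["length_bp"] <= 0, "gene_id"].iloc[0]
        raise DataFormatError(f"{path}: non-positive length for gene {bad!r}")
    sample_cols = list(df.columns[2:])
    if len(df) and (df[sample_cols].to_numpy(dtype=float) < 0).any():
        raise DataFormatError(f"{path}: negative count")
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_survival(path) -> pd.DataFrame:
    """Read a survival table: sample_id, time_days, event, one column per gene."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:3]) != ["sample_id", "time_days", "event"]:
        raise DataFormatError(
            f"{path}: first three columns must be sample_id, time_days, event"
        )
    if len(df):
        if (df["time_days"] <= 0).any():
            bad = df.loc[df["time_days"] <= 0, "sample_id"].iloc[0]
            raise DataFormatError(f"{path}: non-positive time for sample {bad!r}")
        if not df["event"].isin([0, 1]).all():
            bad = df.loc[~df["event"].isin([0, 1]), "sample_id"].iloc[0]
            raise DataFormatError(f"{path}: event not in {{0,1}} for sample {bad!r}")
        gene_cols = df.columns[3:]
        if (df[gene_cols].to_numpy(dtype=float) < 0).any():
            raise DataFormatError(f"{path}: negative expression value")
    return df


def write_survival(surv: pd.DataFrame, path) -> None:
    surv.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
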