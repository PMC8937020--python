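"""Synthetic paired tumor/normal cohort generator with planted ground truth.

Generates, from one seeded configuration: a non-overlapping gene annotation,
dual-mark (5mC/6mA) per-site score tables for paired tumor/normal samples,
a gene-level count table, and a survival table — all with planted effects
recorded in a :class:`GroundTruth` so downstream stages can be validated
against known answers.

Planting model
--------------
* Each gene is independently labelled unstable for each mark; a labelled
  gene receives >=1 up- and >=1 down-regulated site of that mark, with the
  per-gene (up, down) counts drawn from a shared-gamma Poisson mixture whose
  mixing weight is solved numerically for the target Pearson correlation.
  The dual-mark unstable set is the intersection of the two labels.
* Planted differential sites are constructed to pass the calling rules
  (strict >2-fold change, or one-sided zero with the other side >0.6) under
  any aggregation policy; background sites are constrained to a ratio
  strictly inside [0.5, 2] with no zeros, so they can never be called.
* DE labels follow a logistic model whose log-odds add the log odds ratios
  of the two per-mark labels; planted DE genes change expression by exactly
  the configured fold change in the condition means.
* Survival-effect genes (chosen among dual-unstable, DE-down genes) raise
  the hazard of patients in their low-expression half by exp(hazard_log_hr).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ConfigurationError
from .io_formats import (
    MARKS,
    SiteScoreTable,
    write_counts,
    write_gene_annotation,
    write_json,
    write_sample_sheet,
    write_site_scores,
    write_survival,
)

_DEFAULT_BIOTYPES = {"protein_coding": 0.45, "pseudogene": 0.30, "lncRNA": 0.25}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort; every field has a sane default."""

    seed: int = 0
    n_genes: int = 300
    n_chromosomes: int = 4
    gene_length_range: tuple[int, int] = (1000, 5000)
    chromosome_length: int | None = None  # None = grow as needed
    biotype_fractions: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BIOTYPES)
    )
    sites_per_gene_mean: float = 20.0  # differential sites per labelled gene per mark
    background_sites_per_gene: float = 5.0
    intergenic_site_fraction: float = 0.1
    n_pairs: int = 2
    updown_corr_5mC: float = 0.15
    updown_corr_6mA: float = 0.85
    gamma_shape: float = 1.5
    frac_unstable_5mC: float = 0.4
    frac_unstable_6mA: float = 0.4
    unstable_protein_coding_fraction: float | None = None
    zero_rescue_site_fraction: float = 0.2
    de_base_rate: float = 0.2
    de_coupling_odds_ratio_5mC: float = 1.0
    de_coupling_odds_ratio_6mA: float = 1.0
    de_fold_change: float = 4.0
    dispersion: float = 0.05
    library_size: float = 1_000_000.0
    baseline_hazard: float = 1.0 / 1000.0  # per day
    hazard_log_hr: float = 1.0
    n_survival_genes: int = 2
    censor_rate: float = 0.2
    n_patients: int = 200

    def __post_init__(self):
        self.gene_length_range = tuple(self.gene_length_range)
        counts = {
            "n_genes": self.n_genes,
            "n_chromosomes": self.n_chromosomes,
            "n_pairs": self.n_pairs,
            "n_patients": self.n_patients,
        }
        for name, v in counts.items():
            if v < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {v}")
        fracs = {
            "intergenic_site_fraction": self.intergenic_site_fraction,
            "frac_unstable_5mC": self.frac_unstable_5mC,
            "frac_unstable_6mA": self.frac_unstable_6mA,
            "zero_rescue_site_fraction": self.zero_rescue_site_fraction,
            "de_base_rate": self.de_base_rate,
            "censor_rate": self.censor_rate,
        }
        for name, v in fracs.items():
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must lie in [0,1], got {v}")
        total = sum(self.biotype_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"biotype_fractions must sum to 1, got {total}")
        if any(not 0 <= f <= 1 for f in self.biotype_fractions.values()):
            raise ConfigurationError("biotype fractions must lie in [0,1]")
        lo, hi = self.gene_length_range
        if lo < 1 or hi < lo:
            raise ConfigurationError(f"bad gene_length_range {self.gene_length_range}")
        for name in (
            "sites_per_gene_mean",
            "de_fold_change",
            "library_size",
            "baseline_hazard",
            "gamma_shape",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        if self.de_coupling_odds_ratio_5mC <= 0 or self.de_coupling_odds_ratio_6mA <= 0:
            raise ConfigurationError("DE coupling odds ratios must be positive")
        # validate correlation targets eagerly so bad configs fail fast
        for mark in MARKS:
            solve_mixture_weight(
                getattr(self, f"updown_corr_{mark}"),
                self.sites_per_gene_mean / 2.0,
                self.gamma_shape,
            )

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "frac_unstable" in d:  # dual-mark shorthand: sets both per-mark rates
            f = d.pop("frac_unstable")
            if not 0 <= f <= 1:
                raise ConfigurationError(f"frac_unstable must lie in [0,1], got {f}")
            d.setdefault("frac_unstable_5mC", float(np.sqrt(f)))
            d.setdefault("frac_unstable_6mA", float(np.sqrt(f)))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown simulation config key(s): {sorted(unknown)}")
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from exc


@dataclass
class GroundTruth:
    """Planted per-gene labels and per-site directions."""

    genes: pd.DataFrame  # gene_id, biotype, per-mark counts + labels, de, survival
    sites: pd.DataFrame  # chrom, pos0, mark, direction, gene_id (planted only)

    def unstable_gene_ids(self) -> list[str]:
        return self.genes.loc[self.genes["unstable"], "gene_id"].tolist()

    def to_dict(self) -> dict:
        return {
            "genes": self.genes.to_dict(orient="records"),
            "sites": self.sites.to_dict(orient="records"),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(genes=pd.DataFrame(d["genes"]), sites=pd.DataFrame(d["sites"]))


# ---------------------------------------------------------------------------
# the (up, down) count model
# ---------------------------------------------------------------------------


def updown_correlation_of_weight(w: float, mu: float, k: float) -> float:
    """Closed-form Pearson correlation of the shifted shared-gamma Poisson pair.

    Counts are ``1 + Poisson(rate)`` with rates ``(mu-1)*(w*g + (1-w)*h_up)``
    and ``(mu-1)*(w*g + (1-w)*h_down)`` for iid Gamma(k, 1/k) factors g, h;
    the +1 shift guarantees both directions are represented and leaves the
    correlation unchanged. ``mu`` is the per-direction mean count.
    """
    mu_eff = mu - 1.0
    num = w**2 / k
    den = 1.0 / mu_eff + (w**2 + (1 - w) ** 2) / k
    return num / den


def solve_mixture_weight(target: float, mu: float, k: float) -> float:
    """Solve the shared-factor weight achieving *target* correlation."""
    if not 0 <= target < 1:
        raise ConfigurationError(
            f"up/down count correlation target must lie in [0,1), got {target}"
        )
    if mu <= 1:
        raise ConfigurationError(
            f"per-direction mean site count must exceed 1 (sites_per_gene_mean > 2), got {2 * mu}"
        )
    max_corr = updown_correlation_of_weight(1.0, mu, k)
    if target > max_corr:
        raise ConfigurationError(
            f"correlation target {target} exceeds the model maximum "
            f"{max_corr:.3f} (mean {2 * mu} sites/gene, gamma shape {k}); "
            "raise sites_per_gene_mean or lower gamma_shape"
        )
    if target == 0:
        return 0.0
    return float(brentq(lambda w: updown_correlation_of_weight(w, mu, k) - target, 0.0, 1.0))


def draw_updown_counts(
    n: int, mu: float, k: float, w: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n (up, down) pairs; both counts are always >= 1."""
    mu_eff = mu - 1.0
    g = rng.gamma(k, 1.0 / k, size=n)
    hu = rng.gamma(k, 1.0 / k, size=n)
    hd = rng.gamma(k, 1.0 / k, size=n)
    up = 1 + rng.poisson(mu_eff * (w * g + (1 - w) * hu))
    down = 1 + rng.poisson(mu_eff * (w * g + (1 - w) * hd))
    return up.astype(np.int64), down.astype(np.int64)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def gen_annotation(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Generate a non-overlapping gene annotation.

    Genes are dealt round-robin onto ``n_chromosomes`` chromosomes and packed
    left to right with random gaps. Returns ``(genes, chrom_sizes)``.
    """
    n = config.n_genes
    width = max(4, len(str(n)))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(n)]
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    biotypes = list(config.biotype_fractions)
    probs = np.array([config.biotype_fractions[b] for b in biotypes], dtype=float)
    probs = probs / probs.sum()
    biotype = rng.choice(biotypes, size=n, p=probs)
    strand = rng.choice(["+", "-"], size=n)
    chrom_idx = np.arange(n) % config.n_chromosomes

    starts = np.empty(n, dtype=np.int64)
    ends = np.empty(n, dtype=np.int64)
    chrom_sizes: dict[str, int] = {}
    gaps = rng.integers(500, 5000, size=n)
    for ci in range(config.n_chromosomes):
        idx = np.flatnonzero(chrom_idx == ci)
        cursor = 0
        for j in idx:
            cursor += int(gaps[j])
            starts[j] = cursor
            cursor += int(lengths[j])
            ends[j] = cursor
        size = cursor + 1000
        name = f"chr{ci + 1}"
        if config.chromosome_length is not None:
            if size > config.chromosome_length:
                raise ConfigurationError(
                    f"cannot pack genes into chromosome_length={config.chromosome_length} "
                    f"({name} needs {size} bp)"
                )
            size = config.chromosome_length
        chrom_sizes[name] = size

    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": [f"chr{c + 1}" for c in chrom_idx],
            "start": starts,
            "end": ends,
            "strand": strand,
            "biotype": biotype,
        }
    )
    return genes, chrom_sizes


# ---------------------------------------------------------------------------
# gene labels (instability + counts)
# ---------------------------------------------------------------------------


def _label_probabilities(
    config: SimulationConfig, biotype: np.ndarray, frac: float
) -> np.ndarray:
    """Per-gene label probability, optionally biotype-weighted."""
    n = len(biotype)
    target_pc = config.unstable_protein_coding_fraction
    if target_pc is None:
        return np.full(n, frac)
    is_pc = biotype == "protein_coding"
    n_pc = int(is_pc.sum())
    n_other = n - n_pc
    if n_pc == 0 or n_other == 0:
        return np.full(n, frac)
    m = frac * n  # expected labelled genes
    p_pc = target_pc * m / n_pc
    p_other = (1 - target_pc) * m / n_other
    if p_pc > 1 or p_other > 1:
        raise ConfigurationError(
            "unstable_protein_coding_fraction infeasible for the biotype mix"
        )
    return np.where(is_pc, p_pc, p_other)


def gen_gene_labels(
    config: SimulationConfig, genes: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw per-mark instability labels and planted (up, down) site counts.

    Labels are independent across marks; a gene labelled for a mark gets
    counts >= 1 in both directions from the correlated count model, an
    unlabelled gene gets zero differential sites of that mark. The dual-mark
    ``unstable`` flag is the conjunction of the two labels.
    """
    n = len(genes)
    mu = config.sites_per_gene_mean / 2.0
    k = config.gamma_shape
    out = pd.DataFrame(
        {"gene_id": genes["gene_id"].to_numpy(), "biotype": genes["biotype"].to_numpy()}
    )
    for mark in MARKS:
        frac = getattr(config, f"frac_unstable_{mark}")
        p = _label_probabilities(config, out["biotype"].to_numpy(), frac)
        labelled = rng.random(n) < p
        w = solve_mixture_weight(getattr(config, f"updown_corr_{mark}"), mu, k)
        up = np.zeros(n, dtype=np.int64)
        down = np.zeros(n, dtype=np.int64)
        if labelled.any():
            u, d = draw_updown_counts(int(labelled.sum()), mu, k, w, rng)
            up[labelled] = u
            down[labelled] = d
        out[f"unstable_{mark}"] = labelled
        out[f"n_up_{mark}"] = up
        out[f"n_down_{mark}"] = down
    out["unstable"] = out["unstable_5mC"] & out["unstable_6mA"]
    return out


def gen_de_labels(
    config: SimulationConfig, truth_genes: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Add DE labels coupled to the per-mark instability labels.

    ``logit P(DE) = logit(base) + ln(OR_5mC)*unstable_5mC + ln(OR_6mA)*unstable_6mA``.
    DE direction is a fair coin.
    """
    out = truth_genes.copy()
    base = config.de_base_rate
    logit = np.log(base / (1 - base)) if 0 < base < 1 else (-np.inf if base == 0 else np.inf)
    z = (
        logit
        + np.log(config.de_coupling_odds_ratio_5mC) * out["unstable_5mC"].to_numpy()
        + np.log(config.de_coupling_odds_ratio_6mA) * out["unstable_6mA"].to_numpy()
    )
    p = 1.0 / (1.0 + np.exp(-z))
    de = rng.random(len(out)) < p
    direction = np.where(de, np.where(rng.random(len(out)) < 0.5, "up", "down"), "none")
    out["de"] = de
    out["de_direction"] = direction
    return out


def assign_survival_effects(
    config: SimulationConfig, truth_genes: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Flag up to ``n_survival_genes`` dual-unstable DE-down genes as
    survival-effect genes (the planted tumor-suppressor candidates)."""
    out = truth_genes.copy()
    eligible = np.flatnonzero(
        (out["unstable"] & (out["de_direction"] == "down")).to_numpy()
    )
    n_pick = min(config.n_survival_genes, len(eligible))
    picked = rng.choice(eligible, size=n_pick, replace=False) if n_pick else []
    flag = np.zeros(len(out), dtype=bool)
    flag[list(picked)] = True
    out["survival_effect"] = flag
    return out


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------


def _planted_scores(
    n: int, direction: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(tumor, normal) score pairs that pass the calling rules as planted.

    A ``zero_rescue_site_fraction`` share uses the one-sided-zero mechanism
    (zero on the low side, >0.6 on the high side); the rest use a strict
    >2-fold change with both sides positive.
    """
    use_zero = rng.random(n) < config.zero_rescue_site_fraction
    high = rng.uniform(0.65, 0.98, size=n)
    low_base = rng.uniform(0.05, 0.40, size=n)
    ratio_cap = np.minimum(1.0 / low_base, 8.0)
    ratio = 2.25 + rng.random(n) * (ratio_cap - 2.25)
    hi_fold = low_base * ratio  # in (0.1125, 1.0]
    hi = np.where(use_zero, high, hi_fold)
    lo = np.where(use_zero, 0.0, low_base)
    up = direction == "up"
    tumor = np.where(up, hi, lo)
    normal = np.where(up, lo, hi)
    return tumor, normal


def _background_scores(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """(tumor, normal) pairs that can never be called: no zeros, ratio well
    inside (0.5, 2) even after per-sample jitter."""
    normal = rng.uniform(0.10, 0.65, size=n)
    ratio = rng.uniform(0.65, 1.50, size=n)
    tumor = normal * ratio
    return tumor, normal


def _sample_names(config: SimulationConfig) -> dict[str, tuple[str, str]]:
    samples: dict[str, tuple[str, str]] = {}
    for i in range(config.n_pairs):
        pair = f"P{i + 1}"
        samples[f"{pair}_T"] = (pair, "tumor")
        samples[f"{pair}_N"] = (pair, "normal")
    return samples


def _intergenic_positions(
    n: int,
    genes: pd.DataFrame,
    chrom_sizes: dict[str, int],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample n distinct positions outside every gene body."""
    gaps = []  # (chrom, gap_start, gap_len)
    for chrom, size in chrom_sizes.items():
        sub = genes[genes["chrom"] == chrom].sort_values("start")
        cursor = 0
        for row in sub.itertuples():
            if row.start > cursor:
                gaps.append((chrom, cursor, row.start - cursor))
            cursor = max(cursor, int(row.end))
        if size > cursor:
            gaps.append((chrom, cursor, size - cursor))
    total = sum(g[2] for g in gaps)
    if total < n:
        raise ConfigurationError("not enough intergenic space for requested sites")
    cum = np.cumsum([g[2] for g in gaps])
    chosen: set[int] = set()
    while len(chosen) < n:
        draw = rng.integers(0, total, size=max(16, int((n - len(chosen)) * 1.2)))
        chosen.update(int(x) for x in draw)
        if len(chosen) > n:
            chosen = set(sorted(chosen)[:n])
    offsets = np.array(sorted(chosen), dtype=np.int64)
    gap_idx = np.searchsorted(cum, offsets, side="right")
    chroms = np.array([gaps[i][0] for i in gap_idx])
    within = offsets - np.concatenate(([0], cum))[gap_idx]
    pos = np.array([gaps[i][1] for i in gap_idx]) + within
    return chroms, pos


def gen_methylome_pair(
    config: SimulationConfig,
    genes: pd.DataFrame,
    truth_genes: pd.DataFrame,
    chrom_sizes: dict[str, int],
    rng: np.random.Generator,
) -> tuple[dict[str, SiteScoreTable], pd.DataFrame]:
    """Generate per-mark site score tables and the planted-site truth.

    Returns ``(tables_by_mark, planted_sites)``; planted sites carry their
    gene and direction, background sites (genic and intergenic) are not in
    the truth.
    """
    samples = _sample_names(config)
    tumor_cols = [s for s, (_, c) in samples.items() if c == "tumor"]
    normal_cols = [s for s, (_, c) in samples.items() if c == "normal"]
    tables: dict[str, SiteScoreTable] = {}
    truth_rows = []

    merged = genes.merge(truth_genes, on="gene_id", suffixes=("", "_t"))
    starts = merged["start"].to_numpy()
    lengths = (merged["end"] - merged["start"]).to_numpy()

    for mark in MARKS:
        up_counts = merged[f"n_up_{mark}"].to_numpy()
        down_counts = merged[f"n_down_{mark}"].to_numpy()
        bg_counts = rng.poisson(config.background_sites_per_gene, size=len(merged))
        need = up_counts + down_counts + bg_counts
        over = need > lengths
        if over.any():
            raise ConfigurationError(
                f"gene {merged['gene_id'].iloc[int(np.argmax(over))]} too short for "
                f"{int(need[over][0])} sites; widen gene_length_range"
            )
        chroms_l, pos_l, dir_l, gene_l = [], [], [], []
        for i in range(len(merged)):
            tot = int(need[i])
            if tot == 0:
                continue
            offs = rng.choice(int(lengths[i]), size=tot, replace=False)
            chroms_l.append(np.repeat(merged["chrom"].iloc[i], tot))
            pos_l.append(starts[i] + offs)
            dir_l.append(
                np.concatenate(
                    [
                        np.repeat("up", int(up_counts[i])),
                        np.repeat("down", int(down_counts[i])),
                        np.repeat("none", int(bg_counts[i])),
                    ]
                )
            )
            gene_l.append(np.repeat(merged["gene_id"].iloc[i], tot))
        chroms = np.concatenate(chroms_l) if chroms_l else np.array([], dtype=object)
        pos = np.concatenate(pos_l) if pos_l else np.array([], dtype=np.int64)
        direction = np.concatenate(dir_l) if dir_l else np.array([], dtype=object)
        gene_of = np.concatenate(gene_l) if gene_l else np.array([], dtype=object)

        f = config.intergenic_site_fraction
        n_inter = int(round(len(pos) * f / (1 - f))) if f < 1 else 0
        if n_inter:
            ichrom, ipos = _intergenic_positions(n_inter, genes, chrom_sizes, rng)
            chroms = np.concatenate([chroms, ichrom])
            pos = np.concatenate([pos, ipos])
            direction = np.concatenate([direction, np.repeat("none", n_inter)])
            gene_of = np.concatenate([gene_of, np.repeat("", n_inter)])

        n_sites = len(pos)
        planted = direction != "none"
        tumor = np.empty(n_sites)
        normal = np.empty(n_sites)
        if planted.any():
            tumor[planted], normal[planted] = _planted_scores(
                int(planted.sum()), direction[planted], config, rng
            )
        if (~planted).any():
            tumor[~planted], normal[~planted] = _background_scores(int((~planted).sum()), rng)

        data = pd.DataFrame({"chrom": chroms, "pos0": pos.astype(np.int64)})
        for col in tumor_cols:
            jit = np.where(planted, 0.0, rng.uniform(-0.005, 0.005, size=n_sites))
            data[col] = np.clip(tumor + jit, 0.0, 1.0)
        for col in normal_cols:
            jit = np.where(planted, 0.0, rng.uniform(-0.005, 0.005, size=n_sites))
            data[col] = np.clip(normal + jit, 0.0, 1.0)

        table = SiteScoreTable(mark=mark, data=data, samples=dict(samples)).validate()
        tables[mark] = table
        for i in np.flatnonzero(planted):
            truth_rows.append(
                {
                    "chrom": chroms[i],
                    "pos0": int(pos[i]),
                    "mark": mark,
                    "direction": direction[i],
                    "gene_id": gene_of[i],
                }
            )
    planted_sites = pd.DataFrame(
        truth_rows, columns=["chrom", "pos0", "mark", "direction", "gene_id"]
    )
    return tables, planted_sites


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def gen_expression(
    config: SimulationConfig,
    genes: pd.DataFrame,
    truth_genes: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Generate a gene-level count table (gene_id, length_bp, sample cols).

    Expected per-condition expression differs by exactly ``de_fold_change``
    for planted DE genes; counts are gamma-Poisson with the configured
    dispersion, or exactly equal to their expectation when dispersion is 0
    (the noiseless limit, emitted as non-integer counts).
    """
    merged = genes.merge(truth_genes[["gene_id", "de", "de_direction"]], on="gene_id")
    n = len(merged)
    lengths = (merged["end"] - merged["start"]).to_numpy(dtype=float)
    base = rng.lognormal(mean=np.log(50), sigma=1.0, size=n)
    fc = config.de_fold_change
    mult = np.where(
        merged["de_direction"] == "up", fc, np.where(merged["de_direction"] == "down", 1 / fc, 1.0)
    )
    expr = {"normal": base, "tumor": base * mult}
    # one global scale for every sample: per-condition totals may then differ
    # slightly, but per-gene expected count ratios stay exactly de_fold_change
    mass = {c: float((expr[c] * lengths).sum()) for c in expr}
    scale = config.library_size / np.mean(list(mass.values()))

    out = pd.DataFrame({"gene_id": merged["gene_id"], "length_bp": lengths.astype(np.int64)})
    for sample, (_, cond) in _sample_names(config).items():
        mu = expr[cond] * lengths * scale
        if config.dispersion == 0:
            counts = mu
        else:
            shape = 1.0 / config.dispersion
            lam = rng.gamma(shape, mu * config.dispersion)
            counts = rng.poisson(lam).astype(float)
        out[sample] = counts
    return out


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


def gen_survival(
    config: SimulationConfig, truth_genes: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Generate the survival table (sample_id, time_days, event, gene cols).

    Event times are exponential with per-patient hazard
    ``baseline * exp(hazard_log_hr * #effect-genes-in-low-half)``;
    censoring is independent with probability ``censor_rate``.
    """
    n = config.n_patients
    gene_ids = truth_genes["gene_id"].tolist()
    expr = rng.lognormal(mean=np.log(10), sigma=0.5, size=(n, len(gene_ids)))
    effect = truth_genes["survival_effect"].to_numpy(dtype=bool)
    low_burden = np.zeros(n)
    for j in np.flatnonzero(effect):
        low = expr[:, j] <= np.median(expr[:, j])
        low_burden += low
    hazard = config.baseline_hazard * np.exp(config.hazard_log_hr * low_burden)
    t_event = rng.exponential(scale=1.0 / hazard)
    censored = rng.random(n) < config.censor_rate
    t_obs = np.where(censored, t_event * rng.uniform(0.02, 1.0, size=n), t_event)
    t_obs = np.maximum(t_obs, 1e-6)
    meta = pd.DataFrame(
        {
            "sample_id": [f"PT{i + 1:04d}" for i in range(n)],
            "time_days": t_obs,
            "event": (~censored).astype(int),
        }
    )
    return pd.concat([meta, pd.DataFrame(expr, columns=gene_ids)], axis=1)


# ---------------------------------------------------------------------------
# whole-cohort driver
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    config: SimulationConfig
    genes: pd.DataFrame
    chrom_sizes: dict[str, int]
    site_tables: dict[str, SiteScoreTable]
    counts: pd.DataFrame
    survival: pd.DataFrame
    truth: GroundTruth
    samples: dict[str, tuple[str, str]]


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    names = ["annotation", "labels", "methylome", "expression", "survival"]
    return {n: np.random.Generator(np.random.PCG64(s)) for n, s in zip(names, root.spawn(len(names)))}


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate a full cohort in memory. Deterministic in ``config.seed``;
    each stage uses its own derived random stream."""
    rngs = _stage_rngs(config.seed)
    genes, chrom_sizes = gen_annotation(config, rngs["annotation"])
    truth_genes = gen_gene_labels(config, genes, rngs["labels"])
    truth_genes = gen_de_labels(config, truth_genes, rngs["labels"])
    truth_genes = assign_survival_effects(config, truth_genes, rngs["labels"])
    site_tables, planted_sites = gen_methylome_pair(
        config, genes, truth_genes, chrom_sizes, rngs["methylome"]
    )
    counts = gen_expression(config, genes, truth_genes, rngs["expression"])
    survival = gen_survival(config, truth_genes, rngs["survival"])
    return Cohort(
        config=config,
        genes=genes,
        chrom_sizes=chrom_sizes,
        site_tables=site_tables,
        counts=counts,
        survival=survival,
        truth=GroundTruth(genes=truth_genes, sites=planted_sites),
        samples=_sample_names(config),
    )


def write_cohort(cohort: Cohort, outdir) -> dict[str, str]:
    """Write all cohort files into *outdir*; returns the path map."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genes": os.path.join(outdir, "genes.bed"),
        "sites_5mC": os.path.join(outdir, "sites_5mC.tsv"),
        "sites_6mA": os.path.join(outdir, "sites_6mA.tsv"),
        "counts": os.path.join(outdir, "counts.tsv"),
        "survival": os.path.join(outdir, "survival.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
        "sample_sheet": os.path.join(outdir, "sample_sheet.tsv"),
    }
    write_gene_annotation(cohort.genes, paths["genes"])
    write_site_scores(cohort.site_tables["5mC"], paths["sites_5mC"])
    write_site_scores(cohort.site_tables["6mA"], paths["sites_6mA"])
    write_counts(cohort.counts, paths["counts"])
    write_survival(cohort.survival, paths["survival"])
    write_sample_sheet(cohort.samples, paths["sample_sheet"])
    truth = cohort.truth.to_dict()
    truth["config"] = dataclasses.asdict(cohort.config)
    truth["chrom_sizes"] = cohort.chrom_sizes
    write_json(truth, paths["truth"])
    return paths
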