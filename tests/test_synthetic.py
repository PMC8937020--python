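import dataclasses
import filecmp

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methpipe.differential import call_differential_sites
from methpipe.errors import ConfigurationError
from methpipe.synthetic import (
    SimulationConfig,
    draw_updown_counts,
    gen_annotation,
    gen_de_labels,
    gen_gene_labels,
    gen_survival,
    simulate_cohort,
    solve_mixture_weight,
    updown_correlation_of_weight,
    write_cohort,
)

from _oracles import rule_oracle


class TestConfig:
    def test_bad_biotype_sum(self):
        with pytest.raises(ConfigurationError, match="sum to 1"):
            SimulationConfig(biotype_fractions={"pc": 0.5, "pseudo": 0.4})

    def test_bad_fraction(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(censor_rate=1.5)

    def test_bad_count(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_genes=0)

    def test_unknown_key_rejected(self):
        with pytest.raises(ConfigurationError, match="frobnicate"):
            SimulationConfig.from_dict({"frobnicate": 1})

    def test_frac_unstable_shorthand(self):
        cfg = SimulationConfig.from_dict({"frac_unstable": 0.25})
        assert cfg.frac_unstable_5mC == pytest.approx(0.5)
        assert cfg.frac_unstable_6mA == pytest.approx(0.5)

    def test_unreachable_correlation_rejected(self):
        with pytest.raises(ConfigurationError, match="exceeds"):
            SimulationConfig(sites_per_gene_mean=4.0, updown_corr_6mA=0.9)


class TestCountModel:
    def test_weight_solves_closed_form(self):
        w = solve_mixture_weight(0.5, 10.0, 1.5)
        assert updown_correlation_of_weight(w, 10.0, 1.5) == pytest.approx(0.5, abs=1e-10)

    def test_zero_target_zero_weight(self):
        assert solve_mixture_weight(0.0, 10.0, 1.5) == 0.0

    def test_counts_at_least_one(self, rng):
        u, d = draw_updown_counts(500, 10.0, 1.5, 0.5, rng)
        assert u.min() >= 1 and d.min() >= 1

    def test_sample_correlation_near_target(self):
        mu, k = 15.0, 1.5
        w = solve_mixture_weight(0.85, mu, k)
        u, d = draw_updown_counts(2000, mu, k, w, np.random.default_rng(0))
        assert np.corrcoef(u, d)[0, 1] == pytest.approx(0.85, abs=0.05)


class TestAnnotation:
    def test_degenerate_fractions(self, rng):
        cfg = SimulationConfig(n_genes=10, biotype_fractions={"protein_coding": 1.0})
        genes, _ = gen_annotation(cfg, rng)
        assert (genes["biotype"] == "protein_coding").all()
        assert len(genes) == 10

    def test_genes_non_overlapping(self, rng):
        cfg = SimulationConfig(n_genes=200, n_chromosomes=3)
        genes, _ = gen_annotation(cfg, rng)
        for _, sub in genes.groupby("chrom"):
            sub = sub.sort_values("start")
            assert (sub["start"].to_numpy()[1:] >= sub["end"].to_numpy()[:-1]).all()

    def test_biotype_fraction_within_binomial_bounds(self, rng):
        cfg = SimulationConfig(
            n_genes=1000, biotype_fractions={"pc": 0.5, "pseudo": 0.5}
        )
        genes, _ = gen_annotation(cfg, rng)
        lo, hi = stats.binom.interval(0.99, 1000, 0.5)
        assert lo <= (genes["biotype"] == "pseudo").sum() <= hi

    def test_infeasible_packing_raises(self, rng):
        cfg = SimulationConfig(n_genes=50, n_chromosomes=1, chromosome_length=10_000)
        with pytest.raises(ConfigurationError, match="pack"):
            gen_annotation(cfg, rng)


class TestLabels:
    def _genes(self, n):
        return pd.DataFrame({"gene_id": [f"G{i}" for i in range(n)], "biotype": "pc"})

    def test_labelled_genes_have_both_directions(self, rng):
        cfg = SimulationConfig(n_genes=500)
        t = gen_gene_labels(cfg, self._genes(500), rng)
        for mark in ("5mC", "6mA"):
            lab = t[t[f"unstable_{mark}"]]
            assert (lab[f"n_up_{mark}"] >= 1).all()
            assert (lab[f"n_down_{mark}"] >= 1).all()
            unlab = t[~t[f"unstable_{mark}"]]
            assert (unlab[[f"n_up_{mark}", f"n_down_{mark}"]] == 0).all().all()

    def test_dual_unstable_is_conjunction(self, rng):
        t = gen_gene_labels(SimulationConfig(n_genes=300), self._genes(300), rng)
        assert (t["unstable"] == (t["unstable_5mC"] & t["unstable_6mA"])).all()

    def test_de_coupling_null_independent(self):
        """OR=1: planted DE independent of instability (type-I check)."""
        cfg = SimulationConfig(n_genes=2000)
        sig = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            t = gen_de_labels(cfg, gen_gene_labels(cfg, self._genes(2000), rng), rng)
            tab = pd.crosstab(t["unstable_6mA"], t["de"]).to_numpy()
            p = stats.chi2_contingency(tab, correction=False).pvalue
            sig += p < 0.05
        assert sig <= max(5, int(0.05 * n_seeds) + 3)  # ~binomial(40, .05) upper tail


class TestMethylome:
    def test_null_methylome_no_differential_sites(self):
        cfg = SimulationConfig(seed=2, n_genes=60, frac_unstable_5mC=0.0, frac_unstable_6mA=0.0)
        cohort = simulate_cohort(cfg)
        for mark in ("5mC", "6mA"):
            assert len(call_differential_sites(cohort.site_tables[mark])) == 0

    def test_planted_rule_consistency(self, small_cohort):
        """Every planted site passes, every background site fails, the rules
        as re-checked by the independent oracle on condition means."""
        planted = small_cohort.truth.sites.set_index(["chrom", "pos0", "mark"])
        for mark in ("5mC", "6mA"):
            table = small_cohort.site_tables[mark]
            tcols = table.samples_for("tumor")
            ncols = table.samples_for("normal")
            t = table.data[tcols].mean(axis=1).to_numpy()
            n = table.data[ncols].mean(axis=1).to_numpy()
            for i in range(len(table)):
                key = (table.data["chrom"].iat[i], int(table.data["pos0"].iat[i]), mark)
                verdict = rule_oracle(t[i], n[i])
                if key in planted.index:
                    assert verdict == planted.loc[key, "direction"]
                else:
                    assert verdict is None

    def test_correlation_targeting(self):
        cfg = SimulationConfig(
            seed=9,
            n_genes=2000,
            sites_per_gene_mean=30.0,
            frac_unstable_5mC=1.0,
            frac_unstable_6mA=1.0,
            updown_corr_5mC=0.15,
            updown_corr_6mA=0.85,
        )
        rng = np.random.default_rng(9)
        genes = pd.DataFrame({"gene_id": [f"G{i}" for i in range(2000)], "biotype": "pc"})
        t = gen_gene_labels(cfg, genes, rng)
        for mark, target in (("5mC", 0.15), ("6mA", 0.85)):
            r = np.corrcoef(t[f"n_up_{mark}"], t[f"n_down_{mark}"])[0, 1]
            assert r == pytest.approx(target, abs=0.05)

    def test_scores_in_unit_interval(self, small_cohort):
        for mark in ("5mC", "6mA"):
            s = small_cohort.site_tables[mark].scores()
            assert s.min() >= 0 and s.max() <= 1


class TestExpressionGen:
    def test_noiseless_rpkm_ratio_exact(self, small_cohort):
        """dispersion=0 -> condition-mean RPKM ratio is exactly the planted
        fold change for DE genes and exactly 1 otherwise."""
        from methpipe.expression import compute_rpkm

        # equal library sizes isolate the per-gene ratios from composition
        # effects of the differing per-condition column totals
        lib = {s: small_cohort.config.library_size for s in small_cohort.samples}
        rpkm = compute_rpkm(small_cohort.counts, library_sizes=lib)
        truth = small_cohort.truth.genes.set_index("gene_id")
        tcols = [s for s, (_, c) in small_cohort.samples.items() if c == "tumor"]
        ncols = [s for s, (_, c) in small_cohort.samples.items() if c == "normal"]
        mt = rpkm[tcols].mean(axis=1).to_numpy()
        mn = rpkm[ncols].mean(axis=1).to_numpy()
        ratio = mt / mn
        fc = small_cohort.config.de_fold_change
        for i, g in enumerate(rpkm["gene_id"]):
            d = truth.loc[g, "de_direction"]
            expect = fc if d == "up" else (1 / fc if d == "down" else 1.0)
            assert ratio[i] == pytest.approx(expect, rel=1e-9)

    def test_equal_libraries_rpkm_proportional_to_counts(self, rng):
        from methpipe.expression import compute_rpkm
        from methpipe.synthetic import gen_expression

        cfg = SimulationConfig(seed=1, n_genes=50, dispersion=0.0)
        genes = pd.DataFrame(
            {
                "gene_id": [f"G{i}" for i in range(50)],
                "chrom": "chr1",
                "start": 0,
                "end": 1000,  # equal lengths
                "strand": "+",
                "biotype": "pc",
            }
        )
        truth = pd.DataFrame(
            {"gene_id": genes["gene_id"], "de": False, "de_direction": "none"}
        )
        counts = gen_expression(cfg, genes, truth, rng)
        rpkm = compute_rpkm(counts)
        for s in ("P1_T", "P1_N"):
            c = counts[s].to_numpy()
            r = rpkm[s].to_numpy()
            assert np.allclose(r / r.sum(), c / c.sum())


class TestSurvivalGen:
    def test_no_censoring_all_events(self, rng):
        cfg = SimulationConfig(n_patients=100, censor_rate=0.0)
        truth = pd.DataFrame({"gene_id": ["G1"], "survival_effect": [False]})
        surv = gen_survival(cfg, truth, rng)
        assert (surv["event"] == 1).all()

    def test_null_logrank_calibrated(self):
        """hazard_log_hr=0: median-split log-rank rejects at ~alpha."""
        from methpipe.survival import screen_genes

        cfg = SimulationConfig(n_patients=150, hazard_log_hr=0.0, censor_rate=0.2)
        truth = pd.DataFrame({"gene_id": ["G1"], "survival_effect": [True]})
        n_seeds, rejected = 60, 0
        for seed in range(n_seeds):
            surv = gen_survival(cfg, truth, np.random.default_rng(seed))
            out = screen_genes(surv, ["G1"])
            rejected += bool(out["selected"].iloc[0])
        assert rejected <= 7  # ~= binom(60, 0.05) 99.9% upper tail


class TestDeterminism:
    def test_identical_config_byte_identical_outputs(self, tmp_path):
        cfg = SimulationConfig(seed=21, n_genes=40, n_patients=40)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_cohort(simulate_cohort(cfg), d1)
        write_cohort(simulate_cohort(cfg), d2)
        for name in [
            "genes.bed",
            "sites_5mC.tsv",
            "sites_6mA.tsv",
            "counts.tsv",
            "survival.tsv",
            "truth.json",
            "sample_sheet.tsv",
        ]:
            assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name

    def test_different_seed_differs(self, tmp_path):
        c1 = simulate_cohort(SimulationConfig(seed=1, n_genes=40))
        c2 = simulate_cohort(SimulationConfig(seed=2, n_genes=40))
        assert not c1.counts.equals(c2.counts)
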