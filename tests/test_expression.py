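import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from methpipe.errors import ConfigurationError, DataFormatError
from methpipe.expression import (
    association_report,
    build_contingency,
    call_de_genes,
    chi_square_test,
    class_membership,
    compute_rpkm,
)

from _oracles import chi2_2x2_closed_form

SAMPLES = {
    "P1_T": ("P1", "tumor"),
    "P1_N": ("P1", "normal"),
    "P2_T": ("P2", "tumor"),
    "P2_N": ("P2", "normal"),
}


def counts_df(counts, lengths):
    df = pd.DataFrame(counts, columns=list(SAMPLES))
    df.insert(0, "length_bp", lengths)
    df.insert(0, "gene_id", [f"G{i}" for i in range(len(df))])
    return df


class TestRPKM:
    def test_formula(self):
        c = counts_df([[10, 10, 10, 10]], [1000])
        r = compute_rpkm(c, library_sizes={s: 1e6 for s in SAMPLES})
        assert r.loc[0, "P1_T"] == pytest.approx(10.0)

    def test_zero_count(self):
        c = counts_df([[0, 5, 5, 5], [10, 5, 5, 5]], [1000, 1000])
        assert compute_rpkm(c).loc[0, "P1_T"] == 0.0

    def test_zero_library_raises(self):
        c = counts_df([[0, 5, 5, 5]], [1000])
        with pytest.raises(DataFormatError, match="library"):
            compute_rpkm(c)

    @given(st.integers(0, 2**32))
    @settings(max_examples=30, deadline=None)
    def test_conservation_identity(self, seed):
        """sum_g rpkm*length*lib/1e9 == column sum of counts, per sample."""
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 40)
        c = counts_df(rng.integers(0, 1000, size=(n, 4)) + 1, rng.integers(200, 9000, size=n))
        r = compute_rpkm(c)
        lens = c["length_bp"].to_numpy(float)
        for s in SAMPLES:
            lib = c[s].sum()
            back = (r[s].to_numpy() * lens * lib / 1e9).sum()
            assert back == pytest.approx(lib, rel=1e-9)


class TestDECalling:
    def test_fold_four_up(self):
        rpkm = pd.DataFrame({"gene_id": ["G0"], "P1_T": [20.0], "P1_N": [5.0]})
        out = call_de_genes(rpkm, {"P1_T": ("P1", "tumor"), "P1_N": ("P1", "normal")}, pseudocount=0)
        assert out.loc[0, "de"] and out.loc[0, "de_direction"] == "up"
        assert out.loc[0, "fold_change"] == pytest.approx(4.0)

    def test_exact_threshold_not_de(self):
        rpkm = pd.DataFrame({"gene_id": ["G0"], "P1_T": [10.0], "P1_N": [5.0]})
        out = call_de_genes(rpkm, {"P1_T": ("P1", "tumor"), "P1_N": ("P1", "normal")}, pseudocount=0)
        assert not out.loc[0, "de"]

    def test_down_direction(self):
        rpkm = pd.DataFrame({"gene_id": ["G0"], "P1_T": [1.0], "P1_N": [10.0]})
        out = call_de_genes(rpkm, {"P1_T": ("P1", "tumor"), "P1_N": ("P1", "normal")}, pseudocount=0)
        assert out.loc[0, "de_direction"] == "down"

    def test_missing_condition_raises(self):
        rpkm = pd.DataFrame({"gene_id": ["G0"], "P1_T": [1.0]})
        with pytest.raises(ConfigurationError):
            call_de_genes(rpkm, {"P1_T": ("P1", "tumor")})

    def test_recovers_planted_de_noiseless(self, small_cohort):
        rpkm = compute_rpkm(small_cohort.counts)
        out = call_de_genes(rpkm, small_cohort.samples)
        truth = small_cohort.truth.genes
        got = out.set_index("gene_id")
        for row in truth.itertuples():
            assert got.loc[row.gene_id, "de"] == row.de
            if row.de:
                assert got.loc[row.gene_id, "de_direction"] == row.de_direction


class TestContingency:
    LABELS = pd.DataFrame(
        {
            "gene_id": ["A", "B", "C", "D"],
            "has_5mC_up": [True, True, False, False],
            "has_5mC_down": [False, False, False, False],
            "has_6mA_up": [False] * 4,
            "has_6mA_down": [False] * 4,
            "unstable": [False] * 4,
        }
    )
    DE = pd.DataFrame(
        {"gene_id": ["A", "B", "C", "D"], "de": [False, True, True, False],
         "de_direction": ["none", "up", "up", "none"]}
    )

    def test_enumeration(self):
        ct = build_contingency(self.LABELS, self.DE, "5mC", "mark_up_specific", ["A", "B", "C", "D"])
        assert ct.table.tolist() == [[1, 1], [1, 1]]

    def test_cells_sum_to_universe(self, rng):
        n = 200
        labels = pd.DataFrame(
            {
                "gene_id": [f"G{i}" for i in range(n)],
                "has_5mC_up": rng.random(n) < 0.5,
                "has_5mC_down": rng.random(n) < 0.5,
                "has_6mA_up": rng.random(n) < 0.5,
                "has_6mA_down": rng.random(n) < 0.5,
            }
        )
        labels["unstable"] = labels.iloc[:, 1:5].all(axis=1)
        de = pd.DataFrame(
            {"gene_id": labels["gene_id"], "de": rng.random(n) < 0.3,
             "de_direction": "none"}
        )
        ct = build_contingency(labels, de, "6mA", "mark_both_updown", labels["gene_id"])
        assert ct.table.sum() == n

    def test_class_equals_universe_degenerate_flagged(self):
        labels = self.LABELS.copy()
        labels[["has_5mC_up"]] = True
        ct = build_contingency(labels, self.DE, "5mC", "mark_up_specific", ["A", "B", "C", "D"])
        assert ct.degenerate_margin

    def test_empty_universe_raises(self):
        with pytest.raises(DataFormatError):
            build_contingency(self.LABELS, self.DE, "5mC", "mark_up_specific", [])

    def test_class_specs(self):
        labels = pd.DataFrame(
            {
                "gene_id": ["A"],
                "has_5mC_up": [True],
                "has_5mC_down": [True],
                "has_6mA_up": [False],
                "has_6mA_down": [False],
                "unstable": [False],
            }
        )
        assert not class_membership(labels, "5mC", "mark_up_specific").loc["A"]
        assert class_membership(labels, "5mC", "mark_both_updown").loc["A"]


class TestChiSquare:
    def test_hand_derived_example(self):
        # closed form: 60*(10*10-20*20)^2/(30*30*30*30) = 6.66667
        stat, df, p = chi_square_test([[10, 20], [20, 10]])
        assert stat == pytest.approx(6.666667, abs=1e-5)
        assert df == 1
        assert p == pytest.approx(stats.chi2.sf(20 / 3, 1), rel=1e-9)
        assert p == pytest.approx(9.8232e-3, rel=1e-4)

    def test_independence_statistic_zero(self):
        stat, _, p = chi_square_test([[15, 15], [15, 15]])
        assert stat == 0.0
        assert p == 1.0

    @given(st.integers(0, 2**32))
    @settings(max_examples=50, deadline=None)
    def test_transpose_invariance(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(1, 100, size=(2, 2))
        assert chi_square_test(t)[0] == pytest.approx(chi_square_test(t.T)[0], rel=1e-12)

    @given(st.integers(0, 2**32))
    @settings(max_examples=100, deadline=None)
    def test_matches_2x2_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(1, 500, size=4)
        stat, _, _ = chi_square_test([[a, b], [c, d]])
        assert stat == pytest.approx(chi2_2x2_closed_form(a, b, c, d), rel=1e-9)

    def test_matches_scipy(self, rng):
        t = rng.integers(5, 200, size=(3, 4))
        stat, df, p = chi_square_test(t)
        ref = stats.chi2_contingency(t, correction=False)
        assert stat == pytest.approx(ref.statistic, rel=1e-12)
        assert df == ref.dof
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_yates_matches_scipy(self, rng):
        t = rng.integers(5, 200, size=(2, 2))
        stat, _, _ = chi_square_test(t, yates=True)
        ref = stats.chi2_contingency(t, correction=True)
        assert stat == pytest.approx(ref.statistic, rel=1e-12)

    def test_zero_expected_raises(self):
        with pytest.raises(DataFormatError):
            chi_square_test([[0, 0], [5, 5]])

    def test_low_expected_warns(self):
        with pytest.warns(UserWarning, match="below 5"):
            chi_square_test([[1, 2], [2, 1]])


class TestAssociationReport:
    def test_empty_de_set_surfaces_degenerate(self):
        labels = TestContingency.LABELS
        de = TestContingency.DE.copy()
        de["de"] = False
        rep = association_report(labels, de, ["A", "B", "C", "D"])
        assert all("error" in t or t.get("degenerate_margin") for t in rep["tests"])

    def test_unstable_de_fraction(self):
        labels = TestContingency.LABELS.copy()
        labels.loc[0, "unstable"] = True
        labels.loc[1, "unstable"] = True
        rep = association_report(labels, TestContingency.DE, ["A", "B", "C", "D"])
        assert rep["unstable_de_fraction"] == pytest.approx(0.5)  # B de, A not

    def test_planted_odds_ratio_recovered(self):
        """Sample OR of the contingency table within +-20% of the planted OR."""
        from methpipe.gene_mapping import PROFILE_COLUMNS
        from methpipe.instability import classify_genes
        from methpipe.synthetic import SimulationConfig, gen_de_labels, gen_gene_labels

        cfg = SimulationConfig(
            seed=5,
            n_genes=5000,
            de_coupling_odds_ratio_5mC=3.0,
            de_coupling_odds_ratio_6mA=1.0,
        )
        rng = np.random.default_rng(5)
        genes = pd.DataFrame(
            {"gene_id": [f"G{i}" for i in range(cfg.n_genes)], "biotype": "pc"}
        )
        truth = gen_de_labels(cfg, gen_gene_labels(cfg, genes, rng), rng)
        profiles = truth.rename(columns={})[
            ["gene_id", "n_up_5mC", "n_down_5mC", "n_up_6mA", "n_down_6mA"]
        ].copy()
        profiles["total"] = profiles.iloc[:, 1:5].sum(axis=1)
        labels = classify_genes(profiles[PROFILE_COLUMNS])
        de = truth[["gene_id", "de", "de_direction"]]
        ct = build_contingency(labels, de, "5mC", "mark_both_updown", truth["gene_id"])
        assert ct.odds_ratio() == pytest.approx(3.0, rel=0.20)
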