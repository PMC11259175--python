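"""Normalization, NB GLM differential expression, pair-group rules, tau, and
the categorical tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ohnoscope.collinearity import OhnologPair
from ohnoscope.expression import (CONTRASTS, categorical_preference,
                                  classify_pair_groups,
                                  filter_expressed_pairs, normalize_counts,
                                  pair_correlation, tau_class_tests,
                                  tau_index)
from ohnoscope.expression import test_de as run_de
from ohnoscope.simulate import make_sample_sheet


def _null_counts(rng, n_genes, samples, dispersion=0.1, base_sd=0.7):
    base = rng.lognormal(np.log(100), base_sd, n_genes)
    r = 1 / dispersion
    mu = np.tile(base[:, None], (1, len(samples)))
    counts = rng.negative_binomial(r, r / (r + mu))
    return pd.DataFrame(counts, index=[f"g{i}" for i in range(n_genes)],
                        columns=samples.index), mu


class TestNormalizeCounts:
    def test_equal_libraries_unit_size_factors(self):
        samples = make_sample_sheet(1)
        counts = pd.DataFrame(
            np.tile([[10], [20], [30]], (1, 4)),
            index=["a", "b", "c"], columns=samples.index)
        norm = normalize_counts(counts)
        assert np.allclose(norm["size_factors"], 1.0)

    def test_doubled_column_doubles_size_factor(self):
        samples = make_sample_sheet(1)
        base = np.tile([[10], [20], [30]], (1, 4))
        base[:, 1] *= 2
        counts = pd.DataFrame(base, index=["a", "b", "c"],
                              columns=samples.index)
        sf = normalize_counts(counts)["size_factors"]
        assert sf.iloc[1] == pytest.approx(2 * sf.iloc[0])

    def test_fpkm_hand_formula(self):
        samples = make_sample_sheet(1)
        # equal libraries of 1e6, 1-kb gene with 10 counts -> FPKM 10
        counts = pd.DataFrame(
            {s: [10, 10 ** 6 - 10] for s in samples.index},
            index=["g1", "rest"])
        norm = normalize_counts(counts, {"g1": 1000, "rest": 1000})
        assert norm["fpkm"].loc["g1"].iloc[0] == pytest.approx(10.0)

    def test_all_zero_matrix_errors(self):
        samples = make_sample_sheet(1)
        counts = pd.DataFrame(0, index=["a"], columns=samples.index)
        with pytest.raises(ValueError, match="all-zero"):
            normalize_counts(counts)


class TestDifferentialExpression:
    def test_type_one_error_controlled(self):
        rng = np.random.default_rng(11)
        samples = make_sample_sheet(3)
        counts, _ = _null_counts(rng, 800, samples)
        res = run_de(counts, samples, "L-28")
        frac = (res["pvalue"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07
        assert (res["status"] == "ns").mean() > 0.99

    def test_power_and_direction_on_planted_shift(self):
        rng = np.random.default_rng(12)
        samples = make_sample_sheet(3)
        counts, mu = _null_counts(rng, 400, samples)
        cells = (samples["lifestyle"] + ":"
                 + samples["temperature"].astype(str)).to_numpy()
        mu2 = mu.copy()
        mu2[:40, cells == "symbiotic:28"] *= 2 ** 3
        r = 1 / 0.1
        counts = pd.DataFrame(
            rng.negative_binomial(r, r / (r + mu2)),
            index=counts.index, columns=counts.columns)
        res = run_de(counts, samples, "L-28")
        planted = res.iloc[:40]
        assert (planted["pvalue"] < 0.05).mean() >= 0.9
        assert (planted["status"] == "up").mean() >= 0.9
        assert planted["log2fc"].mean() == pytest.approx(3.0, abs=0.5)

    def test_status_invariant_and_bh_monotonicity(self):
        rng = np.random.default_rng(13)
        samples = make_sample_sheet(3)
        counts, _ = _null_counts(rng, 300, samples)
        res = run_de(counts, samples, "T-Fr")
        up = (res["fdr"] < 0.01) & (res["log2fc"] > 1)
        down = (res["fdr"] < 0.01) & (res["log2fc"] < -1)
        assert (res["status"] == np.where(up, "up",
                                          np.where(down, "down", "ns"))).all()
        assert (res["fdr"] >= res["pvalue"] - 1e-12).all()

    def test_unknown_contrast_rejected(self):
        samples = make_sample_sheet(2)
        counts, _ = _null_counts(np.random.default_rng(0), 50, samples)
        with pytest.raises(ValueError, match="unknown contrast"):
            run_de(counts, samples, "L-30")


class TestFilterExpressedPairs:
    def test_hand_enumeration(self):
        samples = make_sample_sheet(3)   # 12 samples
        data = {
            "a1": [12] * 6 + [0] * 6,    # >=10 in exactly half the samples
            "a2": [15] * 12,
            "b1": [9] * 12,              # never reaches 10
            "b2": [50] * 12,
            "c1": [0] * 12,
            "c2": [20] * 12,
        }
        counts = pd.DataFrame(data, index=samples.index).T
        pairs = [OhnologPair("a1", "a2"), OhnologPair("b1", "b2"),
                 OhnologPair("c1", "c2")]
        kept = filter_expressed_pairs(counts, pairs)
        assert {p.key for p in kept} == {("a1", "a2")}


def _de_tables(status_by_gene):
    """DE result stubs: {gene: {contrast: 'up'/'down'}} -> contrast frames."""
    genes = sorted(status_by_gene)
    out = {}
    for c in CONTRASTS:
        st = [status_by_gene[g].get(c, "ns") for g in genes]
        out[c] = pd.DataFrame({"status": st,
                               "log2fc": [2.0 if s == "up" else -2.0
                                          if s == "down" else 0.0 for s in st],
                               "fdr": [1e-4 if s != "ns" else 0.9
                                       for s in st]},
                              index=pd.Index(genes, name="gene_id"))
    return out


class TestClassifyPairGroups:
    @pytest.mark.parametrize("da,db,expected", [
        ({}, {}, 1),
        ({"L-28": "up"}, {}, 2),
        ({"T-Sy": "up"}, {"T-Sy": "up"}, 3),
        ({"L-28": "up"}, {"L-34": "down"}, 4),
        ({"L-34": "up"}, {"L-34": "down"}, 5),
        # opposing beats parallel when both occur
        ({"L-28": "up", "L-34": "up"}, {"L-28": "up", "L-34": "down"}, 5),
        ({"L-28": "down"}, {"L-28": "down", "T-Fr": "up"}, 3),
    ])
    def test_rules(self, da, db, expected):
        de = _de_tables({"A": da, "B": db})
        out = classify_pair_groups(de, [OhnologPair("A", "B")])
        assert out["group"].tolist() == [expected]

    def test_partition_property(self, sim_experiment):
        from ohnoscope.expression import test_all_contrasts as run_all
        de = run_all(sim_experiment["counts"],
                                sim_experiment["samples"])
        truth = sim_experiment["truth"]
        pairs = [OhnologPair(r.gene_a, r.gene_b)
                 for r in truth.wgd_pairs.itertuples(index=False)]
        pairs = [p for p in pairs
                 if all(p.gene_a in de[c].index and p.gene_b in de[c].index
                        for c in CONTRASTS)]
        out = classify_pair_groups(de, pairs)
        assert len(out) == len(pairs)
        assert out["group"].isin([1, 2, 3, 4, 5]).all()

    def test_missing_gene_errors(self):
        de = _de_tables({"A": {}})
        with pytest.raises(ValueError, match="missing"):
            classify_pair_groups(de, [OhnologPair("A", "Z")])


class TestPairCorrelation:
    def test_boundary_values_and_hand_formula(self):
        samples = make_sample_sheet(1)
        expr = pd.DataFrame(
            {"s": [1.0, 2.0, 3.0, 4.0], "t": [2.0, 4.0, 6.0, 8.0],
             "u": [4.0, 3.0, 2.0, 1.0], "v": [1.0, 3.0, 2.0, 5.0]},
            index=samples.index).T
        assert pair_correlation(expr, OhnologPair("s", "t")) == pytest.approx(1.0)
        assert pair_correlation(expr, OhnologPair("s", "u")) == pytest.approx(-1.0)
        expected = np.corrcoef(expr.loc["s"], expr.loc["v"])[0, 1]
        assert pair_correlation(expr, OhnologPair("s", "v")) == \
            pytest.approx(expected)

    def test_zero_variance_flagged(self):
        samples = make_sample_sheet(1)
        expr = pd.DataFrame({"s": [1.0] * 4, "t": [1, 2, 3, 4]},
                            index=samples.index).T
        assert np.isnan(pair_correlation(expr, OhnologPair("s", "t")))


class TestTauIndex:
    def _frame(self, per_condition, samples):
        # expand condition means to replicate columns
        cells = (samples["lifestyle"] + ":"
                 + samples["temperature"].astype(str))
        vals = [per_condition[c] for c in cells]
        return pd.DataFrame({"g": vals}, index=samples.index).T

    def test_uniform_expression_tau_zero(self):
        samples = make_sample_sheet(2)
        lf = self._frame({c: 2.0 for c in
                          ["free:28", "free:34", "symbiotic:28",
                           "symbiotic:34"]}, samples)
        res = tau_index(lf, samples)
        assert res.loc["g", "tau"] == 0.0 and res.loc["g", "eligible"]

    def test_single_condition_tau_one(self):
        samples = make_sample_sheet(2)
        lf = self._frame({"free:28": 3.0, "free:34": 0.0, "symbiotic:28": 0.0,
                          "symbiotic:34": 0.0}, samples)
        res = tau_index(lf, samples)
        assert res.loc["g", "tau"] == 1.0
        assert res.loc["g", "peak_condition"] == "free:28"

    def test_hand_computed_value(self):
        samples = make_sample_sheet(2)
        lf = self._frame({"free:28": 1.0, "free:34": 0.5, "symbiotic:28": 0.0,
                          "symbiotic:34": 0.0}, samples)
        res = tau_index(lf, samples, eligibility_cutoff=0.9)
        assert res.loc["g", "tau"] == pytest.approx(2.5 / 3)

    def test_eligibility_threshold(self):
        samples = make_sample_sheet(2)
        lf = self._frame({"free:28": 0.8, "free:34": 0.1, "symbiotic:28": 0.0,
                          "symbiotic:34": 0.0}, samples)
        res = tau_index(lf, samples)
        assert not res.loc["g", "eligible"]
        assert np.isnan(res.loc["g", "tau"])

    def test_scale_invariance_and_concentration_monotonicity(self):
        samples = make_sample_sheet(2)
        base = {"free:28": 2.0, "free:34": 1.0, "symbiotic:28": 0.5,
                "symbiotic:34": 0.25}
        t1 = tau_index(self._frame(base, samples), samples).loc["g", "tau"]
        scaled = {k: 3 * v for k, v in base.items()}
        t2 = tau_index(self._frame(scaled, samples), samples).loc["g", "tau"]
        assert t1 == pytest.approx(t2)
        concentrated = {"free:28": 2.0, "free:34": 1.0, "symbiotic:28": 0.0,
                        "symbiotic:34": 0.0}
        t3 = tau_index(self._frame(concentrated, samples),
                       samples).loc["g", "tau"]
        assert t3 > t1


class TestTauClassTests:
    def test_shifted_class_detected(self):
        rng = np.random.default_rng(21)
        n = 60
        tau = pd.DataFrame({
            "tau": np.concatenate([rng.uniform(0.1, 0.5, n),
                                   rng.uniform(0.6, 1.0, n)]),
            "eligible": True,
        }, index=[f"g{i}" for i in range(2 * n)])
        classes = pd.DataFrame({
            "gene_id": tau.index,
            "category": ["singleton"] * n + ["wgd_segmental"] * n})
        out = tau_class_tests(tau, classes)
        assert out["kruskal_p"] < 1e-5
        assert out["pairwise"][0]["p_holm"] < 1e-5

    def test_two_class_agreement_with_wilcoxon(self):
        rng = np.random.default_rng(22)
        tau = pd.DataFrame({
            "tau": np.concatenate([rng.uniform(0, 0.3, 30),
                                   rng.uniform(0.7, 1.0, 30)]),
            "eligible": True}, index=[f"g{i}" for i in range(60)])
        classes = pd.DataFrame({"gene_id": tau.index,
                                "category": ["a"] * 30 + ["b"] * 30})
        out = tau_class_tests(tau, classes)
        # both the omnibus and the single pairwise test reject
        assert (out["kruskal_p"] < 0.05) == (out["pairwise"][0]["p_holm"] < 0.05)


class TestCategoricalPreference:
    def test_proportional_table_null(self):
        t = pd.DataFrame([[10, 20], [20, 40]])
        res = categorical_preference(t)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)
        assert np.allclose(res.residuals, 0.0, atol=1e-9)

    def test_hand_computed_two_by_two(self):
        res = categorical_preference(pd.DataFrame([[20, 10], [10, 20]]))
        assert res.chi2 == pytest.approx(6.667, abs=1e-3)
        # standardized residual: (20-15)/sqrt(15*0.5*0.5) = 2.582
        assert res.residuals.iloc[0, 0] == pytest.approx(2.582, abs=1e-3)
        assert res.cell_pvalues.iloc[0, 0] == pytest.approx(
            min(1.0, 4 * 2 * stats.norm.sf(2.5819888974)), abs=1e-6)

    def test_single_row_errors(self):
        with pytest.raises(ValueError, match="2x2"):
            categorical_preference(pd.DataFrame([[5, 5]]))

    def test_zero_expected_errors(self):
        with pytest.raises(ValueError, match="merge"):
            categorical_preference(pd.DataFrame([[0, 0], [1, 2]]))
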