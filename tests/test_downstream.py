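"""Stratification, AUC, survival, chemoresponse and instability metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from ripscore.containers import RipscoreWarning
from ripscore.downstream import (
    cnd,
    contingency_fold,
    cox_multivariate,
    km_logrank,
    mutation_counts,
    pcr_rates,
    rate_fold,
    rf_pcr_comparison,
    roc_auc,
    stratify_sign,
    stratify_tertiles,
)


def series(values, prefix="s"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))],
                     dtype=float)


class TestStratify:
    def test_sign_partition(self):
        groups = stratify_sign(series([-1.0, 2.0]))
        assert list(groups["low"]) == ["s0"]
        assert list(groups["high"]) == ["s1"]

    def test_all_negative_warns_empty_high(self):
        with pytest.warns(RipscoreWarning, match="high group"):
            groups = stratify_sign(series([-1.0, -2.0]))
        assert len(groups["high"]) == 0

    def test_zero_goes_low_with_warning(self):
        with pytest.warns(RipscoreWarning, match="0"):
            groups = stratify_sign(series([0.0, 1.0]))
        assert "s0" in groups["low"]

    def test_sign_counts_match_naive_filter(self, rng):
        scores = series(rng.normal(size=200))
        groups = stratify_sign(scores)
        assert len(groups["high"]) == int((scores > 0).sum())
        assert len(groups["low"]) == int((scores <= 0).sum())

    def test_tertiles_hand_case(self):
        groups = stratify_tertiles(series(np.arange(1.0, 10.0)))
        assert list(groups["low"]) == ["s0", "s1", "s2"]
        assert list(groups["intermediate"]) == ["s3", "s4", "s5"]
        assert list(groups["high"]) == ["s6", "s7", "s8"]

    def test_tertiles_constant_scores_collapse_low(self):
        with pytest.warns(RipscoreWarning, match="degenerate"):
            groups = stratify_tertiles(series([2.0, 2.0, 2.0]))
        assert len(groups["low"]) == 3

    @pytest.mark.parametrize("n", [30, 31, 32, 100])
    def test_tertile_sizes_nearly_equal_for_distinct_values(self, n, rng):
        scores = series(rng.permutation(np.arange(n, dtype=float)))
        sizes = sorted(len(v) for v in stratify_tertiles(scores).values())
        assert sizes[-1] - sizes[0] <= 1

    @pytest.mark.parametrize("fn", [stratify_sign, stratify_tertiles])
    def test_partitions_are_disjoint_and_exhaustive(self, fn, rng):
        scores = series(rng.normal(size=100))
        groups = fn(scores)
        combined = [i for idx in groups.values() for i in idx]
        assert sorted(combined) == sorted(scores.index)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_random_scores_near_half(self, rng):
        labels = rng.integers(0, 2, 2000)
        scores = rng.normal(size=2000)
        assert roc_auc(labels, scores) == pytest.approx(0.5, abs=0.05)

    def test_matches_pairwise_oracle(self, rng):
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        scores = rng.choice([0.1, 0.2, 0.3, 0.4], size=40)  # forces ties
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert roc_auc(labels, scores) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        labels = rng.integers(0, 2, 300)
        labels[:2] = [0, 1]
        scores = rng.normal(size=300) + labels
        assert roc_auc(labels, scores) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)

    def test_complement_identity(self, rng):
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        scores = rng.normal(size=50)  # continuous: no ties
        assert roc_auc(labels, scores) + roc_auc(labels, -scores) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])


class TestKmLogrank:
    def test_identical_groups_statistic_near_zero(self):
        time = pd.Series([3.0, 5.0, 8.0, 3.0, 5.0, 8.0], index=list("abcdef"))
        event = pd.Series([1, 0, 1, 1, 0, 1], index=list("abcdef"))
        groups = {"x": pd.Index(list("abc")), "y": pd.Index(list("def"))}
        res = km_logrank(groups, time, event)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_two_group_statistic(self):
        # O_A = 3, E_A = 1.15, V = 0.6775 -> chi2 = 1.85^2 / 0.6775
        time = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], index=list("abcdef"))
        event = pd.Series([1] * 6, index=list("abcdef"))
        groups = {"A": pd.Index(list("abc")), "B": pd.Index(list("def"))}
        res = km_logrank(groups, time, event)
        assert res.statistic == pytest.approx(1.85**2 / 0.6775, abs=1e-6)

    def test_invariant_to_sample_ordering(self, rng):
        n = 60
        idx = pd.Index([f"s{i}" for i in range(n)])
        time = pd.Series(rng.exponential(10, n), index=idx)
        event = pd.Series(rng.integers(0, 2, n), index=idx)
        groups = {"a": idx[: n // 2], "b": idx[n // 2:]}
        res1 = km_logrank(groups, time, event)
        perm = idx[rng.permutation(n)]
        res2 = km_logrank({"a": groups["a"][::-1], "b": groups["b"][::-1]},
                          time.loc[perm], event.loc[perm])
        assert res1.statistic == pytest.approx(res2.statistic, abs=1e-9)

    def test_no_events_rejected(self):
        time = pd.Series([1.0, 2.0], index=["a", "b"])
        event = pd.Series([0, 0], index=["a", "b"])
        with pytest.raises(ValueError, match="events"):
            km_logrank({"x": pd.Index(["a"]), "y": pd.Index(["b"])}, time, event)

    def test_curves_are_survival_functions(self):
        time = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        event = pd.Series([1, 1, 1, 0], index=list("abcd"))
        groups = {"g": pd.Index(list("ab")), "h": pd.Index(list("cd"))}
        res = km_logrank(groups, time, event)
        for curve in res.curves.values():
            vals = curve.iloc[:, 0].values
            assert vals[0] == 1.0
            assert np.all(np.diff(vals) <= 1e-12)


class TestCoxMultivariate:
    def test_matches_partial_likelihood_oracle(self):
        rng = np.random.default_rng(42)
        n = 30
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1 / (0.1 * np.exp(0.8 * x)))
        out = cox_multivariate(pd.DataFrame({"x": x}), pd.Series(t),
                               pd.Series(np.ones(n, dtype=int)))

        def neg_partial_likelihood(beta):
            risk = np.exp(beta * x)
            return -sum(beta * x[i] - np.log(risk[t >= t[i]].sum())
                        for i in range(n))

        oracle = minimize_scalar(neg_partial_likelihood, bounds=(-10, 10),
                                 method="bounded").x
        assert out.loc["x", "coefficient"] == pytest.approx(oracle, abs=1e-4)
        assert out.loc["x", "hr"] == pytest.approx(np.exp(oracle), rel=1e-4)

    def test_null_covariate_has_small_effect(self):
        rng = np.random.default_rng(7)
        n = 500
        t = rng.exponential(10, n)
        noise = rng.normal(size=n)
        out = cox_multivariate(pd.DataFrame({"noise": noise}), pd.Series(t),
                               pd.Series(np.ones(n, dtype=int)))
        assert abs(out.loc["noise", "coefficient"]) < 0.2
        assert out.loc["noise", "p"] > 0.05

    def test_recovers_positive_hazard_coefficient(self):
        rng = np.random.default_rng(3)
        n = 500
        a = rng.normal(size=n)
        t = rng.exponential(1 / (0.05 * np.exp(0.8 * a)))
        out = cox_multivariate(pd.DataFrame({"a": a}), pd.Series(t),
                               pd.Series(np.ones(n, dtype=int)))
        assert out.loc["a", "coefficient"] == pytest.approx(0.8, abs=0.15)
        assert out.loc["a", "p"] < 1e-10

    def test_constant_covariate_rejected(self):
        t = pd.Series([1.0, 2.0, 3.0])
        ev = pd.Series([1, 1, 1])
        with pytest.raises(ValueError, match="constant"):
            cox_multivariate(pd.DataFrame({"c": [1.0, 1.0, 1.0]}), t, ev)


class TestPcrRates:
    def test_all_pcr_gives_unit_fold(self):
        groups = {"low": pd.Index(["s0"]), "high": pd.Index(["s1"])}
        labels = series([1.0, 1.0]).astype(int)
        res = pcr_rates(groups, labels)
        assert res.rates == {"low": 1.0, "high": 1.0}
        assert res.fold == 1.0

    def test_rates_match_naive_counting(self, rng):
        labels = pd.Series(rng.integers(0, 2, 90),
                           index=[f"s{i}" for i in range(90)])
        groups = {"low": labels.index[:30], "intermediate": labels.index[30:60],
                  "high": labels.index[60:]}
        res = pcr_rates(groups, labels)
        for name, idx in groups.items():
            assert res.rates[name] == labels.loc[idx].mean()

    def test_zero_low_rate_fold_undefined(self):
        with pytest.warns(RipscoreWarning, match="undefined"):
            assert rate_fold(0.4, 0.0) is None

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pcr_rates({"low": pd.Index([]), "high": pd.Index(["s0"])},
                      series([1.0]).astype(int))


class TestContingencyFold:
    def test_equal_frequencies_unit_fold_zero_chi2(self):
        res = contingency_fold(10, 100, 20, 200)
        assert res.fold == pytest.approx(1.0)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_reciprocal_identity(self, rng):
        a, c = int(rng.integers(1, 50)), int(rng.integers(1, 50))
        res1 = contingency_fold(a, 100, c, 120)
        res2 = contingency_fold(c, 120, a, 100)
        assert res1.fold * res2.fold == pytest.approx(1.0)

    def test_chi2_matches_textbook_formula(self, rng):
        a, b = int(rng.integers(5, 40)), int(rng.integers(5, 40))
        n1, n2 = 100, 150
        res = contingency_fold(a, n1, b, n2)
        table = np.array([[a, n1 - a], [b, n2 - b]], dtype=float)
        n = table.sum()
        expected = np.outer(table.sum(1), table.sum(0)) / n
        chi2 = ((table - expected) ** 2 / expected).sum()
        assert res.chi2 == pytest.approx(chi2, abs=1e-9)

    def test_zero_reference_frequency_undefined(self):
        with pytest.warns(RipscoreWarning, match="undefined"):
            res = contingency_fold(0, 100, 10, 100)
        assert res.fold is None

    def test_bad_denominator_rejected(self):
        with pytest.raises(ValueError):
            contingency_fold(1, 0, 1, 10)


class TestCnd:
    def seg(self, rows):
        return pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end",
                                           "value"])

    def test_hand_case(self):
        segs = self.seg([("s1", "chr1", 1, 500, 4)])
        out = cnd(segs, genome_size=1000)
        assert out.loc["s1"] == pytest.approx(0.5)

    def test_no_abnormal_segments_is_zero(self):
        segs = self.seg([("s1", "chr1", 1, 500, 2)])  # copy-neutral
        assert cnd(segs, genome_size=1000).loc["s1"] == 0.0
        assert len(cnd(self.seg([]), genome_size=1000)) == 0

    def test_matches_naive_summation(self, rng):
        rows = []
        for i in range(100):
            s = f"s{rng.integers(5)}"
            start = int(rng.integers(1, 1000))
            size = int(rng.integers(1, 500))
            rows.append((s, "chr1", start, start + size - 1, float(rng.integers(1, 6))))
        segs = self.seg(rows)
        out = cnd(segs, genome_size=10_000)
        naive = {}
        for s, _, start, end, c in rows:
            naive[s] = naive.get(s, 0.0) + abs(np.log2(c / 2) * (end - start + 1)) / 10_000
        for s, v in naive.items():
            assert out.loc[s] == pytest.approx(v, abs=1e-12)

    def test_scales_inversely_with_genome_size(self):
        segs = self.seg([("s1", "chr1", 1, 500, 4)])
        assert cnd(segs, genome_size=2000).loc["s1"] == pytest.approx(
            cnd(segs, genome_size=1000).loc["s1"] / 2)

    def test_log2ratio_dialect_uses_value_directly(self):
        segs = self.seg([("s1", "chr1", 1, 500, 1.0)])  # log2(c/2) = 1
        assert cnd(segs, genome_size=1000, dialect="log2ratio").loc["s1"] == \
            pytest.approx(0.5)

    def test_nonpositive_copy_number_rejected(self):
        segs = self.seg([("s1", "chr1", 1, 500, 0)])
        with pytest.raises(ValueError, match="positive"):
            cnd(segs, genome_size=1000)


class TestMutationCounts:
    def table(self, rows):
        return pd.DataFrame(rows, columns=["sample_id", "gene", "variant_class"])

    def test_distinct_genes_counted_once(self):
        t = self.table([("s1", "TP53", "Missense_Mutation"),
                        ("s1", "TP53", "Nonsense_Mutation")])
        assert mutation_counts(t).loc["s1"] == 1

    def test_silent_only_counts_zero(self):
        t = self.table([("s1", "TP53", "Silent")])
        assert mutation_counts(t).loc["s1"] == 0

    def test_unknown_class_excluded_with_warning(self):
        t = self.table([("s1", "TP53", "Weird_Class"),
                        ("s1", "BRCA1", "Missense_Mutation")])
        with pytest.warns(RipscoreWarning, match="unknown"):
            out = mutation_counts(t)
        assert out.loc["s1"] == 1

    def test_matches_groupby_oracle(self, rng):
        genes = [f"G{i}" for i in range(30)]
        classes = ["Missense_Mutation", "Silent", "Frame_Shift_Del", "Intron"]
        rows = [(f"s{rng.integers(4)}", genes[rng.integers(30)],
                 classes[rng.integers(4)]) for _ in range(300)]
        t = self.table(rows)
        out = mutation_counts(t)
        qualifying = {"Missense_Mutation", "Frame_Shift_Del"}
        for s in t["sample_id"].unique():
            expected = t[(t["sample_id"] == s)
                         & t["variant_class"].isin(qualifying)]["gene"].nunique()
            assert out.loc[s] == expected


class TestRfPcrComparison:
    def test_uninformative_features_auc_near_half(self, rng):
        n = 120
        features = pd.DataFrame(rng.normal(size=(n, 3)),
                                columns=["f1", "f2", "rips"],
                                index=[f"s{i}" for i in range(n)])
        labels = pd.Series(rng.integers(0, 2, n), index=features.index)
        mean_auc, sd = rf_pcr_comparison(features, labels, n_repeats=3, seed=0)
        assert mean_auc == pytest.approx(0.5, abs=0.1)

    def test_informative_score_column_lifts_auc(self, rng):
        n = 150
        a = rng.normal(size=n)
        features = pd.DataFrame({
            "age": rng.normal(55, 8, n),
            "grade": rng.integers(1, 4, n).astype(float),
            "rips": a + rng.normal(0, 0.3, n),
        }, index=[f"s{i}" for i in range(n)])
        labels = pd.Series((rng.random(n) < 1 / (1 + np.exp(-2 * a))).astype(int),
                           index=features.index)
        with_rips, _ = rf_pcr_comparison(features, labels, include_rips=True,
                                         n_repeats=3, seed=1)
        without, _ = rf_pcr_comparison(features, labels, include_rips=False,
                                       n_repeats=3, seed=1)
        assert with_rips > without

    def test_too_few_samples_rejected(self, rng):
        features = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "rips"])
        labels = pd.Series(rng.integers(0, 2, 20))
        with pytest.raises(ValueError, match="50"):
            rf_pcr_comparison(features, labels)
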