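"""Bulk-expression statistics against hand computations and brute force."""

import numpy as np
import pandas as pd
import pytest

from k27shared.expression import (
    ExpressionMatrix,
    bh_adjust,
    bimodal_split,
    coexpression_diff,
    collapse_probes,
    diff_expression,
    gsea_preranked,
    linear_fit,
    rank_metric,
    sd_heterogeneity,
    split_by_mean,
)


def matrix_from(values, groups, index=None, probe_map=None):
    """Build an ExpressionMatrix from {sample: row-values} columns."""
    df = pd.DataFrame(values)
    if index is not None:
        df.index = index
    return ExpressionMatrix(
        values=df, probe_map=probe_map or {}, sample_groups=groups
    )


def brute_force_bh(p):
    """Step-up BH from the definition: q_(i) = min_{j>=i} m*p_(j)/j, capped."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = min(running, 1.0)
    return q


def brute_force_es(ranked, gene_set, weight):
    """Running-sum oracle walking the descending-score gene list."""
    genes = sorted(ranked, key=lambda g: (-ranked[g], g))
    hits = [g in gene_set for g in genes]
    total_hit_weight = sum(abs(ranked[g]) ** weight for g, h in zip(genes, hits) if h)
    n_miss = len(genes) - sum(hits)
    running, best = 0.0, 0.0
    for g, h in zip(genes, hits):
        if h:
            running += abs(ranked[g]) ** weight / total_hit_weight
        else:
            running -= 1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


class TestDiffExpression:
    def test_identical_groups_give_p_one(self):
        vals = {f"s{i}": [5.0, 2.0] for i in range(6)}
        groups = {f"s{i}": "A" if i < 3 else "B" for i in range(6)}
        df = pd.DataFrame(vals, index=["g1", "g2"])
        # add symmetric variation so variance is nonzero and means equal
        df.loc["g1", ["s0", "s3"]] += 1
        df.loc["g1", ["s1", "s4"]] -= 1
        res = {r.gene_id: r for r in diff_expression(
            ExpressionMatrix(values=df, sample_groups=groups), "A", "B")}
        assert res["g1"].diff == pytest.approx(0)
        assert res["g1"].p == pytest.approx(1)

    def test_noiseless_shift_flags_degenerate(self):
        df = pd.DataFrame(
            {"s0": [10.0], "s1": [10.0], "s2": [8.0], "s3": [8.0]}, index=["g"]
        )
        groups = {"s0": "A", "s1": "A", "s2": "B", "s3": "B"}
        (r,) = diff_expression(
            ExpressionMatrix(values=df, sample_groups=groups), "A", "B"
        )
        assert r.diff == pytest.approx(2.0)
        assert r.degenerate and r.p == 0.0

    def test_pooled_t_matches_scipy_per_row(self, rng):
        from scipy import stats

        a, b = rng.normal(0, 1, (20, 5)), rng.normal(0.5, 1, (20, 4))
        df = pd.DataFrame(
            np.hstack([a, b]),
            index=[f"g{i}" for i in range(20)],
            columns=[f"s{i}" for i in range(9)],
        )
        groups = {f"s{i}": "A" if i < 5 else "B" for i in range(9)}
        res = diff_expression(
            ExpressionMatrix(values=df, sample_groups=groups), "A", "B"
        )
        for i, r in enumerate(res):
            t, p = stats.ttest_ind(a[i], b[i], equal_var=True)
            assert r.p == pytest.approx(p)
            assert r.diff == pytest.approx(a[i].mean() - b[i].mean())

    def test_monte_carlo_power_at_planted_shift(self):
        """n=5+5, delta=2, sigma=1: rejection rate matches noncentral-t power.

        Each of the 1000 replicate rows is an independent experiment; the
        empirical rejection rate at alpha=0.05 must agree with the analytic
        noncentral-t power for this design within Monte-Carlo error.
        """
        from scipy import stats

        rng = np.random.default_rng(11)
        n_rep = 1000
        a = rng.normal(2.0, 1.0, (n_rep, 5))
        b = rng.normal(0.0, 1.0, (n_rep, 5))
        df = pd.DataFrame(
            np.hstack([a, b]),
            index=[f"rep{i}" for i in range(n_rep)],
            columns=[f"s{i}" for i in range(10)],
        )
        groups = {f"s{i}": "A" if i < 5 else "B" for i in range(10)}
        res = diff_expression(
            ExpressionMatrix(values=df, sample_groups=groups), "A", "B"
        )
        power = np.mean([r.p < 0.05 for r in res])
        # analytic oracle: ncp = delta / (sigma * sqrt(1/5 + 1/5)), df = 8
        ncp = 2.0 / np.sqrt(2.0 / 5.0)
        crit = stats.t.ppf(0.975, df=8)
        analytic = stats.nct.sf(crit, df=8, nc=ncp) + stats.nct.cdf(
            -crit, df=8, nc=ncp
        )
        mc_se = np.sqrt(analytic * (1 - analytic) / n_rep)
        assert power == pytest.approx(analytic, abs=3 * mc_se)
        assert power > 0.75

    def test_requires_two_samples_per_group(self):
        df = pd.DataFrame({"s0": [1.0], "s1": [2.0], "s2": [3.0]}, index=["g"])
        groups = {"s0": "A", "s1": "B", "s2": "B"}
        with pytest.raises(ValueError):
            diff_expression(
                ExpressionMatrix(values=df, sample_groups=groups), "A", "B"
            )


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.04], [0.04]),
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ],
    )
    def test_hand_computed_examples(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected)

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(200):
            p = rng.uniform(0, 1, int(rng.integers(1, 40)))
            assert bh_adjust(p) == pytest.approx(brute_force_bh(p))

    def test_monotone_in_sorted_p_order(self, rng):
        p = rng.uniform(0, 1, 100)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestRankMetric:
    @pytest.mark.parametrize(
        "q,diff,expected", [(0.01, 2.0, 4.0), (1.0, 5.0, 0.0), (0.1, -3.0, -3.0)]
    )
    def test_examples(self, q, diff, expected):
        assert rank_metric(q, diff) == pytest.approx(expected)

    def test_zero_q_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            score = rank_metric(0.0, 1.0)
        assert score == pytest.approx(300.0)


class TestGSEAPreranked:
    def make_ranked(self, n=10, seed=5):
        rng = np.random.default_rng(seed)
        return {f"g{i:02d}": float(s) for i, s in enumerate(rng.normal(0, 2, n))}

    def test_leading_block_maximizes_es(self):
        ranked = {f"g{i:02d}": float(20 - i) for i in range(20)}
        top = {"g00", "g01"}
        res = gsea_preranked(ranked, top, n_perm=50, min_size=1, max_size=50)
        assert res.es > 0.85  # running sum peaks right after the hit block

    def test_es_matches_brute_force_oracle(self, rng):
        for seed in range(10):
            ranked = self.make_ranked(10, seed)
            genes = sorted(ranked)
            gene_set = set(rng.choice(genes, 3, replace=False))
            for weight in (0.0, 1.0):
                res = gsea_preranked(
                    ranked, gene_set, n_perm=10, weight=weight,
                    min_size=1, max_size=10,
                )
                assert res.es == pytest.approx(
                    brute_force_es(ranked, gene_set, weight)
                )

    def test_es_bounded_and_reversal_negates_at_weight_zero(self, rng):
        ranked = self.make_ranked(30, seed=9)
        gene_set = set(rng.choice(sorted(ranked), 8, replace=False))
        res = gsea_preranked(ranked, gene_set, n_perm=10, weight=0.0,
                             min_size=1, max_size=30)
        assert -1 <= res.es <= 1
        reversed_ranked = {g: -s for g, s in ranked.items()}
        rev = gsea_preranked(reversed_ranked, gene_set, n_perm=10, weight=0.0,
                             min_size=1, max_size=30)
        assert rev.es == pytest.approx(-res.es)

    def test_size_gates_and_universe_checks(self):
        ranked = self.make_ranked(10)
        with pytest.raises(ValueError, match="universe"):
            gsea_preranked(ranked, {"absent"}, min_size=1, max_size=10)
        with pytest.raises(ValueError, match="outside"):
            gsea_preranked(ranked, {"g00"})  # default min_size 15

    def test_deterministic_under_seed(self):
        ranked = self.make_ranked(20)
        gene_set = {"g00", "g03", "g07", "g11"}
        a = gsea_preranked(ranked, gene_set, n_perm=100, min_size=1,
                           max_size=20, seed=42)
        b = gsea_preranked(ranked, gene_set, n_perm=100, min_size=1,
                           max_size=20, seed=42)
        assert (a.es, a.nes, a.p_perm) == (b.es, b.nes, b.p_perm)


class TestCollapseProbes:
    def build(self):
        df = pd.DataFrame(
            {
                "s1": [5.0, 7.0, 3.0],
                "s2": [5.4, 7.2, 3.1],
                "s3": [5.0, 7.0, 9.0],
            },
            index=["pA1", "pA2", "pB1"],
        )
        return ExpressionMatrix(
            values=df,
            probe_map={"pA1": "geneA", "pA2": "geneA", "pB1": "geneB"},
            sample_groups={"s1": "ref", "s2": "ref", "s3": "other"},
        )

    def test_keeps_max_mean_probe_over_reference(self):
        out = collapse_probes(self.build(), "ref")
        # pA2 mean over {s1,s2} = 7.1 > pA1 5.2
        assert out.values.loc["geneA", "s1"] == 7.0
        assert list(out.values.index) == ["geneA", "geneB"]

    def test_single_probe_gene_is_identity(self):
        out = collapse_probes(self.build(), "ref")
        assert out.values.loc["geneB"].tolist() == [3.0, 3.1, 9.0]

    def test_tie_keeps_lexicographically_smallest_probe(self):
        df = pd.DataFrame({"s1": [4.0, 4.0], "s2": [6.0, 6.0]},
                          index=["p2", "p1"])
        m = ExpressionMatrix(
            values=df,
            probe_map={"p1": "g", "p2": "g"},
            sample_groups={"s1": "ref", "s2": "ref"},
        )
        out = collapse_probes(m, "ref")
        pd.testing.assert_series_equal(
            out.values.loc["g"], df.loc["p1"], check_names=False
        )

    def test_invariant_to_probe_row_order(self, rng):
        m = self.build()
        shuffled = ExpressionMatrix(
            values=m.values.iloc[[2, 0, 1]],
            probe_map=m.probe_map,
            sample_groups=m.sample_groups,
        )
        a = collapse_probes(m, "ref").values
        b = collapse_probes(shuffled, "ref").values
        pd.testing.assert_frame_equal(a, b)


class TestSDHeterogeneity:
    def test_closed_form_and_exclusions(self):
        ma = matrix_from(
            {"s1": [1.0, 5.0], "s2": [3.0, 5.0]},
            {"s1": "x", "s2": "x"},
            index=["gShared", "gOnlyA"],
        )
        mb = matrix_from(
            {"t1": [2.0], "t2": [2.0], "t3": [8.0]},
            {"t1": "y", "t2": "y", "t3": "y"},
            index=["gShared"],
        )
        table, excluded = sd_heterogeneity(ma, mb)
        assert excluded == ["gOnlyA"]
        assert table.loc["gShared", "sd_a"] == pytest.approx(np.sqrt(2))
        assert table.loc["gShared", "sd_b"] == pytest.approx(np.std([2, 2, 8], ddof=1))

    def test_constant_gene_has_zero_sd(self):
        m = matrix_from({"s1": [4.0], "s2": [4.0], "s3": [4.0]},
                        {f"s{i}": "x" for i in (1, 2, 3)}, index=["g"])
        table, _ = sd_heterogeneity(m, m)
        assert (table == 0).all().all()


class TestBimodalSplit:
    def test_mixture_threshold_near_density_crossing(self):
        rng = np.random.default_rng(2)
        values = np.concatenate(
            [rng.normal(0, 0.3, 100), rng.normal(5, 0.3, 100)]
        )
        threshold = bimodal_split(values)
        assert threshold is not None
        assert 1.5 <= threshold <= 3.5

    def test_unimodal_returns_none(self):
        rng = np.random.default_rng(3)
        assert bimodal_split(rng.normal(0, 1, 300)) is None

    def test_symmetric_two_point_data(self):
        values = np.array([0.0] * 50 + [10.0] * 50)
        threshold = bimodal_split(values)
        assert threshold == pytest.approx(5.0, abs=0.5)

    def test_converges_to_true_crossing_with_n(self):
        """At n=5000 the KDE valley approaches the analytic density crossing.

        For an equal mixture of N(0, 0.3^2) and N(5, 0.3^2) the densities
        cross at 2.5 by symmetry.
        """
        rng = np.random.default_rng(4)
        values = np.concatenate(
            [rng.normal(0, 0.3, 2500), rng.normal(5, 0.3, 2500)]
        )
        threshold = bimodal_split(values)
        grid_step = (values.max() - values.min()) / 511
        assert threshold == pytest.approx(2.5, abs=max(0.25, 10 * grid_step))

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            bimodal_split([1.0] * 5)


class TestSplitsAndFits:
    def test_split_by_mean_examples(self):
        labels = split_by_mean(pd.Series([1.0, 2.0, 3.0, 4.0]))
        assert labels.tolist() == ["low", "low", "high", "high"]
        assert split_by_mean(pd.Series([2.0, 2.0, 2.0])).tolist() == ["low"] * 3

    def test_split_recovers_mixture_components(self):
        rng = np.random.default_rng(5)
        comp = rng.random(400) < 0.5
        values = pd.Series(np.where(comp, 4.0, 0.0) + rng.normal(0, 1, 400))
        labels = split_by_mean(values)
        error = np.mean((labels == "high") != comp)
        assert error < 0.05  # 4-sigma separation

    def test_coexpression_diff_recovers_planted_shift(self):
        rng = np.random.default_rng(6)
        anchor = np.concatenate([rng.normal(0, 0.5, 30), rng.normal(6, 0.5, 30)])
        partner = np.where(anchor > 3, 2.0, 0.0) + rng.normal(0, 0.3, 60)
        flat = rng.normal(1, 0.3, 60)
        df = pd.DataFrame(
            [anchor, partner, flat],
            index=["anchor", "partner", "flat"],
            columns=[f"s{i}" for i in range(60)],
        )
        m = ExpressionMatrix(values=df,
                             sample_groups={c: "all" for c in df.columns})
        labels = split_by_mean(df.loc["anchor"])
        delta = coexpression_diff(m, labels)
        assert delta["anchor"] > 0
        assert delta["partner"] == pytest.approx(2.0, abs=0.4)
        assert delta["flat"] == pytest.approx(0.0, abs=0.4)

    def test_coexpression_requires_both_classes(self):
        df = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["g"])
        m = ExpressionMatrix(values=df,
                             sample_groups={"s1": "x", "s2": "x"})
        labels = pd.Series({"s1": "high", "s2": "high"})
        with pytest.raises(ValueError):
            coexpression_diff(m, labels)

    def test_linear_fit_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        slope, intercept, r2 = linear_fit(x, 2 * x + 1)
        assert (slope, intercept, r2) == pytest.approx((2.0, 1.0, 1.0))

    def test_linear_fit_independent_noise_r2_near_zero(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(0, 1, 2000), rng.normal(0, 1, 2000)
        *_, r2 = linear_fit(x, y)
        assert r2 < 0.01

    def test_linear_fit_preconditions(self):
        with pytest.raises(ValueError):
            linear_fit([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            linear_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
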