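import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from alphamorph.errors import DegenerateInputError
from alphamorph._enet import enet_logistic_path, lambda_path
from alphamorph.stats import (
    REGULARISER_MIXING,
    AgreementReport,
    BootstrapConfig,
    agreement_analysis,
    bootstrap_feature_importance,
    dice,
    dunn_posthoc,
    group_comparison,
    relative_error,
    _rank_auc,
)

from helpers import dunn_z_by_hand, kruskal_by_hand


def make_table(rng, groups, n_per_group=20, shift=None):
    rows = []
    for gi, g in enumerate(groups):
        for i in range(n_per_group):
            rows.append(
                {
                    "image_id": f"{g}_{i}",
                    "param_a": rng.normal((shift or {}).get(g, 0.0), 1.0),
                    "param_b": rng.normal(0.0, 1.0),
                    "group_label": g,
                }
            )
    return pd.DataFrame(rows)


class TestGroupComparison:
    def test_identical_groups_p_one(self):
        values = np.arange(10, dtype=float)
        table = pd.DataFrame(
            {
                "image_id": [f"i{k}" for k in range(20)],
                "param_a": np.concatenate([values, values]),
                "group_label": ["a"] * 10 + ["b"] * 10,
            }
        )
        report = group_comparison(table, ["param_a"])
        assert report.omnibus.loc[0, "H"] == pytest.approx(0.0, abs=1e-9)
        assert report.omnibus.loc[0, "p_raw"] == pytest.approx(1.0)

    def test_hand_rank_oracle(self):
        groups = {
            "g1": np.array([1.0, 3.0, 5.0, 7.0]),
            "g2": np.array([2.0, 4.0, 6.0, 8.0]),
            "g3": np.array([10.0, 11.0, 12.0, 13.0]),
        }
        h_expected = kruskal_by_hand(list(groups.values()))
        h_scipy, _ = sps.kruskal(*groups.values())
        assert h_scipy == pytest.approx(h_expected, rel=1e-12)
        ph = dunn_posthoc(groups)
        z01 = dunn_z_by_hand(list(groups.values()), 0, 1)
        row = ph[(ph.group_a == "g1") & (ph.group_b == "g2")].iloc[0]
        assert row.z == pytest.approx(z01, rel=1e-12)

    def test_separated_group_detected(self, rng):
        table = make_table(rng, ["a", "b", "c"], 30, shift={"c": 3.0})
        report = group_comparison(table, ["param_a", "param_b"])
        row = report.omnibus[report.omnibus.parameter == "param_a"].iloc[0]
        assert row.significant
        ph = report.posthoc[report.posthoc.parameter == "param_a"]
        sig_pairs = ph[ph.significant]
        assert {"c"} <= set(sig_pairs.group_a) | set(sig_pairs.group_b)

    def test_adjusted_p_not_less_than_raw(self, rng):
        table = make_table(rng, ["a", "b", "c"], 15)
        report = group_comparison(table, ["param_a", "param_b"])
        assert (report.omnibus.p_adjusted >= report.omnibus.p_raw - 1e-15).all()

    def test_small_group_skipped(self, rng):
        table = make_table(rng, ["a", "b"], 10)
        table = pd.concat(
            [table, pd.DataFrame([{"image_id": "c_0", "param_a": 1.0,
                                   "param_b": 1.0, "group_label": "c"}])],
            ignore_index=True,
        )
        with pytest.raises(DegenerateInputError):
            group_comparison(table, ["param_a", "param_b"])

    def test_needs_two_groups(self, rng):
        table = make_table(rng, ["only"], 10)
        with pytest.raises(DegenerateInputError):
            group_comparison(table, ["param_a"])


class TestMultiplicityInvariants:
    def test_bh_and_bonferroni_monotone(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.uniform(0, 1, size=8)
            _, bh, *_ = multipletests(p, method="fdr_bh")
            _, bonf, *_ = multipletests(p, method="bonferroni")
            assert np.all(bh >= p - 1e-15)
            assert np.all(bonf >= p - 1e-15)
            order = np.argsort(p)
            assert np.all(np.diff(bh[order]) >= -1e-12)
            assert np.all(np.diff(bonf[order]) >= -1e-12)


class TestEnetSolver:
    def test_regulariser_mixing_map(self):
        assert REGULARISER_MIXING == {"lasso": 1.0, "ridge": 0.0, "elastic_net": 0.5}

    @pytest.mark.parametrize("l1", [1.0, 0.5, 0.0])
    def test_matches_sklearn(self, l1, rng):
        from sklearn.linear_model import LogisticRegression

        n, p = 60, 4
        X = rng.normal(size=(n, p))
        X = (X - X.mean(0)) / X.std(0)
        y = (rng.random(n) < 1 / (1 + np.exp(-X[:, 0]))).astype(float)
        lams = lambda_path(X, y, l1)
        B, b0 = enet_logistic_path(X, y, lams, l1)
        for li in (30, 80):
            sk = LogisticRegression(
                C=1.0 / (n * lams[li]), l1_ratio=l1, solver="saga",
                max_iter=100000, tol=1e-12,
            ).fit(X, y)
            assert np.allclose(B[li], sk.coef_[0], atol=1e-4)
            assert b0[li] == pytest.approx(sk.intercept_[0], abs=1e-4)

    def test_lambda_max_zeroes_coefficients(self, rng):
        X = rng.normal(size=(50, 3))
        X = (X - X.mean(0)) / X.std(0)
        y = (rng.random(50) < 0.5).astype(float)
        lams = lambda_path(X, y, 1.0)
        B, _ = enet_logistic_path(X, y, lams[:1], 1.0)
        assert np.all(B[0] == 0.0)

    def test_rank_auc_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        scores = np.round(rng.normal(size=(50, 4)), 1)  # induce ties
        mine = _rank_auc(scores, y)
        for j in range(4):
            assert mine[j] == pytest.approx(roc_auc_score(y, scores[:, j]))


class TestBootstrapImportance:
    def test_determinism(self, rng):
        X = rng.normal(size=(120, 3))
        y = (rng.random(120) < 0.4).astype(int)
        cfg = BootstrapConfig(n_trials=5, per_class=15)
        r1 = bootstrap_feature_importance(X, y, cfg, seed=3)
        r2 = bootstrap_feature_importance(X, y, cfg, seed=3)
        assert r1.counts == r2.counts
        assert r1.auc == r2.auc

    def test_counts_bounded_by_trials(self, rng):
        X = rng.normal(size=(100, 4))
        y = (rng.random(100) < 0.5).astype(int)
        cfg = BootstrapConfig(n_trials=8, per_class=10)
        rep = bootstrap_feature_importance(X, y, cfg, seed=1)
        for d in rep.counts.values():
            assert all(0 <= v <= 8 for v in d.values())

    def test_planted_signal_recovered(self, rng):
        n = 300
        y = (np.arange(n) < 40).astype(int)
        X = np.column_stack(
            [1.81 * y + rng.normal(size=n)] + [rng.normal(size=n) for _ in range(4)]
        )
        cfg = BootstrapConfig(n_trials=30, per_class=40, regularisers=("lasso",))
        rep = bootstrap_feature_importance(
            pd.DataFrame(X, columns=list("abcde")), y, cfg, seed=0
        )
        counts = rep.counts[("lasso", "lambda_min")]
        assert counts["a"] == max(counts.values())
        assert rep.auc["lasso"][0] > 0.8

    def test_degenerate_feature_dropped(self, rng):
        X = np.column_stack([np.ones(80), rng.normal(size=80)])
        y = (rng.random(80) < 0.5).astype(int)
        cfg = BootstrapConfig(n_trials=3, per_class=10)
        rep = bootstrap_feature_importance(X, y, cfg, seed=0)
        assert rep.feature_names == ("feature_1",)

    def test_class_too_small(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.array([1] + [0] * 9)
        with pytest.raises(DegenerateInputError):
            bootstrap_feature_importance(X, y, BootstrapConfig(n_trials=2), seed=0)


class TestDice:
    def test_identical(self):
        a = np.zeros((5, 5), bool)
        a[1:3, 1:4] = True
        assert dice(a, a) == pytest.approx(1.0)

    def test_disjoint(self):
        a = np.zeros((5, 5), bool)
        b = np.zeros((5, 5), bool)
        a[0, 0] = True
        b[4, 4] = True
        assert dice(a, b) == 0.0

    def test_formula(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a.flat[:4] = True
        b.flat[1:7] = True  # |A|=4, |B|=6, overlap 3
        assert dice(a, b) == pytest.approx(0.6)

    def test_symmetry(self, rng):
        a = rng.random((8, 8)) > 0.5
        b = rng.random((8, 8)) > 0.5
        assert dice(a, b) == dice(b, a)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice(np.ones((3, 3), bool), np.ones((4, 4), bool))

    def test_both_empty(self):
        with pytest.raises(DegenerateInputError):
            dice(np.zeros((3, 3), bool), np.zeros((3, 3), bool))


class TestRelativeError:
    def test_equal_values(self):
        assert relative_error(5.0, 5.0) == 0.0

    def test_ten_percent(self):
        assert relative_error(100.0, 90.0) == pytest.approx(0.10)

    def test_vector_against_loop(self, rng):
        av = rng.uniform(1, 10, 20)
        mv = av + rng.normal(0, 1, 20)
        res = [relative_error(a, m) for a, m in zip(av, mv)]
        assert np.mean(res) == pytest.approx(np.mean(np.abs(av - mv) / np.abs(av)))
        assert np.max(res) == pytest.approx(np.max(np.abs(av - mv) / np.abs(av)))

    def test_zero_reference(self):
        with pytest.raises(ValueError):
            relative_error(0.0, 1.0)


def desc_frame(ids, values, group):
    return pd.DataFrame(
        {
            "image_id": ids,
            "op_alpha_min": values,
            "group_label": group,
        }
    )


class TestAgreement:
    def test_perfect_agreement(self, rng):
        ids = [f"i{k}" for k in range(6)]
        vals = rng.uniform(10, 20, 6)
        groups = ["h", "h", "h", "d", "d", "d"]
        man = desc_frame(ids, vals, groups)
        report = agreement_analysis(man, man.copy(), ["op_alpha_min"])
        row = report.per_parameter.iloc[0]
        assert row.mre == 0.0 and row.max_re == 0.0
        assert row.pearson_r == pytest.approx(1.0)

    def test_offset_case(self, rng):
        ids = [f"i{k}" for k in range(8)]
        vals = rng.uniform(10, 20, 8)
        man = desc_frame(ids, vals, ["h"] * 4 + ["d"] * 4)
        aut = desc_frame(ids, vals + 2.0, ["h"] * 4 + ["d"] * 4)
        report = agreement_analysis(man, aut, ["op_alpha_min"])
        row = report.per_parameter.iloc[0]
        assert row.pearson_r == pytest.approx(1.0)
        assert row.mre == pytest.approx(np.mean(2.0 / vals))

    def test_recomputation_oracle(self, rng):
        ids = [f"i{k}" for k in range(10)]
        vals = rng.uniform(5, 30, 10)
        noise = vals + rng.normal(0, 2, 10)
        groups = ["h"] * 5 + ["d"] * 5
        man = desc_frame(ids, vals, groups)
        aut = desc_frame(ids, noise, groups)
        masks_m = {i: rng.random((6, 6)) > 0.4 for i in ids}
        masks_a = {i: rng.random((6, 6)) > 0.4 for i in ids}
        report = agreement_analysis(
            man, aut, ["op_alpha_min"],
            manual_masks=masks_m, automatic_masks=masks_a,
        )
        row = report.per_parameter.iloc[0]
        res = np.abs(vals - noise) / np.abs(vals)
        assert row.mre == pytest.approx(res.mean())
        assert row.max_re == pytest.approx(res.max())
        r, p = sps.pearsonr(vals, noise)
        assert row.pearson_r == pytest.approx(r)
        assert row.pearson_p == pytest.approx(p)
        assert row.ranksum_p_manual == pytest.approx(
            sps.ranksums(vals[:5], vals[5:]).pvalue
        )
        for i in ids:
            d = report.per_image.set_index("image_id").loc[i, "dsc"]
            inter = (masks_m[i] & masks_a[i]).sum()
            assert d == pytest.approx(2 * inter / (masks_m[i].sum() + masks_a[i].sum()))
        assert isinstance(report, AgreementReport)

    def test_unpaired_ids_raise(self, rng):
        man = desc_frame(["a", "b", "c"], [1.0, 2.0, 3.0], ["h", "h", "d"])
        aut = desc_frame(["a", "b", "x"], [1.0, 2.0, 3.0], ["h", "h", "d"])
        with pytest.raises(ValueError, match="unpaired"):
            agreement_analysis(man, aut, ["op_alpha_min"])
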