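import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bifluent.stats import (
    backward_stepwise,
    bh_adjust,
    independent_contrast,
    mixed_anova,
    paired_contrast,
    pca_varimax,
    planned_contrasts,
)


def bh_oracle(pvals):
    """Definitional BH: sorted p * m / rank, cumulative minimum from the
    largest rank down, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adjusted[i] = running
    return adjusted


class TestBhAdjust:
    def test_worked_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=20)
        adj = bh_adjust(p)
        assert np.all(adj >= p) and np.all(adj <= 1)

    def test_against_oracle_many_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(500):
            p = rng.uniform(size=rng.integers(1, 30))
            assert bh_adjust(p) == pytest.approx(bh_oracle(p))

    def test_empty(self):
        assert bh_adjust([]).size == 0


def hand_mixed_anova(wide, groups):
    """Balanced-design sums-of-squares decomposition, written from the
    textbook formulas as an independent oracle."""
    n, k = wide.shape
    levels = sorted(set(groups))
    g = len(levels)
    npg = n // g
    grand = wide.mean()
    subj_means = wide.mean(axis=1)
    group_means = {lv: wide[groups == lv].mean() for lv in levels}
    cond_means = wide.mean(axis=0)
    cell_means = {lv: wide[groups == lv].mean(axis=0) for lv in levels}

    ss_group = k * npg * sum((group_means[lv] - grand) ** 2 for lv in levels)
    ss_subj_in_g = k * sum(
        (subj_means[i] - group_means[groups[i]]) ** 2 for i in range(n)
    )
    ss_within = n * sum((cond_means[j] - grand) ** 2 for j in range(k))
    ss_inter = npg * sum(
        (cell_means[lv][j] - group_means[lv] - cond_means[j] + grand) ** 2
        for lv in levels
        for j in range(k)
    )
    ss_total = ((wide - grand) ** 2).sum()
    ss_err = ss_total - ss_group - ss_subj_in_g - ss_within - ss_inter

    df_group, df_subj = g - 1, n - g
    df_within = k - 1
    df_inter = (g - 1) * (k - 1)
    df_err = (n - g) * (k - 1)
    return {
        "between": (ss_group / df_group) / (ss_subj_in_g / df_subj),
        "within": (ss_within / df_within) / (ss_err / df_err),
        "interaction": (ss_inter / df_inter) / (ss_err / df_err),
    }


def _long_format(wide, groups):
    n, k = wide.shape
    rows = []
    for i in range(n):
        for j in range(k):
            rows.append(
                {
                    "participant_id": f"S{i}",
                    "group": groups[i],
                    "condition": f"C{j}",
                    "y": wide[i, j],
                }
            )
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_no_effects_zero_f(self):
        rng = np.random.default_rng(1)
        n, k = 8, 3
        subject_offsets = rng.normal(size=n)
        wide = np.tile(subject_offsets[:, None], (1, k))
        groups = np.array(["A"] * 4 + ["B"] * 4)
        # group means equalized: mirror offsets across groups
        wide[4:] = wide[:4]
        data = _long_format(wide, groups)
        res = mixed_anova(data, "y", "condition", "group")
        uni = res[res.approach == "univariate"].set_index("effect")
        assert uni.loc["between", "F"] == pytest.approx(0, abs=1e-10)
        # zero noise leaves the within error term empty: 0/0, reported as
        # NaN rather than a spurious effect
        within_f = uni.loc["within", "F"]
        assert np.isnan(within_f) or within_f == pytest.approx(0, abs=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_hand_ss_decomposition(self, seed):
        rng = np.random.default_rng(seed)
        n, k = 8, 4
        wide = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
        groups = np.array(["A"] * 4 + ["B"] * 4)
        wide[groups == "B"] += 0.8
        expected = hand_mixed_anova(wide, groups)
        res = mixed_anova(_long_format(wide, groups), "y", "condition", "group")
        uni = res[res.approach == "univariate"].set_index("effect")
        for effect, f in expected.items():
            assert uni.loc[effect, "F"] == pytest.approx(f, rel=1e-8)

    def test_np2_in_unit_interval(self):
        rng = np.random.default_rng(3)
        wide = rng.normal(size=(10, 3))
        groups = np.array(["A"] * 5 + ["B"] * 5)
        res = mixed_anova(_long_format(wide, groups), "y", "condition", "group")
        assert ((res["np2"] >= 0) & (res["np2"] <= 1)).all()
        assert (res["F"] >= 0).all()

    def test_multivariate_df_pattern(self):
        # k-level within factor with two groups: multivariate error df is
        # n - g - (k - 1) + 1
        rng = np.random.default_rng(4)
        n, k = 57, 4
        wide = rng.normal(size=(n, k))
        groups = np.array(["A"] * 35 + ["B"] * 22)
        res = mixed_anova(_long_format(wide, groups), "y", "condition", "group")
        multi = res[res.approach == "multivariate"].set_index("effect")
        assert multi.loc["within", "df1"] == 3
        assert multi.loc["within", "df2"] == 53

    def test_multivariate_equals_univariate_for_two_levels(self):
        rng = np.random.default_rng(5)
        wide = rng.normal(size=(12, 2))
        groups = np.array(["A"] * 6 + ["B"] * 6)
        res = mixed_anova(_long_format(wide, groups), "y", "condition", "group")
        uni = res[res.approach == "univariate"].set_index("effect")
        multi = res[res.approach == "multivariate"].set_index("effect")
        for effect in ("within", "interaction"):
            assert multi.loc[effect, "F"] == pytest.approx(
                uni.loc[effect, "F"], rel=1e-8
            )

    def test_planted_group_effect_power(self):
        detected = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n1, n2, k = 35, 22, 2
            wide = np.vstack(
                [rng.normal(0, 1, size=(n1, k)), rng.normal(1.5, 1, size=(n2, k))]
            )
            wide += rng.normal(scale=0.5, size=(n1 + n2, 1))
            groups = np.array(["A"] * n1 + ["B"] * n2)
            res = mixed_anova(_long_format(wide, groups), "y", "condition", "group")
            uni = res[res.approach == "univariate"].set_index("effect")
            detected += uni.loc["between", "p"] < 0.05
        assert detected >= 18

    def test_single_level_factor_rejected(self):
        data = _long_format(np.zeros((4, 2)), np.array(["A"] * 4))
        with pytest.raises(ValueError, match="fewer than 2 levels"):
            mixed_anova(data, "y", "condition", "group")

    def test_incomplete_subject_dropped(self):
        rng = np.random.default_rng(6)
        wide = rng.normal(size=(8, 3))
        groups = np.array(["A"] * 4 + ["B"] * 4)
        data = _long_format(wide, groups)
        data = data[~((data.participant_id == "S0") & (data.condition == "C2"))]
        res = mixed_anova(data, "y", "condition", "group")
        reference = mixed_anova(
            _long_format(wide[1:], groups[1:]), "y", "condition", "group"
        )
        uni = res[res.approach == "univariate"]["F"].to_numpy()
        ref = reference[reference.approach == "univariate"]["F"].to_numpy()
        assert uni == pytest.approx(ref)


class TestPlannedContrasts:
    def test_identical_paired_vectors(self):
        res = paired_contrast([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["t"] == 0.0 and res["p"] == 1.0 and res["d"] == 0.0

    def test_bh_within_family(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=10)
        contrasts = [
            ("c1", base + 2.0 + rng.normal(scale=0.3, size=10), base, True),
            ("c2", base + 1.0 + rng.normal(scale=0.3, size=10), base, True),
            ("c3", base + rng.normal(scale=0.3, size=10), base, True),
        ]
        frame = planned_contrasts(contrasts)
        assert (frame["p_adj"] >= frame["p"] - 1e-15).all()
        assert frame["p_adj"].to_numpy() == pytest.approx(
            bh_oracle(frame["p"].to_numpy())
        )

    def test_paired_shift_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=12), rng.normal(size=12)
        a = paired_contrast(x, y)
        b = paired_contrast(x + 5.0, y + 5.0)
        assert a["t"] == pytest.approx(b["t"])
        assert a["d"] == pytest.approx(b["d"])

    def test_welch_for_independent(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, size=30)
        y = rng.normal(0, 4, size=10)
        res = independent_contrast(x, y)
        # Welch df is non-integer and below the pooled df
        assert res["df"] < 38 and res["df"] != int(res["df"])

    def test_cohens_d_pooled(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([3.0, 4.0, 5.0, 6.0])
        res = independent_contrast(x, y)
        pooled_sd = np.sqrt((3 * x.var(ddof=1) + 3 * y.var(ddof=1)) / 6)
        assert res["d"] == pytest.approx((x.mean() - y.mean()) / pooled_sd)

    def test_undersized_cell_skipped(self):
        frame = planned_contrasts([("tiny", [1.0], [2.0], False)])
        assert frame.empty


class TestPcaVarimax:
    def _planted_two_factor(self, n=300, seed=0, noise=0.3):
        rng = np.random.default_rng(seed)
        f = rng.normal(size=(n, 2))
        loadings = np.array(
            [[0.9, 0.0], [0.85, 0.1], [0.8, 0.0], [0.0, 0.9], [0.1, 0.85], [0.0, 0.8]]
        )
        X = f @ loadings.T + noise * rng.normal(size=(n, 6))
        return pd.DataFrame(X, columns=[f"v{i}" for i in range(6)])

    def test_planted_structure_recovered(self):
        res = pca_varimax(self._planted_two_factor())
        assert res.n_retained == 2
        salient = res.salient
        # each planted variable loads saliently on exactly one component
        assert (salient.sum(axis=1) == 1).all()
        first_block = salient.iloc[:3].idxmax(axis=1).nunique()
        assert first_block == 1

    def test_communalities_preserved(self):
        res = pca_varimax(self._planted_two_factor(seed=1))
        before = (res.loadings**2).sum(axis=1)
        after = (res.rotated_loadings**2).sum(axis=1)
        assert np.allclose(before, after, atol=1e-8)

    def test_rotation_orthonormal(self):
        res = pca_varimax(self._planted_two_factor(seed=2))
        R = res.rotation_matrix
        assert np.allclose(R @ R.T, np.eye(R.shape[0]), atol=1e-10)

    def test_scores_zero_mean(self):
        res = pca_varimax(self._planted_two_factor(seed=3))
        assert np.allclose(res.scores.mean(axis=0), 0, atol=1e-10)

    def test_eigenvalues_non_increasing(self):
        res = pca_varimax(self._planted_two_factor(seed=4))
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_identity_correlation_strict_threshold(self):
        # exactly orthogonal columns: every eigenvalue is exactly 1, and the
        # strict ">" retains nothing
        n = 64
        t = np.arange(n)
        X = np.column_stack(
            [np.cos(np.pi * (t + 0.5) * k / n) for k in range(1, 5)]
        )
        frame = pd.DataFrame(X, columns=list("abcd"))
        with pytest.raises(ValueError, match="nothing retained"):
            pca_varimax(frame)

    def test_constant_column_rejected(self):
        frame = self._planted_two_factor()
        frame["flat"] = 1.0
        with pytest.raises(ValueError, match="flat"):
            pca_varimax(frame)

    def test_variance_explained_sums_below_one(self):
        res = pca_varimax(self._planted_two_factor(seed=5))
        assert 0 < res.variance_explained.sum() <= 1


class TestBackwardStepwise:
    def test_signal_predictor_retained(self):
        rng = np.random.default_rng(0)
        n = 40
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = 2.0 * x1 + 0.01 * rng.normal(size=n)
        res = backward_stepwise(y, pd.DataFrame({"x1": x1, "x2": x2}))
        assert res.retained == ["x1"]
        assert "x2" in res.dropped

    def test_all_noise_intercept_only(self):
        rng = np.random.default_rng(9)
        n = 60
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
        y = rng.normal(size=n)
        res = backward_stepwise(y, X, removal_alpha=0.01)
        assert res.retained == []

    def test_single_significant_predictor_unchanged(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        y = x + 0.1 * rng.normal(size=30)
        res = backward_stepwise(y, pd.DataFrame({"x": x}))
        assert res.retained == ["x"]
        assert res.dropped == []

    def test_collinear_predictor_dropped(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        X = pd.DataFrame({"x": x, "x_copy": x})
        y = x + 0.1 * rng.normal(size=30)
        res = backward_stepwise(y, X)
        assert "x_copy" in res.dropped
        assert res.retained == ["x"]

    def test_padj_is_bh_of_coefficients(self):
        rng = np.random.default_rng(3)
        n = 50
        X = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"])
        y = X["a"] + 0.5 * X["b"] + 0.5 * rng.normal(size=n)
        res = backward_stepwise(y.to_numpy(), X)
        coef = res.coefficients
        assert coef["p_adj"].to_numpy() == pytest.approx(
            bh_oracle(coef["p"].to_numpy())
        )

    def test_r_squared_reported(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        y = x + 0.1 * rng.normal(size=30)
        res = backward_stepwise(y, pd.DataFrame({"x": x}))
        assert 0.9 < res.r_squared <= 1.0
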