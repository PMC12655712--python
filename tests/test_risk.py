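"""Multinomial logistic fits, bootstrap stability selection and composite
risk factors, cross-checked against closed forms and statsmodels."""

import numpy as np
import pandas as pd
import pytest

from milksupply import risk


def simulate_multinomial(rng, n, coefs, p_x=0.4):
    """Outcome with K levels from a known logit model on one binary x."""
    x = (rng.random(n) < p_x).astype(float)
    X = np.column_stack([np.ones(n), x])
    eta = np.hstack([np.zeros((n, 1)), X @ np.asarray(coefs).T])
    P = np.exp(eta) / np.exp(eta).sum(1, keepdims=True)
    y = np.array([rng.choice(P.shape[1], p=p) for p in P])
    return X, x, y


class TestFitMultinomial:
    def test_intercept_only_recovers_sample_proportions(self):
        counts = {1: 254, 2: 30, 3: 56, 4: 120}
        y = np.repeat(list(counts), list(counts.values()))
        X = np.ones((len(y), 1))
        m = risk.fit_multinomial(X, y, feature_names=["intercept"],
                                 reference_level=1)
        probs = m.predict_proba(np.ones((1, 1)))[0]
        expected = np.array(list(counts.values())) / len(y)
        assert probs == pytest.approx(expected, abs=1e-6)

    def test_two_by_two_odds_ratio_closed_form(self):
        # exposure x outcome counts (31,16 / 101,86): OR = 31*86/(16*101)
        y = np.array([1] * 101 + [1] * 86 + [3] * 31 + [3] * 16)
        x = np.array([1.0] * 101 + [0.0] * 86 + [1.0] * 31 + [0.0] * 16)
        X = np.column_stack([np.ones_like(x), x])
        m = risk.fit_multinomial(X, y, feature_names=["intercept", "x"],
                                 reference_level=1)
        assert m.odds_ratios[0, 1] == pytest.approx(31 * 86 / (16 * 101), rel=1e-6)

    def test_binary_outcome_matches_statsmodels_logit(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(12)
        n = 400
        x1 = rng.normal(size=n)
        x2 = (rng.random(n) < 0.3).astype(float)
        eta = -0.5 + 0.8 * x1 - 0.6 * x2
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        X = np.column_stack([np.ones(n), x1, x2])
        ours = risk.fit_multinomial(X, y, reference_level=0)
        theirs = sm.Logit(y, X).fit(disp=0)
        assert ours.coef[0] == pytest.approx(theirs.params, abs=1e-5)
        assert ours.se[0] == pytest.approx(theirs.bse, rel=1e-3)

    def test_four_level_outcome_matches_statsmodels_mnlogit(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(15)
        coefs = [[-1.0, 0.8], [-0.4, -0.5], [-1.5, 1.2]]
        X, x, y = simulate_multinomial(rng, 600, coefs)
        ours = risk.fit_multinomial(X, y, reference_level=0)
        theirs = sm.MNLogit(y, X).fit(disp=0)
        assert ours.coef.T == pytest.approx(np.asarray(theirs.params), abs=1e-4)

    def test_reference_level_change_is_coefficient_shift(self):
        rng = np.random.default_rng(16)
        coefs = [[-1.0, 0.8], [-0.4, -0.5]]
        X, x, y = simulate_multinomial(rng, 800, coefs)
        m0 = risk.fit_multinomial(X, y, reference_level=0)
        m1 = risk.fit_multinomial(X, y, reference_level=1)
        # beta(k | ref=1) = beta(k | ref=0) - beta(1 | ref=0)
        b_level2_ref0 = m0.coef[1]
        b_level1_ref0 = m0.coef[0]
        idx = m1.levels.index(2) - 1
        assert m1.coef[idx] == pytest.approx(b_level2_ref0 - b_level1_ref0,
                                             abs=1e-5)

    def test_gradient_norm_small_at_convergence(self):
        rng = np.random.default_rng(17)
        X, x, y = simulate_multinomial(rng, 300, [[-0.5, 0.6], [-1.0, -0.3]])
        m = risk.fit_multinomial(X, y, reference_level=0)
        assert m.converged and m.grad_norm < 1e-6

    def test_coefficient_bias_vanishes_large_n(self):
        """Averaged over replicates at n = 5000, the MLE's bias on every
        coefficient is below 0.05."""
        rng = np.random.default_rng(18)
        coefs = np.array([[-1.0, 0.9], [-0.6, -0.7], [-1.8, 1.4]])
        acc = np.zeros_like(coefs)
        reps = 10
        for _ in range(reps):
            X, x, y = simulate_multinomial(rng, 5000, coefs)
            m = risk.fit_multinomial(X, y, reference_level=0)
            acc += m.coef
        assert np.abs(acc / reps - coefs).max() < 0.05

    def test_wald_ci_coverage_near_nominal(self):
        """95% Wald CI for a single slope covers the truth at close to the
        nominal rate over repeated simulations."""
        rng = np.random.default_rng(19)
        beta = 0.7
        hits = 0
        reps = 300
        for _ in range(reps):
            X, x, y = simulate_multinomial(
                rng, 800, [[-0.8, beta], [-1.2, -0.4]]
            )
            m = risk.fit_multinomial(X, y, reference_level=0)
            lo, hi = m.ci()
            i = m.feature_names.index("x1")
            if lo[0, i] <= np.exp(beta) <= hi[0, i]:
                hits += 1
        assert 0.92 <= hits / reps <= 0.98


class TestStabilitySelection:
    @staticmethod
    def _cohort(rng, n, strong=None):
        df = pd.DataFrame({f"f{i}": rng.random(n) < 0.3 for i in range(6)})
        df["age"] = rng.normal(30, 4, n)
        df["conf"] = rng.random(n) < 0.5
        eta2 = -1.2 + (np.log(4.0) * df["f0"] if strong else 0.0)
        p2 = 1 / (1 + np.exp(-eta2))
        u = rng.random(n)
        df["cls"] = np.where(u < p2 * 0.5, 2, np.where(u < p2, 3, 1))
        return df

    def test_single_resample_keeping_all(self):
        rng = np.random.default_rng(30)
        df = self._cohort(rng, 300, strong=True)
        sel = risk.bootstrap_stability(
            df, "cls", [f"f{i}" for i in range(6)], ["age", "conf"],
            B=1, seed=1, reference_level=1,
        )
        assert sel.B == 1
        assert set(sel.frequencies) == {f"f{i}" for i in range(6)}
        assert all(v in (0.0, 1.0) for v in sel.frequencies.values())

    def test_confounders_never_selectable(self):
        rng = np.random.default_rng(31)
        df = self._cohort(rng, 300, strong=True)
        sel = risk.bootstrap_stability(
            df, "cls", ["f0", "f1"], ["age", "conf"], B=3, seed=2,
            reference_level=1,
        )
        assert "age" not in sel.frequencies
        assert set(sel.retained) <= {"f0", "f1"}

    def test_null_factors_rarely_retained(self):
        rng = np.random.default_rng(32)
        df = self._cohort(rng, 1200, strong=False)
        sel = risk.bootstrap_stability(
            df, "cls", [f"f{i}" for i in range(6)], ["age", "conf"],
            B=30, seed=3, reference_level=1,
        )
        assert sum(f > 0.5 for f in sel.frequencies.values()) <= 1

    def test_strong_factor_reliably_retained(self):
        rng = np.random.default_rng(33)
        df = self._cohort(rng, 1200, strong=True)
        sel = risk.bootstrap_stability(
            df, "cls", [f"f{i}" for i in range(6)], ["age", "conf"],
            B=30, seed=4, reference_level=1,
        )
        assert sel.frequencies["f0"] > 0.9
        assert "f0" in sel.retained


class TestComposite:
    def test_four_level_coding(self):
        a = pd.Series([False, True, False, True, pd.NA], dtype="boolean")
        b = pd.Series([False, False, True, True, True], dtype="boolean")
        comp = risk.make_composite(a, b)
        assert list(comp[:4]) == ["neither", "a_only", "b_only", "both"]
        assert pd.isna(comp[4])

    def test_level_counts_equal_crosstab(self):
        rng = np.random.default_rng(40)
        a = pd.Series(rng.random(500) < 0.4, dtype="boolean")
        b = pd.Series(rng.random(500) < 0.3, dtype="boolean")
        comp = risk.make_composite(a, b)
        counts = comp.value_counts()
        assert counts["both"] == int((a & b).sum())
        assert counts["a_only"] == int((a & ~b).sum())
        assert counts["b_only"] == int((~a & b).sum())
        assert counts["neither"] == int((~a & ~b).sum())

    def test_degenerate_composite_nests_single_factor_model(self):
        """When the second flag is always false, the A-only odds ratio
        equals the flag's odds ratio from the plain model."""
        rng = np.random.default_rng(41)
        n = 800
        a = rng.random(n) < 0.4
        eta = -1.0 + 1.1 * a
        y = np.where(rng.random(n) < 1 / (1 + np.exp(-eta)), 2, 1)
        df = pd.DataFrame({
            "class_label": y,
            "a": pd.array(a, dtype="boolean"),
            "b": pd.array(np.zeros(n, bool), dtype="boolean"),
            "age": rng.normal(30, 4, n),
        })
        plain = risk.fit_multinomial_df(df, "class_label", ["a", "age"],
                                        reference_level=1)
        comp = risk.make_composite(df["a"], df["b"], name="ab")
        model, info = risk.fit_composite_model(
            df, comp, retained_predictors=[], confounders=["age"],
            source_flags=("a", "b"), reference_level=1,
        )
        assert info["undefined_levels"] == ["b_only", "both"]
        i_plain = plain.feature_names.index("a")
        i_comp = model.feature_names.index("ab_a_only")
        assert model.coef[0, i_comp] == pytest.approx(
            plain.coef[0, i_plain], abs=1e-6
        )

    def test_superadditive_interaction_recovered(self):
        """A both-levels odds ratio of 9 with mild single-factor effects is
        recovered within 1.5x at n = 2000."""
        rng = np.random.default_rng(42)
        n = 2000
        a = rng.random(n) < 0.35
        b = rng.random(n) < 0.35
        eta = -1.6 + np.log(1.8) * (a & ~b) + np.log(2.0) * (b & ~a) \
            + np.log(9.0) * (a & b)
        y = np.where(rng.random(n) < 1 / (1 + np.exp(-eta)), 3, 1)
        df = pd.DataFrame({
            "class_label": y,
            "a": pd.array(a, dtype="boolean"),
            "b": pd.array(b, dtype="boolean"),
            "age": rng.normal(30, 4, n),
        })
        comp = risk.make_composite(df["a"], df["b"], name="ab")
        model, _ = risk.fit_composite_model(
            df, comp, retained_predictors=[], confounders=["age"],
            source_flags=("a", "b"), reference_level=1,
        )
        i = model.feature_names.index("ab_both")
        assert 9.0 / 1.5 <= np.exp(model.coef[0, i]) <= 9.0 * 1.5
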