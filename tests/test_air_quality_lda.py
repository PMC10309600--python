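"""Fisher LDA, ROC AUC and filter-style variable importance."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from aeroyield.air_quality_lda import (
    AirQualityLDA,
    _solve_discriminant,
    fit_lda,
    label_sufficiency,
    roc_auc,
    variable_importance,
)
from aeroyield.exceptions import DegenerateLabelsError, SchemaError
from aeroyield.synthetic_data import AirGenSpec, gen_air_quality


def _pair_auc(scores, labels):
    """Brute-force Mann-Whitney oracle over all positive-negative pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestLabels:
    def test_threshold_is_inclusive(self):
        labels = label_sufficiency([9.9, 10.0, 10.1], 10.0)
        assert labels.tolist() == [0, 1, 1]

    def test_single_class_warned(self):
        with pytest.warns(UserWarning, match="single-class"):
            labels = label_sufficiency([1.0, 2.0], 10.0)
        assert labels.tolist() == [0, 0]

    def test_missing_yield_column(self):
        with pytest.raises(SchemaError, match="yield_ng"):
            label_sufficiency(pd.DataFrame({"pm_0_3": [1.0]}))


class TestFitLda:
    def test_separated_classes_rank_correctly(self, rng):
        x = np.concatenate([rng.normal(-3, 1, 50), rng.normal(3, 1, 50)])[:, None]
        y = np.repeat([0, 1], 50)
        model = fit_lda(x, y)
        assert roc_auc(model.scores(x), y) >= 0.99

    def test_no_signal_auc_near_half(self, rng):
        x = rng.normal(0, 1, (200, 3))
        y = np.repeat([0, 1], 100)
        model = fit_lda(x, y)
        assert roc_auc(model.scores(x), y) == pytest.approx(0.5, abs=0.1)

    def test_hand_inverted_diagonal_covariance(self):
        w = _solve_discriminant(np.array([[1.0, 0.0], [0.0, 4.0]]), np.array([1.0, 1.0]))
        assert w[0] / w[1] == pytest.approx(4.0)  # w proportional to (1, 0.25)

    def test_matches_sklearn_ranking(self, rng):
        x = rng.normal(0, 1, (120, 4))
        y = (x[:, 0] + 0.5 * x[:, 2] + rng.normal(0, 1, 120) > 0).astype(int)
        ours = fit_lda(x, y)
        sk = LinearDiscriminantAnalysis().fit(x, y)
        assert roc_auc(ours.scores(x), y) == pytest.approx(
            roc_auc(sk.decision_function(x), y), abs=1e-12
        )

    def test_affine_rescaling_invariance(self, rng):
        x = rng.normal(0, 1, (80, 3))
        y = (x[:, 0] > 0).astype(int)
        s1 = fit_lda(x, y).scores(x)
        x2 = x.copy()
        x2[:, 1] = 1000.0 * x2[:, 1] - 77.0
        s2 = fit_lda(x2, y).scores(x2)
        np.testing.assert_allclose(s1, s2, atol=1e-10)

    def test_standardisation_stored(self, rng):
        x = rng.normal(5, 3, (60, 2))
        y = np.repeat([0, 1], 30)
        model = fit_lda(x, y)
        z = model.standardize(x)
        np.testing.assert_allclose(z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            fit_lda(np.random.default_rng(0).normal(size=(10, 2)), np.zeros(10))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0

    def test_all_ties(self):
        assert roc_auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_stated_example(self):
        assert roc_auc([1, 2, 3, 4, 5, 6], [0, 0, 1, 0, 1, 1]) == pytest.approx(8 / 9)

    def test_matches_pair_enumeration_on_all_six_point_sets(self, rng):
        score_sets = [
            [1, 2, 3, 4, 5, 6],
            [1, 1, 2, 2, 3, 3],
            [0.5, 0.5, 0.5, 1.0, 1.0, 2.0],
            list(rng.normal(size=6)),
        ]
        for scores in score_sets:
            for labels in itertools.product([0, 1], repeat=6):
                if 0 < sum(labels) < 6:
                    assert roc_auc(scores, labels) == pytest.approx(
                        _pair_auc(scores, labels), abs=1e-12
                    )

    def test_negation_antisymmetry(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        assert roc_auc(scores, labels) + roc_auc(-scores, labels) == pytest.approx(1.0)


class TestVariableImportance:
    def test_null_variable_lowest(self, rng):
        n = 500
        signal = rng.normal(0, 1, n)
        y = (signal + rng.normal(0, 0.5, n) > 0).astype(int)
        null = rng.permutation(signal)
        rep = variable_importance(np.column_stack([signal, null]), y, ["sig", "null"])
        assert rep.raw_auc["null"] == pytest.approx(0.5, abs=0.06)
        assert rep.importance["sig"] == 100.0
        assert rep.importance["null"] == 0.0

    def test_two_variable_scaling(self, rng):
        n = 300
        y = rng.integers(0, 2, n)
        x1 = y + rng.normal(0, 0.3, n)
        x2 = y + rng.normal(0, 3.0, n)
        rep = variable_importance(np.column_stack([x1, x2]), y)
        assert rep.importance["x0"] == 100.0
        assert rep.importance["x1"] == 0.0

    def test_monotone_transform_invariance(self, rng):
        n = 200
        y = rng.integers(0, 2, n)
        x = np.column_stack([y + rng.normal(0, 1, n), rng.normal(2, 1, n)])
        r1 = variable_importance(x, y)
        x2 = x.copy()
        x2[:, 0] = np.exp(x2[:, 0])  # strictly increasing
        r2 = variable_importance(x2, y)
        assert r1.raw_auc["x0"] == pytest.approx(r2.raw_auc["x0"], abs=1e-12)

    def test_folding_handles_inverted_predictors(self, rng):
        n = 400
        y = rng.integers(0, 2, n)
        x = np.column_stack([-2.0 * y + rng.normal(0, 0.3, n), rng.normal(size=n)])
        rep = variable_importance(x, y)
        assert rep.raw_auc["x0"] > 0.9  # folded despite negative association
        assert rep.importance["x0"] == 100.0


class TestCaretOracle:
    def test_folded_auc_matches_caret_filter_importance(self, rng, tmp_path):
        """Independent oracle: caret::filterVarImp on the same small table."""
        import subprocess

        n = 40
        y = rng.integers(0, 2, n)
        x = np.column_stack(
            [
                y + rng.normal(0, 0.8, n),
                -y + rng.normal(0, 1.5, n),  # negatively associated: folding matters
                rng.normal(0, 1, n),
            ]
        )
        df = pd.DataFrame(x, columns=["x1", "x2", "x3"]).assign(y=y)
        data_csv, out_csv = tmp_path / "in.csv", tmp_path / "out.csv"
        df.to_csv(data_csv, index=False)
        script = tmp_path / "oracle.R"
        script.write_text(
            'args <- commandArgs(trailingOnly = TRUE)\n'
            'd <- read.csv(args[1])\n'
            'suppressMessages(library(caret))\n'
            'imp <- filterVarImp(d[, c("x1", "x2", "x3")], factor(d$y))\n'
            'write.csv(imp, args[2])\n'
        )
        subprocess.run(
            ["Rscript", str(script), str(data_csv), str(out_csv)],
            check=True, capture_output=True,
        )
        caret = pd.read_csv(out_csv, index_col=0)["X0"]
        rep = variable_importance(x, y, ["x1", "x2", "x3"])
        for var in ("x1", "x2", "x3"):
            assert rep.raw_auc[var] == pytest.approx(caret[var], abs=1e-9)


class TestModelInterface:
    def _df(self, rng, n=240):
        spec = AirGenSpec(n_records=n, rng_seed=int(rng.integers(2**31)))
        df, _ = gen_air_quality(spec)
        return df

    def test_bayes_auc_convergence(self, rng):
        # two shared-covariance Gaussians: Bayes AUC = Phi(Delta / sqrt(2))
        from scipy.stats import norm

        n = 5000
        mu = np.array([1.0, 0.5])
        cov = np.array([[1.0, 0.3], [0.3, 2.0]])
        delta = np.sqrt(mu @ np.linalg.solve(cov, mu))
        L = np.linalg.cholesky(cov)
        x0 = rng.standard_normal((n, 2)) @ L.T
        x1 = rng.standard_normal((n, 2)) @ L.T + mu
        x = np.vstack([x0, x1])
        y = np.repeat([0, 1], n)
        fit = AirQualityLDA(x, y.astype(float)).fit()
        assert fit.auc("resubstitution") == pytest.approx(norm.cdf(delta / np.sqrt(2)), abs=0.02)

    def test_loo_not_above_resubstitution_on_average(self, rng):
        diffs = []
        for _ in range(20):
            df = self._df(rng, n=60)
            fit = AirQualityLDA.from_dataframe(df.drop(columns=["hour_index"])).fit()
            diffs.append(fit.auc("resubstitution") - fit.auc("loo"))
        assert np.mean(diffs) >= 0

    def test_fit_by_hour_strata_independent(self, rng):
        df = self._df(rng, n=360)
        fits = AirQualityLDA.fit_by_hour(df)
        assert set(fits) == {"H1", "H2", "H3"}
        h1 = df[df["hour_index"] == "H1"].drop(columns=["hour_index"])
        direct = AirQualityLDA.from_dataframe(h1).fit()
        np.testing.assert_allclose(fits["H1"].lda.w, direct.lda.w)

    def test_planted_fine_pm_signal_important_in_every_stratum(self):
        df, _ = gen_air_quality(AirGenSpec(n_records=600, rng_seed=42))
        for fit in AirQualityLDA.fit_by_hour(df).values():
            rep = fit.importance()
            for var in ("pm_0_3", "pm_0_5", "pm_1_0"):
                assert rep.importance[var] > 70

    def test_summary_lists_all_variables(self, rng):
        df = self._df(rng)
        fit = AirQualityLDA.from_dataframe(df.drop(columns=["hour_index"])).fit()
        text = fit.summary()
        for var in ("pm_0_3", "pm_10", "wb", "rh"):
            assert var in text
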