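"""Fisher discriminant: closed forms, invariances, stepwise selection, fixture."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wavetex import (
    REFERENCE_GROUP_MEANS,
    SyntheticCohortConfig,
    fit_lda,
    generate_feature_cohort,
    reference_model,
    stepwise_select,
)
from wavetex.features import FeatureTable, feature_names

# entry threshold calibrated for screening ~120 null candidates at once
# (Bonferroni-style: the classical single-test 3.84 admits the maximum of
# >100 null F statistics almost surely)
F_STRICT = float(stats.f.isf(0.05 / 120, 1, 19))


def _table(X, y, names=None):
    names = names or [f"f{i}" for i in range(X.shape[1])]
    df = pd.DataFrame(X, columns=names,
                      index=pd.Index([f"s{i}" for i in range(len(y))], name="subject_id"))
    df.insert(0, "label", y)
    return FeatureTable(df)


class TestFitLda:
    def test_one_dimensional_closed_form(self):
        # class means 0 and 1 with equal within-class sd s -> coefficient 1/s
        s = 2.0
        x = np.array([-s, s, -s, s, 1 - s, 1 + s, 1 - s, 1 + s])
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        model = fit_lda(_table(x[:, None], y), ["f0"])
        sd_within = np.sqrt((4 * s**2 + 4 * s**2) / 6)  # n - 2 denominator
        assert abs(model.coefficients[0] - 1 / sd_within) < 1e-12
        ds = model.score_table(_table(x[:, None], y))
        sep = ds[y == 1].mean() - ds[y == 0].mean()
        assert abs(sep - 1 / sd_within) < 1e-12

    def test_ds_convention_unit_variance_zero_mean(self, separated_feature_cohort):
        names = ["db2dec2sd", "bior33dec1max", "bior33dec3mn"]
        model = fit_lda(separated_feature_cohort, names)
        ds = model.score_table(separated_feature_cohort).to_numpy()
        y = separated_feature_cohort.labels
        assert abs(ds.mean()) < 1e-9  # weighted grand mean 0
        pooled = (np.sum((ds[y == 1] - ds[y == 1].mean()) ** 2)
                  + np.sum((ds[y == 0] - ds[y == 0].mean()) ** 2)) / (len(ds) - 2)
        assert abs(pooled - 1.0) < 1e-9  # pooled within-class variance 1
        assert ds[y == 1].mean() > ds[y == 0].mean()  # positives score higher

    def test_affine_invariance(self, separated_feature_cohort, rng):
        names = ["db1dec1mn", "db2dec2sd", "sym5dec2mn", "coif1dec3md"]
        base = fit_lda(separated_feature_cohort, names)
        ds0 = base.score_table(separated_feature_cohort).to_numpy()
        A = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        b = rng.normal(size=4) * 10
        df = separated_feature_cohort.data.copy()
        df[names] = df[names].to_numpy() @ A.T + b
        trans = fit_lda(FeatureTable(df), names)
        ds1 = trans.score_table(FeatureTable(df)).to_numpy()
        np.testing.assert_allclose(ds0, ds1, atol=1e-8)

    def test_matches_sklearn_direction(self, separated_feature_cohort):
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        names = ["db2dec2sd", "bior33dec1max", "sym5dec2mn"]
        model = fit_lda(separated_feature_cohort, names)
        lda = sklearn.LinearDiscriminantAnalysis(solver="lsqr")
        lda.fit(separated_feature_cohort.data[names].to_numpy(),
                separated_feature_cohort.labels)
        ratio = lda.coef_.ravel() / model.coefficients
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-6)

    def test_duplicated_feature_is_singular(self, separated_feature_cohort):
        df = separated_feature_cohort.data.copy()
        df["dupe"] = df["db1dec1mn"]
        with pytest.raises(ValueError, match="singular|collinear"):
            fit_lda(FeatureTable(df), ["db1dec1mn", "dupe"])

    def test_small_class_rejected(self):
        x = np.arange(6, dtype=float)[:, None]
        with pytest.raises(ValueError):
            fit_lda(_table(x, np.array([1, 0, 0, 0, 0, 0])), ["f0"])

    def test_too_many_features_rejected(self, null_feature_cohort):
        names = feature_names()[:21]  # 22 subjects: need p < 20
        with pytest.raises(ValueError, match="p < n"):
            fit_lda(null_feature_cohort, names)


class TestStepwise:
    def test_single_feature_enters_iff_f_exceeds_threshold(self, rng):
        # strong single feature
        y = np.array([1] * 8 + [0] * 8)
        x_strong = (rng.normal(size=16) + 4.0 * y)[:, None]
        res = stepwise_select(_table(x_strong, y))
        assert res.selected == ("f0",)
        # null single feature at a fixed seed with F below threshold
        x_weak = rng.normal(size=16)[:, None]
        res2 = stepwise_select(_table(x_weak, y))
        f_vals = res2.trace[0]["F"]
        if res2.selected:
            assert f_vals["f0"] >= 3.84
        else:
            assert f_vals["f0"] < 3.84

    def test_two_informative_recovered_with_little_noise(self, rng):
        """Two features carrying all separation among 118 nulls are found;
        at an entry threshold calibrated for 120 candidates at most one
        noise feature slips in."""
        n = 40  # the partial F of a second informative feature is bounded
        # by ~n-3, so the cohort must comfortably exceed the entry threshold
        y = np.array([1] * (n // 2) + [0] * (n // 2))
        X = rng.normal(size=(n, 120))
        X[:, 3] += 5.0 * y
        X[:, 77] += 5.0 * (1 - y)  # informative with opposite polarity
        names = feature_names()
        f_strict = float(stats.f.isf(0.05 / 120, 1, n - 3))
        res = stepwise_select(_table(X, y, names), f_enter=f_strict,
                              f_remove=f_strict - 1)
        selected = set(res.selected)
        assert {names[3], names[77]} <= selected
        assert len(selected - {names[3], names[77]}) <= 1

    def test_pure_noise_selects_nothing_at_calibrated_threshold(self):
        """Null tables yield an empty model in >= 90% of 50 seeds when the
        entry threshold accounts for the 120-candidate search."""
        empty = 0
        for s in range(50):
            ft = generate_feature_cohort(
                SyntheticCohortConfig(effect=0.0, seed=1000 + s), rho=0.0)
            res = stepwise_select(ft, f_enter=F_STRICT, f_remove=F_STRICT - 1)
            empty += not res.selected
        assert empty >= 45

    def test_trace_records_candidates(self, separated_feature_cohort):
        res = stepwise_select(separated_feature_cohort, max_features=3)
        assert res.selected
        enters = [t for t in res.trace if t["action"] == "enter"]
        assert len(enters) == len(res.selected) or any(
            t["action"] == "remove" for t in res.trace)
        assert all(isinstance(t["F"], dict) for t in res.trace
                   if t["action"] == "enter-candidates")


class TestReferenceModel:
    def test_group_means_worked_example(self):
        """The published four-variable score formula separates the two
        group-mean vectors at roughly +/-6, straddling the cutoff."""
        m = reference_model()
        ds_pos = m.score(REFERENCE_GROUP_MEANS["pcr_present"])
        ds_neg = m.score(REFERENCE_GROUP_MEANS["pcr_absent"])
        assert abs(ds_pos - 6.0) < 0.05
        assert abs(ds_neg + 6.0) < 0.05
        assert ds_pos > m.cutoff > ds_neg

    def test_all_zero_vector_scores_constant(self):
        m = reference_model()
        zero = {name: 0.0 for name in m.feature_names}
        assert m.score(zero) == -541.1768021

    def test_has_exactly_four_features(self):
        assert len(reference_model().feature_names) == 4

    def test_missing_feature_named_in_error(self):
        m = reference_model()
        with pytest.raises(KeyError, match="sym5dec2mn"):
            m.score({"db2dec2sd": 1.0, "bior33dec1max": 1.0, "bior33dec3mn": 1.0})

    def test_json_round_trip_preserves_digits(self, tmp_path):
        m = reference_model()
        path = tmp_path / "model.json"
        m.to_json(path)
        back = type(m).from_json(path)
        assert back.feature_names == m.feature_names
        np.testing.assert_array_equal(back.coefficients, m.coefficients)
        assert back.constant == m.constant
        assert back.cutoff == m.cutoff
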