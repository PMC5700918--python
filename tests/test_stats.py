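"""Behavioural-statistics unit tests: hand-computed metric values, GLM
coefficient recovery, textbook ANOVA arithmetic, studentized-range
comparisons, PCA spectra and UPGMA merge structure."""

import numpy as np
import pandas as pd
import pytest

from sfdispersal import stats
from sfdispersal.stats import (
    Dendrogram, analyze_tracks, boxcox_anova, cluster_treatments,
    compute_metrics, fit_survival_logistic, halfnormal_envelope,
    kaiser_retained, pca_correlation, pearson_corr, tukey_pairwise,
)
from sfdispersal.synthetic import (BioassayDesign, BioassayParams,
                                   generate_bioassay, generate_tracks)
from sfdispersal.util import expit

from conftest import make_record


class TestComputeMetrics:
    def test_hand_computed_proportions(self):
        rec = make_record(on_fed=10, on_notfed=2, off_fed=3, off_notfed=1,
                          unrecovered=4)
        m = compute_metrics(rec).iloc[0]
        assert m["survival"] == pytest.approx(0.80)
        assert m["host_acceptance"] == pytest.approx(0.75)
        assert m["dispersal_rate"] == pytest.approx(0.25)
        assert m["pfd"] == pytest.approx(0.1875)
        assert m["ifp"] == pytest.approx(0.625)

    def test_all_on_plant_fed(self):
        m = compute_metrics(make_record(20, 0, 0, 0, 0)).iloc[0]
        assert m["dispersal_rate"] == 0
        assert m["ifp"] == 1
        assert m["pfd"] == 0

    def test_all_unrecovered_gives_missing_not_zero_division(self):
        m = compute_metrics(make_record(0, 0, 0, 0, 20)).iloc[0]
        assert m["survival"] == 0
        assert m[["host_acceptance", "dispersal_rate",
                  "pfd", "ifp"]].isna().all()

    def test_released_denominator_mode(self):
        rec = make_record(10, 2, 3, 1, 4)
        m = compute_metrics(rec, denominator_mode="released").iloc[0]
        assert m["host_acceptance"] == pytest.approx(12 / 20)
        assert m["pfd"] == pytest.approx(3 / 20)

    def test_negative_counts_rejected(self):
        rec = make_record(10, 2, 3, 1, 4)
        rec.loc[0, "on_fed"] = -1
        rec.loc[0, "unrecovered"] = 15
        with pytest.raises(ValueError, match="negative"):
            compute_metrics(rec)

    def test_conservation_violation_lists_rows(self):
        rec = make_record(10, 2, 3, 1, 4)
        rec.loc[0, "released"] = 19
        with pytest.raises(ValueError, match="conservation"):
            compute_metrics(rec)

    def test_identities_on_generated_table(self, small_bioassay):
        m = compute_metrics(small_bioassay).dropna()
        assert ((m[["survival", "host_acceptance", "dispersal_rate",
                    "pfd", "ifp"]] >= 0).all().all())
        assert np.allclose(m["host_acceptance"] + m["dispersal_rate"], 1.0)
        assert (m["pfd"] <= m["dispersal_rate"] + 1e-12).all()
        assert (m["ifp"] <= m["host_acceptance"] + 1e-12).all()


def _survival_table(b0, b1, n_plants, rng, strain="SS"):
    """Binomial survival counts per plant from a logistic-in-time model."""
    rows = []
    for t in (6, 12, 18, 24):
        p = expit(b0 + b1 * t)
        alive = rng.binomial(20, p, size=n_plants)
        for i, a in enumerate(alive):
            rows.append([i + 1, strain, "NONBT", t, 20, a, 0, 0, 0, 20 - a])
    return pd.DataFrame(rows, columns=[
        "block", "strain", "variety", "interval_h", "released",
        "on_fed", "on_notfed", "off_fed", "off_notfed", "unrecovered"])


class TestSurvivalLogistic:
    @pytest.mark.parametrize("b0,b1", [(2.7690, -0.1470), (1.1089, -0.0483)])
    def test_recovers_generating_coefficients(self, b0, b1, rng):
        fit = fit_survival_logistic(_survival_table(b0, b1, 250, rng), "SS")
        assert fit.b1 == pytest.approx(b1, abs=0.01)
        assert fit.b0 == pytest.approx(b0, abs=0.15)
        assert not fit.separable

    def test_flat_survival_gives_zero_slope(self, rng):
        fit = fit_survival_logistic(_survival_table(0.0, 0.0, 400, rng), "SS")
        assert abs(fit.b1) < 0.01
        lo, hi = fit.conf_int()[1]
        assert hi - lo < 0.05

    def test_separation_flagged_with_warning(self):
        rows = []
        for t, p in [(6, 1.0), (12, 1.0), (18, 0.0), (24, 0.0)]:
            for i in range(5):
                a = int(20 * p)
                rows.append([i, "SS", "NONBT", t, 20, a, 0, 0, 0, 20 - a])
        df = pd.DataFrame(rows, columns=_survival_table(0, 0, 1,
                          np.random.default_rng(0)).columns)
        with pytest.warns(RuntimeWarning, match="separation"):
            fit = fit_survival_logistic(df, "SS")
        assert fit.separable

    def test_single_time_point_rejected(self, rng):
        df = _survival_table(1.0, -0.1, 10, rng)
        with pytest.raises(ValueError, match="2 distinct"):
            fit_survival_logistic(df[df.interval_h == 6], "SS")

    def test_dispersion_scales_standard_errors(self, rng):
        """Quasi-binomial SEs are sqrt(dispersion) times the binomial ones."""
        fit = fit_survival_logistic(_survival_table(1.0, -0.05, 100, rng), "SS")
        assert fit.dispersion > 0
        assert fit.se_b1 > 0


class TestBoxcoxAnova:
    def test_textbook_one_way_f(self):
        df = pd.DataFrame({"y": [1, 2, 5, 6], "g": ["A", "A", "B", "B"]})
        a = boxcox_anova(df, "y", "C(g)", lam=1.0)
        assert a.effect("g")["F"] == pytest.approx(32.0)
        assert a.effect("g")["df"] == 1
        assert a.effect("Residual")["df"] == 2

    def test_equal_group_means_give_zero_f(self):
        df = pd.DataFrame({"y": [1, 2, 3, 1, 2, 3],
                           "g": ["A"] * 3 + ["B"] * 3})
        a = boxcox_anova(df, "y", "C(g)", lam=1.0)
        assert a.effect("g")["F"] == pytest.approx(0.0, abs=1e-12)

    def test_lambda_one_matches_untransformed(self, rng):
        df = pd.DataFrame({"y": rng.gamma(4, 2, 24),
                           "g": np.repeat(["A", "B", "C"], 8)})
        f_fixed = boxcox_anova(df, "y", "C(g)", lam=1.0).effect("g")["F"]
        raw = boxcox_anova(df.assign(y=df.y), "y", "C(g)", lam=None)
        # affine invariance: a separate fit with lam forced to 1 equals raw OLS
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm
        direct = anova_lm(smf.ols("y ~ C(g)", df).fit(), typ=2)
        assert f_fixed == pytest.approx(direct.loc["C(g)", "F"])
        assert -2 <= raw.lam <= 2

    def test_nonpositive_response_needs_offset(self):
        df = pd.DataFrame({"y": [0.0, 0.2, 0.4, 0.6],
                           "g": ["A", "A", "B", "B"]})
        with pytest.raises(ValueError, match="zero_offset"):
            boxcox_anova(df, "y", "C(g)")
        a = boxcox_anova(df, "y", "C(g)", lam=1.0, zero_offset=0.5 / 20)
        assert np.isfinite(a.effect("g")["F"])


class TestTukeyPairwise:
    def test_identical_groups_share_letter_with_p_one(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 1.0, 2.0],
                           "g": ["A", "A", "B", "B"]})
        res = tukey_pairwise(df, "y", "g")
        assert res.pairs["p_adj"].iloc[0] == pytest.approx(1.0, abs=1e-9)
        assert res.letters["A"] == res.letters["B"]

    def test_extreme_group_lettered_separately(self):
        df = pd.DataFrame({
            "y": [0.0, 0.1, 0.0, -0.1, 10.0, 10.1],
            "g": ["A", "A", "B", "B", "C", "C"]})
        res = tukey_pairwise(df, "y", "g")
        assert res.letters["A"] == res.letters["B"]
        assert not set(res.letters["C"]) & set(res.letters["A"])

    def test_tukey_kramer_se_for_unequal_n(self):
        df = pd.DataFrame({
            "y": [1.0, 2.0, 4.0, 5.0, 6.0, 7.0],
            "g": ["A"] * 2 + ["B"] * 4})
        res = tukey_pairwise(df, "y", "g")
        # hand computation: SSE = 0.5 + 5.0, df = 4, MSE = 1.375
        mse = (0.5 + 5.0) / 4
        se = np.sqrt(mse / 2 * (1 / 2 + 1 / 4))
        assert res.mse == pytest.approx(mse)
        assert res.pairs["se"].iloc[0] == pytest.approx(se)

    def test_adjusted_p_not_below_pairwise_t(self, rng):
        from scipy import stats as sps
        df = pd.DataFrame({"y": rng.normal(0, 1, 30),
                           "g": np.repeat(list("ABCDE"), 6)})
        res = tukey_pairwise(df, "y", "g")
        for _, row in res.pairs.iterrows():
            t = abs(row["diff"]) / (row["se"] * np.sqrt(2))
            p_t = 2 * sps.t.sf(t, res.df_resid)
            assert row["p_adj"] >= p_t - 1e-12

    def test_single_group_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2.0], "g": ["A", "A"]})
        with pytest.raises(ValueError, match="2 groups"):
            tukey_pairwise(df, "y", "g")


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 5.0, 7.0])
        assert pearson_corr(x, x) == pytest.approx(1.0)
        assert pearson_corr(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert pearson_corr([1, 2, 3], [1, 2, 4]) == pytest.approx(0.9820, abs=5e-5)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_corr([1, 1, 1], [1, 2, 3])


class TestPCA:
    def test_rank_one_correlation(self, rng):
        x = rng.normal(0, 1, 50)
        df = pd.DataFrame({"a": x, "b": 3 * x + 1})
        res = pca_correlation(df)
        assert res.eigenvalues == pytest.approx([2.0, 0.0], abs=1e-10)
        assert res.variance_explained[0] == pytest.approx(100.0)
        assert res.retained == 1

    def test_kaiser_rule_on_reported_spectrum(self):
        # leading eigenvalue fractions 39.42% and 33.79% of 4 variables
        eig = np.array([0.3942 * 4, 0.3379 * 4, 0.60, 0.4716])
        assert eig[0] == pytest.approx(1.5768)
        assert eig[1] == pytest.approx(1.3516)
        assert kaiser_retained(eig) == 2

    def test_independent_columns_give_unit_spectrum(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (100_000, 4)),
                          columns=list("abcd"))
        res = pca_correlation(df)
        assert np.all(np.abs(res.eigenvalues - 1) < 0.05)

    def test_spectrum_and_vectors_are_consistent(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (40, 5)) @ rng.normal(0, 1, (5, 5)),
                          columns=list("abcde"))
        res = pca_correlation(df)
        assert res.eigenvalues.sum() == pytest.approx(5.0, abs=1e-8)
        assert np.allclose(res.eigenvectors.T @ res.eigenvectors,
                           np.eye(5), atol=1e-8)
        assert res.variance_explained.sum() == pytest.approx(100.0)

    def test_constant_column_named_in_error(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=10), "b": np.ones(10),
                           "c": rng.normal(size=10)})
        with pytest.raises(ValueError, match="b"):
            pca_correlation(df)


class TestClustering:
    def test_duplicate_rows_merge_at_zero(self):
        d = cluster_treatments(np.array([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]]))
        assert d.merges[0, 2] == pytest.approx(0.0)

    def test_hand_upgma_on_three_points(self):
        d = cluster_treatments(np.array([0.0, 1.0, 5.0]), labels=list("xyz"))
        assert d.merges[0, 2] == pytest.approx(1.0)
        assert d.merges[1, 2] == pytest.approx(4.5)   # mean of 5 and 4

    def test_cut_counts_groups_above_threshold(self):
        Z = np.array([[0, 1, 0.5, 2], [2, 3, 0.9, 2], [4, 5, 1.4, 4]])
        d = Dendrogram(Z, ["p", "q", "r", "s"])
        assert d.n_groups(1.15) == 2
        assert d.n_groups(0.4) == 4
        assert d.n_groups(2.0) == 1

    def test_newick_roundtrip_leaf_set(self):
        labels = ["TW6", "TW12", "WS6", "NBT6"]
        d = cluster_treatments(np.arange(8.0).reshape(4, 2), labels=labels)
        nwk = d.to_newick()
        assert nwk.endswith(";")
        for lab in labels:
            assert lab in nwk

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            cluster_treatments(np.array([[0.0, np.nan], [1.0, 2.0]]))


class TestTracksAnalysis:
    def test_identical_groups_give_zero_f(self):
        rows = []
        for s in ("SS", "RR"):
            for v in ("BT_WS", "NONBT"):
                for y in (1.0, 2.0, 3.0):
                    rows.append([s, v, y, y / 10, y * 100])
        tracks = pd.DataFrame(rows, columns=[
            "strain", "variety", "distance_cm", "velocity_cm_s", "mobility_s"])
        res = analyze_tracks(tracks)
        for _, (anova, _) in res.items():
            for eff in ("strain", "variety", "strain x variety"):
                assert anova.table.loc[eff, "F"] == pytest.approx(0.0, abs=1e-10)

    def test_interaction_degrees_of_freedom(self):
        tracks = generate_tracks(5, rng=0)
        anova, _ = analyze_tracks(tracks)["distance_cm"]
        assert anova.table.loc["strain x variety", "df"] == 1

    def test_resistant_nonbt_moves_least(self):
        tracks = generate_tracks(200, rng=8)
        _, tukey = analyze_tracks(tracks)["distance_cm"]
        means = tukey.means
        assert means["RR:NONBT"] < means["RR:BT_WS"]
        assert not (set(tukey.letters["RR:NONBT"])
                    & set(tukey.letters["RR:BT_WS"]))


class TestHalfNormalEnvelope:
    def test_envelope_structure(self):
        design = BioassayDesign(n_blocks=6)
        records = generate_bioassay(design, BioassayParams(), rng=3)
        env = halfnormal_envelope(records, "SS", n_sims=99, rng=1)
        assert list(env.columns) == ["quantile", "observed", "lower", "upper"]
        assert (env["lower"] <= env["upper"]).all()
        assert env["quantile"].is_monotonic_increasing
        # a well-specified model should stay mostly inside the envelope
        inside = ((env.observed >= env.lower) & (env.observed <= env.upper))
        assert inside.mean() > 0.5
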