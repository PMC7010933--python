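"""The statistical battery: contingency, MANOVA, ANCOVA, correlation,
mismatch-group contrasts, and Tukey pairwise comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hsescan.architecture_stats import (
    ancova_magnitude,
    manova_arch_vs_response,
    mismatch_group_key,
    mismatch_position_effect,
    nucleotide_multiple_comparison,
    position_magnitude_correlation,
    response_proportion_test,
)
from hsescan.hse_scanner import scan_sequence


class TestResponseProportionTest:
    def test_equal_proportions_give_zero(self):
        res = response_proportion_test({"A": (10, 100), "B": (20, 200)})
        assert res.statistic == pytest.approx(0.0)
        assert res.df == 1

    def test_doubling_counts_doubles_statistic(self):
        counts = {"A": (10, 100), "B": (30, 150), "C": (5, 80)}
        doubled = {k: (2 * a, 2 * b) for k, (a, b) in counts.items()}
        r1 = response_proportion_test(counts)
        r2 = response_proportion_test(doubled)
        assert r2.statistic == pytest.approx(2 * r1.statistic)

    def test_row_permutation_invariance(self):
        counts = {"A": (10, 100), "B": (30, 150), "C": (5, 80)}
        perm = {"C": counts["C"], "A": counts["A"], "B": counts["B"]}
        assert response_proportion_test(counts).statistic == pytest.approx(
            response_proportion_test(perm).statistic
        )

    def test_errors(self):
        with pytest.raises(ValueError):
            response_proportion_test({"A": (1, 10)})
        with pytest.raises(ValueError):
            response_proportion_test({"A": (1, 0), "B": (2, 10)})


class TestManova:
    @staticmethod
    def _pillai_oracle(df):
        """Hand computation of Pillai's trace and its F approximation
        from between/within scatter matrices (independent of the
        fitted-model route used by the implementation)."""
        Y = df[["position", "subunit_count"]].to_numpy(dtype=float)
        labels = df["responsive"].to_numpy()
        grand = Y.mean(axis=0)
        B = np.zeros((2, 2))
        W = np.zeros((2, 2))
        for lab in np.unique(labels):
            sub = Y[labels == lab]
            d = (sub.mean(axis=0) - grand)[:, None]
            B += len(sub) * d @ d.T
            W += (sub - sub.mean(axis=0)).T @ (sub - sub.mean(axis=0))
        V = np.trace(B @ np.linalg.inv(B + W))
        N, p, g = len(Y), 2, 2
        s = min(p, g - 1)
        m = (abs(p - (g - 1)) - 1) / 2
        nn = (N - g - p - 1) / 2
        F = ((2 * nn + s + 1) / (2 * m + s + 1)) * (V / s) / (1 - V / s)
        df1, df2 = s * (2 * m + s + 1), s * (2 * nn + s + 1)
        return F, float(stats.f.sf(F, df1, df2))

    def _data(self, rng, n=500, shift=0.0):
        resp = np.repeat([True, False], n)
        pos = rng.normal(1000, 100, size=2 * n) + np.where(resp, -shift * 100, 0)
        sub = rng.normal(4, 1, size=2 * n)
        return pd.DataFrame(
            {"position": pos, "subunit_count": sub, "responsive": resp}
        )

    def test_identical_groups_give_null_result(self, rng):
        df = self._data(rng, n=200, shift=0.0)
        # force identical group means exactly
        for var in ("position", "subunit_count"):
            for lab in (True, False):
                sel = df["responsive"] == lab
                df.loc[sel, var] -= df.loc[sel, var].mean()
        res = manova_arch_vs_response(df)
        assert res.overall_F == pytest.approx(0.0, abs=1e-8)
        assert res.overall_p == pytest.approx(1.0, abs=1e-6)

    def test_agrees_with_scatter_matrix_oracle(self, rng):
        df = self._data(rng, n=150, shift=0.5)
        res = manova_arch_vs_response(df)
        F, p = self._pillai_oracle(df)
        assert res.overall_F == pytest.approx(F, rel=1e-6)
        assert res.overall_p == pytest.approx(p, rel=1e-6)

    def test_power_against_three_sd_shift(self, rng):
        df = self._data(rng, n=500, shift=3.0)
        res = manova_arch_vs_response(df)
        assert res.per_variable_p["position"] < 1e-6
        assert res.overall_p < 1e-6

    def test_permutation_null_calibrated(self, rng):
        df = self._data(rng, n=100, shift=0.0)
        rejections = 0
        n_perm = 200
        for _ in range(n_perm):
            perm = df.copy()
            perm["responsive"] = rng.permutation(perm["responsive"].to_numpy())
            rejections += manova_arch_vs_response(perm).overall_p < 0.05
        assert 0.005 <= rejections / n_perm <= 0.12

    def test_constant_dependent_named_in_error(self, rng):
        df = self._data(rng, n=20)
        df["subunit_count"] = 4.0
        with pytest.raises(ValueError, match="subunit_count"):
            manova_arch_vs_response(df)


class TestAncova:
    def test_closed_form_slope_recovery(self):
        # exactly linear 6-point data: OLS must return the slope exactly
        pos = np.array([100.0, 400, 700, 1000, 1300, 1600])
        df = pd.DataFrame({"position": pos, "mfh": 1.5 - 0.002 * pos})
        res = ancova_magnitude(df, factor=None)
        assert res.covariate_coefficient == pytest.approx(-0.002, abs=1e-9)

    def test_null_factor_gives_near_zero_f(self, rng):
        # every observation appears under both levels, so the fitted
        # level contrast is exactly zero whatever the noise looks like
        n = 150
        base = pd.DataFrame(
            {
                "position": rng.uniform(0, 2000, n),
                "mfh": rng.normal(0, 1, n),
            }
        )
        df = pd.concat(
            [base.assign(level="x"), base.assign(level="y")], ignore_index=True
        )
        res = ancova_magnitude(df, factor="level")
        assert res.factor_F == pytest.approx(0.0, abs=1e-8)
        assert res.level_effects["y"] == pytest.approx(0.0, abs=1e-8)

    def test_planted_negative_position_effect_detected(self, rng):
        n = 1000
        pos = rng.uniform(0, 2000, n)
        df = pd.DataFrame(
            {
                "position": pos,
                "level": rng.choice(["a", "b"], n),
                "mfh": -0.0006 * pos + rng.normal(0, 1, n),
            }
        )
        res = ancova_magnitude(df, factor="level")
        assert res.covariate_p < 0.05
        assert res.covariate_coefficient < 0

    def test_collinear_design_rejected(self, rng):
        n = 50
        df = pd.DataFrame(
            {
                "position": np.ones(n),  # collinear with the intercept
                "mfh": rng.normal(0, 1, n),
            }
        )
        with pytest.raises(ValueError, match="collinear"):
            ancova_magnitude(df, factor=None)


class TestCorrelation:
    def test_perfect_linear(self):
        df = pd.DataFrame({"position": [1, 2, 3, 4.0], "mfh": [4, 3, 2, 1.0]})
        r, p = position_magnitude_correlation(df)
        assert r == pytest.approx(-1.0)
        df2 = pd.DataFrame({"position": [1, 2, 3.0], "mfh": [1, 2, 3.0]})
        assert position_magnitude_correlation(df2)[0] == pytest.approx(1.0)

    def test_sampling_distribution_near_planted_rho(self, rng):
        rho, n = -0.15, 300
        cov = [[1, rho], [rho, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=n)
        df = pd.DataFrame({"position": xy[:, 0], "mfh": xy[:, 1]})
        r, _ = position_magnitude_correlation(df)
        assert abs(r - rho) < 0.12

    def test_degenerate_inputs_rejected(self):
        df = pd.DataFrame({"position": [1.0, 1, 1], "mfh": [1, 2, 3.0]})
        with pytest.raises(ValueError):
            position_magnitude_correlation(df)
        with pytest.raises(ValueError):
            position_magnitude_correlation(
                pd.DataFrame({"position": [1.0, 2], "mfh": [1.0, 2]})
            )


class TestMismatchGroupKey:
    @pytest.mark.parametrize(
        "seq,label",
        [
            ("TGATGATTCGAGAAC", "G 1-4"),
            ("TGAAGATTGGAGAAC", "G 2-4"),
        ],
    )
    def test_gaa_first_labels(self, seq, label):
        (m,) = scan_sequence(seq)
        assert mismatch_group_key(m).label == label

    def test_ttc_first_label(self):
        # TTC-first varied HSE with the mismatch in subunit 2 position 3
        seq = "ATTCA" + "TGCAG" + "GTTCC"
        (m,) = scan_sequence(seq)
        assert m.first_orientation == "TTC"
        key = mismatch_group_key(m)
        assert key.label == "C 2-3"

    def test_typical_rejected(self):
        (m,) = scan_sequence("TGAAGATTCGAGAAC")
        with pytest.raises(ValueError):
            mismatch_group_key(m)


def _group_records(rng, n_per_group, groups, effects=None, slope=0.0):
    effects = effects or {}
    frames = []
    for g in ["typical"] + groups:
        pos = rng.uniform(0, 2000, n_per_group)
        mfh = rng.normal(effects.get(g, 0.0), 1.0, n_per_group) + slope * pos
        frames.append(
            pd.DataFrame(
                {"mismatch_group": g, "position": pos, "mfh": mfh,
                 "subunit_count": 3}
            )
        )
    return pd.concat(frames, ignore_index=True)


class TestMismatchPositionEffect:
    def test_planted_group_boost_recovered(self, rng):
        records = _group_records(
            rng, 200, ["C 2-3", "G 1-4", "C 1-2"], effects={"C 2-3": 0.5}
        )
        out = mismatch_position_effect(records)
        assert out["C 2-3"].p < 0.05 and out["C 2-3"].direction > 0
        assert out["G 1-4"].p > 0.05 and out["C 1-2"].p > 0.05

    def test_small_groups_skipped(self, rng):
        records = _group_records(rng, 10, ["C 2-3"])
        records = pd.concat(
            [records, _group_records(rng, 10, [])], ignore_index=True
        )
        tiny = records[records["mismatch_group"] != "C 2-3"].head(22)
        out = mismatch_position_effect(
            pd.concat([tiny, records[records["mismatch_group"] == "C 2-3"].head(2)]),
            min_group_n=3,
        )
        assert out == {}

    def test_non_three_subunit_records_excluded(self, rng):
        records = _group_records(rng, 50, ["C 2-3"], effects={"C 2-3": 5.0})
        records.loc[records["mismatch_group"] == "C 2-3", "subunit_count"] = 4
        out = mismatch_position_effect(records)
        assert out == {}  # the boosted group vanished with the restriction


class TestNucleotideComparison:
    def test_identical_groups_share_one_letter(self, rng):
        n = 60
        df = pd.DataFrame(
            {
                "observed_base": np.repeat(["A", "C", "G"], n),
                "position": rng.uniform(0, 2000, 3 * n),
                "mfh": rng.normal(0, 1, 3 * n),
            }
        )
        res = nucleotide_multiple_comparison(df)
        assert all(p > 0.05 for p in res.pairwise_p.values[np.triu_indices(3, 1)])
        assert len(set(res.letters.values())) == 1

    def test_two_groups_tukey_equals_plain_contrast(self, rng):
        """With k = 2 the studentized-range adjustment reduces to the
        unadjusted two-group linear contrast."""
        n = 40
        df = pd.DataFrame(
            {
                "observed_base": np.repeat(["A", "G"], n),
                "position": rng.uniform(0, 2000, 2 * n),
                "mfh": np.concatenate(
                    [rng.normal(0.5, 1, n), rng.normal(0, 1, n)]
                ),
            }
        )
        res = nucleotide_multiple_comparison(df)
        # oracle: t-test on the coefficient of the same linear model
        import statsmodels.api as sm

        X = sm.add_constant(
            np.column_stack(
                [(df["observed_base"] == "G").astype(float), df["position"]]
            )
        )
        fit = sm.OLS(df["mfh"], X).fit()
        assert res.pairwise_p.loc["A", "G"] == pytest.approx(
            fit.pvalues.iloc[1], rel=1e-6
        )

    def test_planted_ordering_recovered(self, rng):
        n = 100
        df = pd.DataFrame(
            {
                "observed_base": np.repeat(["A", "C", "G"], n),
                "position": rng.uniform(0, 2000, 3 * n),
                "mfh": np.concatenate(
                    [rng.normal(1.0, 1, n), rng.normal(0, 1, n),
                     rng.normal(0, 1, n)]
                ),
            }
        )
        res = nucleotide_multiple_comparison(df)
        assert res.letters["A"] != res.letters["G"]
        assert res.letters["A"] != res.letters["C"]
        assert set(res.letters["G"]) & set(res.letters["C"])

    def test_single_group_rejected(self, rng):
        df = pd.DataFrame(
            {"observed_base": ["A"] * 5, "position": range(5),
             "mfh": rng.normal(0, 1, 5)}
        )
        with pytest.raises(ValueError):
            nucleotide_multiple_comparison(df)
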