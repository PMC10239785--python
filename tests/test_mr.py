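"""Two-sample MR estimators against independent oracles and invariants."""

import numpy as np
import pandas as pd
import pytest

from alcogla import mr
from alcogla.synthetic import SummaryConfig, generate_summary_stats


def _make_set(rng, n=30, theta=0.5, intercept=0.0, noise=0.5):
    """Instrument with outcome noise = ``noise`` x the reported SE."""
    bx = rng.uniform(0.05, 0.3, n) * np.where(rng.random(n) < 0.5, -1, 1)
    sy = rng.uniform(0.01, 0.05, n)
    by = intercept * np.sign(bx) + theta * bx + noise * rng.normal(0, sy, n)
    return pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(n)],
            "beta_exposure": bx,
            "se_exposure": np.full(n, 0.005),
            "pval_exposure": np.full(n, 1e-10),
            "beta_outcome": by,
            "se_outcome": sy,
        }
    )


def _noiseless_set(n=10, theta=-1.5):
    bx = np.linspace(0.05, 0.3, n)
    return pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(n)],
            "beta_exposure": bx,
            "se_exposure": np.full(n, 0.005),
            "pval_exposure": np.full(n, 1e-10),
            "beta_outcome": theta * bx,
            "se_outcome": np.full(n, 0.03),
        }
    )


class TestHarmonize:
    def _tables(self):
        exposure = pd.DataFrame(
            {
                "snp_id": ["rs1", "rs2", "rs3"],
                "effect_allele": ["A", "C", "A"],
                "other_allele": ["G", "T", "C"],
                "beta": [0.1, -0.2, 0.15],
                "se": [0.01, 0.02, 0.01],
                "pval": [1e-9, 1e-8, 1e-7],
                "n": 1000,
            }
        )
        outcome = exposure.copy()
        outcome["beta"] = [0.3, 0.4, 0.5]
        return exposure, outcome

    def test_identical_alleles_unchanged(self):
        exposure, outcome = self._tables()
        hz = mr.harmonize(exposure, outcome)
        np.testing.assert_allclose(hz["beta_outcome"], [0.3, 0.4, 0.5])

    def test_swapped_alleles_flip_sign(self):
        exposure, outcome = self._tables()
        outcome.loc[1, ["effect_allele", "other_allele"]] = ["T", "C"]
        hz = mr.harmonize(exposure, outcome)
        assert hz.set_index("snp_id").loc["rs2", "beta_outcome"] == -0.4

    def test_palindromic_dropped(self):
        exposure, outcome = self._tables()
        exposure.loc[2, ["effect_allele", "other_allele"]] = ["A", "T"]
        outcome.loc[2, ["effect_allele", "other_allele"]] = ["A", "T"]
        hz = mr.harmonize(exposure, outcome)
        assert "rs3" not in set(hz["snp_id"])
        assert hz.attrs["n_palindromic_dropped"] == 1

    def test_row_order_invariance(self, rng):
        exposure, outcome = self._tables()
        shuffled = outcome.sample(frac=1, random_state=7).reset_index(drop=True)
        a = mr.harmonize(exposure, outcome)
        b = mr.harmonize(exposure, shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_no_overlap_rejected(self):
        exposure, outcome = self._tables()
        outcome["snp_id"] = ["x1", "x2", "x3"]
        with pytest.raises(ValueError):
            mr.harmonize(exposure, outcome)


class TestInstrument:
    def test_full_vs_restricted(self):
        sc = generate_summary_stats(SummaryConfig(n_snps=25, seed=2))
        hz = sc.harmonized()
        full = mr.build_instrument(hz, p_threshold=1.0)
        restricted = mr.build_instrument(hz, p_threshold=1.0,
                                         exclude_ids=("rs1229984",))
        assert len(full) == 25
        assert len(restricted) == 24
        assert "rs1229984" not in set(restricted["snp_id"])

    def test_threshold_one_keeps_all(self):
        sc = generate_summary_stats(SummaryConfig(n_snps=15, seed=3))
        hz = sc.harmonized()
        assert len(mr.build_instrument(hz, p_threshold=1.0)) == 15

    def test_empty_instrument_rejected(self):
        sc = generate_summary_stats(SummaryConfig(n_snps=5, seed=3))
        hz = sc.harmonized()
        with pytest.raises(ValueError):
            mr.build_instrument(hz, p_threshold=1.0,
                                exclude_ids=tuple(hz["snp_id"]))


class TestWaldRatio:
    def test_arithmetic(self):
        est, se = mr.wald_ratio(0.2, 0.01, 0.4, 0.05)
        assert est == 2.0
        assert se == pytest.approx(0.05 / 0.2)

    def test_zero_numerator(self):
        est, se = mr.wald_ratio(0.2, 0.01, 0.0, 0.05)
        assert est == 0.0
        assert se == pytest.approx(0.25)

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(ZeroDivisionError):
            mr.wald_ratio(0.0, 0.01, 0.4, 0.05)

    def test_second_order_se_matches_simulation(self, rng):
        bx, sx, by, sy = 0.5, 0.03, 1.0, 0.05  # se/beta <= 0.1
        _, se2 = mr.wald_ratio(bx, sx, by, sy, second_order=True)
        sims = (by + rng.normal(0, sy, 200_000)) / (bx + rng.normal(0, sx, 200_000))
        assert se2 == pytest.approx(sims.std(), rel=0.1)


class TestIVW:
    def test_noiseless_recovers_theta_with_zero_q(self):
        est = mr.ivw(_noiseless_set(theta=-1.5))
        assert est.estimate == pytest.approx(-1.5, abs=1e-12)
        assert est.diagnostics["Q"] == pytest.approx(0.0, abs=1e-18)

    def test_single_snp_reduces_to_wald_ratio(self):
        df = _noiseless_set(n=1)
        est = mr.ivw(df)
        wald, se = mr.wald_ratio(
            df["beta_exposure"][0], df["se_exposure"][0],
            df["beta_outcome"][0], df["se_outcome"][0],
        )
        assert est.estimate == pytest.approx(wald)
        assert est.se == pytest.approx(se)

    def test_matches_weighted_regression_oracle(self, rng):
        df = _make_set(rng)
        est = mr.ivw(df, "fixed")
        w = 1 / df["se_outcome"] ** 2
        num = (w * df["beta_exposure"] * df["beta_outcome"]).sum()
        den = (w * df["beta_exposure"] ** 2).sum()
        assert est.estimate == pytest.approx(num / den, rel=1e-12)
        assert est.se == pytest.approx(1 / np.sqrt(den), rel=1e-12)

    def test_random_effects_never_narrower_than_fixed(self, rng):
        df = _make_set(rng, noise=0.1)
        assert mr.ivw(df, "multiplicative_random").se >= mr.ivw(df, "fixed").se

    def test_unknown_variance_model(self, rng):
        with pytest.raises(ValueError):
            mr.ivw(_make_set(rng), "bayesian")


class TestEgger:
    def test_exact_affine_data_recovered(self):
        df = _noiseless_set(n=8, theta=2.0)
        df["beta_outcome"] = 0.05 + 2.0 * df["beta_exposure"]
        est = mr.egger(df)
        assert est.estimate == pytest.approx(2.0, abs=1e-10)
        assert est.diagnostics["egger_intercept"] == pytest.approx(0.05, abs=1e-10)

    def test_matches_weighted_normal_equations(self, rng):
        df = _make_set(rng)
        est = mr.egger(df)
        sign = np.sign(df["beta_exposure"])
        bx = (df["beta_exposure"] * sign).to_numpy()
        by = (df["beta_outcome"] * sign).to_numpy()
        w = (1 / df["se_outcome"] ** 2).to_numpy()
        X = np.column_stack([np.ones(len(df)), bx])
        coef = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * by))
        assert est.estimate == pytest.approx(coef[1], rel=1e-10)
        assert est.diagnostics["egger_intercept"] == pytest.approx(coef[0],
                                                                   rel=1e-10)

    def test_i2gx_in_unit_interval(self, rng):
        est = mr.egger(_make_set(rng))
        assert 0.0 <= est.diagnostics["I2GX"] <= 1.0

    def test_too_few_snps(self):
        with pytest.raises(ValueError):
            mr.egger(_noiseless_set(n=2))


class TestWeightedMedian:
    def test_equal_weights_is_plain_median(self):
        n = 7
        ratios = np.array([0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 10.0])
        df = pd.DataFrame(
            {
                "snp_id": [f"s{i}" for i in range(n)],
                "beta_exposure": np.ones(n),
                "se_exposure": np.full(n, 1e-6),
                "pval_exposure": np.zeros(n),
                "beta_outcome": ratios,
                "se_outcome": np.ones(n),
            }
        )
        est = mr.weighted_median(df, n_boot=50, seed=1)
        assert est.estimate == pytest.approx(np.median(ratios))

    def test_matches_quantile_definition_oracle(self, rng):
        df = _make_set(rng, n=15)
        est = mr.weighted_median(df, n_boot=50, seed=1)
        ratios = (df["beta_outcome"] / df["beta_exposure"]).to_numpy()
        w = (df["beta_exposure"] ** 2 / df["se_outcome"] ** 2).to_numpy()
        order = np.argsort(ratios)
        r, ww = ratios[order], w[order]
        s = (np.cumsum(ww) - ww / 2) / ww.sum()
        j = np.searchsorted(s, 0.5)
        expected = r[j - 1] + (r[j] - r[j - 1]) * (0.5 - s[j - 1]) / (s[j] - s[j - 1])
        assert est.estimate == pytest.approx(expected, rel=1e-12)

    def test_robust_to_minority_outliers(self, rng):
        """With <50% of weight on pleiotropic variants, the estimate stays
        near the true effect."""
        theta = 1.0
        df = _make_set(rng, n=21, theta=theta, noise=0.005)
        bad = rng.choice(21, size=8, replace=False)  # ~38% of equal-ish weight
        df.loc[bad, "beta_outcome"] += 0.3 * np.abs(df.loc[bad, "beta_exposure"]) * 10
        est = mr.weighted_median(df, n_boot=100, seed=2)
        assert est.estimate == pytest.approx(theta, abs=0.15)


class TestWeightedMode:
    def test_degenerate_identical_ratios(self):
        df = _noiseless_set(n=6, theta=0.7)
        for phi in (0.5, 1.0, 2.0):
            est = mr.weighted_mode(df, phi=phi, n_boot=50, seed=1)
            assert est.estimate == pytest.approx(0.7, abs=1e-9)

    def test_matches_fine_grid_search(self, rng):
        df = _make_set(rng, n=15)
        est = mr.weighted_mode(df, n_boot=50, seed=1)
        ratios = (df["beta_outcome"] / df["beta_exposure"]).to_numpy()
        w = (df["beta_exposure"] ** 2 / df["se_outcome"] ** 2).to_numpy()
        n = len(ratios)
        mad = np.median(np.abs(ratios - np.median(ratios))) / 0.6745
        h = 0.9 * min(ratios.std(ddof=1), mad) * n ** (-0.2)
        fine = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 20001)
        dens = sum(
            wi * np.exp(-0.5 * ((fine - ri) / h) ** 2) for wi, ri in zip(w, ratios)
        )
        brute = fine[np.argmax(dens)]
        grid_step = (ratios.max() - ratios.min() + 6 * h) / 511
        assert abs(est.estimate - brute) <= grid_step

    def test_majority_cluster_wins(self, rng):
        n_major, n_minor = 20, 8
        bx = rng.uniform(0.1, 0.3, n_major + n_minor)
        ratios = np.r_[rng.normal(1.0, 0.02, n_major), rng.normal(3.0, 0.02, n_minor)]
        df = pd.DataFrame(
            {
                "snp_id": [f"s{i}" for i in range(n_major + n_minor)],
                "beta_exposure": bx,
                "se_exposure": np.full(n_major + n_minor, 0.005),
                "pval_exposure": np.zeros(n_major + n_minor),
                "beta_outcome": ratios * bx,
                "se_outcome": np.full(n_major + n_minor, 0.02),
            }
        )
        est = mr.weighted_mode(df, n_boot=50, seed=3)
        pooled_mean = np.average(ratios, weights=bx**2)
        assert abs(est.estimate - 1.0) < 0.2
        assert abs(est.estimate - pooled_mean) > 0.3

    def test_bad_bandwidth_rejected(self, rng):
        with pytest.raises(ValueError):
            mr.weighted_mode(_make_set(rng), phi=0.0)


class TestPresso:
    def test_null_data_no_outliers_no_correction(self, rng):
        df = _make_set(rng, n=20, noise=0.005)
        est = mr.mr_presso(df, n_sim=300, seed=1)
        assert est.diagnostics["global_p"] > 0.2
        assert est.diagnostics["outlier_ids"] == []
        assert est.diagnostics["corrected"] is False

    def test_planted_outlier_flagged_and_corrected(self, rng):
        df = _make_set(rng, n=50, theta=1.0, noise=1.0)
        df.loc[10, "beta_outcome"] += 10 * df.loc[10, "se_outcome"]
        est = mr.mr_presso(df, n_sim=400, seed=2)
        assert "s10" in est.diagnostics["outlier_ids"]
        assert est.diagnostics["corrected"] is True
        assert est.diagnostics["global_p"] < 0.05
        assert np.isfinite(est.diagnostics["distortion_p"])
        assert est.n_snps < 50

    def test_global_p_matches_independent_simulation_loop(self, rng):
        df = _make_set(rng, n=12)
        n_sim, seed = 150, 5
        est = mr.mr_presso(df, n_sim=n_sim, seed=seed)
        # replay the simulation with an independent plain-python loop
        bx = df["beta_exposure"].to_numpy()
        by = df["beta_outcome"].to_numpy()
        sx = df["se_exposure"].to_numpy()
        sy = df["se_outcome"].to_numpy()
        w = 1 / sy**2
        n = len(df)

        def loo(bxv, byv):
            out = np.empty(n)
            for j in range(n):
                keep = np.arange(n) != j
                out[j] = np.sum(w[keep] * bxv[keep] * byv[keep]) / np.sum(
                    w[keep] * bxv[keep] ** 2
                )
            return out

        theta = loo(bx, by)
        rss_obs = np.sum(w * (by - theta * bx) ** 2)
        gen = np.random.default_rng(seed)
        bx_sim = bx[None, :] + gen.normal(0, sx, (n_sim, n))
        by_sim = theta[None, :] * bx[None, :] + gen.normal(0, sy, (n_sim, n))
        exceed = 0
        for s in range(n_sim):
            th = loo(bx_sim[s], by_sim[s])
            rss = np.sum(w * (by_sim[s] - th * bx_sim[s]) ** 2)
            exceed += rss >= rss_obs
        expected_p = (1 + exceed) / (1 + n_sim)
        assert est.diagnostics["global_p"] == pytest.approx(expected_p)

    def test_too_few_snps_or_sims(self, rng):
        with pytest.raises(ValueError):
            mr.mr_presso(_make_set(rng, n=3))
        with pytest.raises(ValueError):
            mr.mr_presso(_make_set(rng), n_sim=10)


class TestMultivariable:
    def test_matches_weighted_normal_equations(self, rng):
        df = _make_set(rng)
        df["beta_exposure2"] = rng.normal(0, 0.05, len(df))
        df["se_exposure2"] = 0.005
        est = mr.multivariable_mr(df)
        X = df[["beta_exposure", "beta_exposure2"]].to_numpy()
        w = (1 / df["se_outcome"] ** 2).to_numpy()
        coef = np.linalg.solve(X.T @ (w[:, None] * X),
                               X.T @ (w * df["beta_outcome"].to_numpy()))
        assert est.estimate == pytest.approx(coef[0], rel=1e-10)

    def test_vanishing_second_exposure_approaches_ivw(self, rng):
        df = _make_set(rng, noise=1e-4)
        df["beta_exposure2"] = 1e-8 * rng.normal(size=len(df))
        df["se_exposure2"] = 0.005
        est = mr.multivariable_mr(df)
        fixed = mr.ivw(df, "fixed")
        assert est.estimate == pytest.approx(fixed.estimate, rel=1e-3)

    def test_reduces_confounded_bias(self, rng):
        """When the second exposure directly affects the outcome, adjusting
        for its betas moves the estimate toward the truth."""
        theta, theta2 = 1.0, 2.0
        n = 40
        bx = rng.uniform(0.05, 0.3, n)
        bx2 = 0.5 * bx + rng.normal(0, 0.02, n)  # correlated pathways
        sy = np.full(n, 0.01)
        by = theta * bx + theta2 * bx2 + rng.normal(0, sy)
        df = pd.DataFrame(
            {
                "snp_id": [f"s{i}" for i in range(n)],
                "beta_exposure": bx,
                "se_exposure": np.full(n, 0.005),
                "pval_exposure": np.zeros(n),
                "beta_outcome": by,
                "se_outcome": sy,
                "beta_exposure2": bx2,
                "se_exposure2": np.full(n, 0.005),
            }
        )
        uni = mr.ivw(df, "fixed")
        multi = mr.multivariable_mr(df)
        assert abs(multi.estimate - theta) < abs(uni.estimate - theta)

    def test_collinear_exposures_rejected(self, rng):
        df = _make_set(rng)
        df["beta_exposure2"] = 2 * df["beta_exposure"]
        df["se_exposure2"] = 0.005
        with pytest.raises(ValueError):
            mr.multivariable_mr(df)


class TestInvariances:
    @pytest.mark.parametrize("method", ["ivw", "egger", "median", "mode"])
    def test_order_and_joint_sign_flip_invariance(self, rng, method):
        df = _make_set(rng, n=20)
        flipped = df.copy()
        flip = rng.random(20) < 0.5
        flipped.loc[flip, "beta_exposure"] *= -1
        flipped.loc[flip, "beta_outcome"] *= -1
        permuted = flipped.sample(frac=1, random_state=3).reset_index(drop=True)

        def run(frame):
            if method == "ivw":
                return mr.ivw(frame).estimate
            if method == "egger":
                return mr.egger(frame).estimate
            if method == "median":
                return mr.weighted_median(frame, n_boot=10, seed=0).estimate
            return mr.weighted_mode(frame, n_boot=10, seed=0).estimate

        assert run(df) == pytest.approx(run(permuted), rel=1e-9)

    def test_restricted_equals_leave_one_out(self):
        sc = generate_summary_stats(SummaryConfig(n_snps=30, seed=12))
        hz = sc.harmonized()
        restricted = mr.build_instrument(hz, 1.0, exclude_ids=("rs1229984",))
        loo = hz[hz["snp_id"] != "rs1229984"]
        assert mr.ivw(restricted).estimate == pytest.approx(
            mr.ivw(loo).estimate, rel=1e-12
        )

    def test_battery_runs_all_methods(self):
        sc = generate_summary_stats(
            SummaryConfig(n_snps=20, seed=14, second_exposure_effect=0.5)
        )
        hz = sc.harmonized()
        ests = mr.run_mr_battery(
            hz, ("ivw", "median", "mode", "egger", "presso", "mvmr"),
            seed=1, n_boot=50, n_sim=150,
        )
        assert [e.method.split("_")[0] for e in ests] == [
            "ivw", "weighted", "weighted", "egger", "mr", "multivariable"
        ]
        for e in ests:
            assert e.ci_low <= e.estimate <= e.ci_high
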