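"""GLM closed forms, likelihood oracles, AIC selection and the outlier rule."""

import subprocess
import warnings
from datetime import datetime, timedelta

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad
from scipy.special import gammaln

from ethoforage.ethogram import AttackRecord, DielBin, SamplingInterval
from ethoforage.models import (
    ModelSpec,
    aic_model_selection,
    fit_attack_rate_model,
    fit_capture_success_model,
    flag_outlier_intervals,
    intervals_to_frame,
    marginal_loglik,
    wald_interval,
)
from ethoforage.simulate import SimConfig, simulate_attack_process


def make_intervals(counts, exposure=1.0, start_hour=12):
    return [
        SamplingInterval(
            "A01", "MINWR_2010", datetime(2010, 4, 23, start_hour, 0) + timedelta(hours=i),
            exposure, c, True,
        )
        for i, c in enumerate(counts)
    ]


def make_attacks(n_success, n_fail, position="surface", hour=12):
    out = []
    for i in range(n_success + n_fail):
        out.append(
            AttackRecord(
                f"A{i % 5:02d}", "MINWR_2010",
                datetime(2010, 4, 23, hour, 0, 0) + timedelta(minutes=i),
                position, "sit_and_wait", "vegetation",
                "success" if i < n_success else "attempt_only",
            )
        )
    return out


class TestClosedForms:
    def test_null_poisson_rate_is_total_over_exposure(self):
        fit = fit_attack_rate_model(make_intervals([1, 0, 1, 2]), ModelSpec("attack_count"))
        assert fit.cell_predictions["mean"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_offset_halves_exposure_doubles_rate(self):
        fit = fit_attack_rate_model(
            make_intervals([1, 0, 1, 2], exposure=0.5), ModelSpec("attack_count")
        )
        assert fit.cell_predictions["mean"].iloc[0] == pytest.approx(2.0, abs=1e-12)

    def test_doubling_every_exposure_halves_rate_exactly(self):
        counts = [3, 1, 0, 2, 4, 1]
        r1 = fit_attack_rate_model(make_intervals(counts, 1.0), ModelSpec("attack_count"))
        with pytest.warns(UserWarning, match="non-standard exposure"):
            doubled = make_intervals(counts, 2.0)
        r2 = fit_attack_rate_model(doubled, ModelSpec("attack_count"))
        assert r2.cell_predictions["mean"].iloc[0] == pytest.approx(
            r1.cell_predictions["mean"].iloc[0] / 2.0, rel=1e-12
        )

    def test_null_binomial_probability_is_success_fraction(self):
        fit = fit_capture_success_model(make_attacks(31, 28), ModelSpec("outcome"))
        assert fit.cell_predictions["mean"].iloc[0] == pytest.approx(31 / 59, abs=1e-10)

    def test_saturated_one_factor_logit_reproduces_cell_means(self):
        attacks = make_attacks(76, 24, position="submerged") + make_attacks(41, 59, "surface")
        fit = fit_capture_success_model(attacks, ModelSpec("outcome", ("water_position",)))
        cells = fit.cell_predictions.set_index("water_position")["mean"]
        assert cells["submerged"] == pytest.approx(0.76, abs=1e-9)
        assert cells["surface"] == pytest.approx(0.41, abs=1e-9)

    def test_boundary_cell_reported_with_warning(self):
        with pytest.warns(UserWarning, match="boundary|separation"):
            fit = fit_capture_success_model(make_attacks(20, 0), ModelSpec("outcome"))
        assert fit.cell_predictions["mean"].iloc[0] == pytest.approx(1.0, abs=1e-6)
        assert fit.messages


class TestLikelihoodOracle:
    def test_poisson_llf_matches_pmf_summation(self):
        """Fitted log-likelihood equals direct pmf summation on <= 5 observations."""
        counts = [0, 1, 2]
        fit = fit_attack_rate_model(make_intervals(counts), ModelSpec("attack_count"))
        rate = fit.cell_predictions["mean"].iloc[0]
        oracle = sum(stats.poisson.logpmf(c, rate) for c in counts)
        assert fit.log_likelihood == pytest.approx(oracle, abs=1e-8)
        assert fit.aic == pytest.approx(2 * fit.k - 2 * oracle, abs=1e-8)

    def test_bernoulli_llf_matches_pmf_summation(self):
        fit = fit_capture_success_model(make_attacks(2, 3), ModelSpec("outcome"))
        p = fit.cell_predictions["mean"].iloc[0]
        oracle = sum(stats.bernoulli.logpmf(y, p) for y in [1, 1, 0, 0, 0])
        assert fit.log_likelihood == pytest.approx(oracle, abs=1e-8)

    def test_aic_identity_holds_for_every_fit(self):
        cfg = SimConfig()
        intervals, attacks = simulate_attack_process(cfg, 21)
        viable = [iv for iv in intervals if iv.viable]
        for fit in (
            fit_attack_rate_model(viable, ModelSpec("attack_count", ("diel_bin",))),
            fit_capture_success_model(attacks, ModelSpec("outcome", ("water_position",))),
        ):
            assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.log_likelihood, abs=1e-6)


class TestWaldInterval:
    def test_zero_se_logit_collapses_to_point(self):
        assert wald_interval(0.0, 0.0, "logit") == (0.5, 0.5)

    def test_log_link_example(self):
        lo, hi = wald_interval(np.log(0.49), 0.08, "log")
        assert (round(lo, 2), round(hi, 2)) == (0.42, 0.57)

    def test_ordering_and_errors(self):
        lo, hi = wald_interval(1.3, 0.2, "logit")
        assert lo < hi
        with pytest.raises(ValueError, match=">= 0"):
            wald_interval(0.0, -1.0, "log")
        with pytest.raises(ValueError, match="unknown link"):
            wald_interval(0.0, 1.0, "probit")


class TestOutlierRule:
    def test_default_threshold_flags_the_frenzy(self):
        intervals = make_intervals([0, 1, 2, 18])
        kept, flagged = flag_outlier_intervals(intervals)
        assert [iv.attack_count for iv in flagged] == [18]
        assert len(kept) == 3

    def test_nothing_flagged_below_threshold(self):
        kept, flagged = flag_outlier_intervals(make_intervals([0, 4, 10]))
        assert flagged == [] and len(kept) == 3

    def test_zero_threshold_flags_every_attack_interval(self):
        kept, flagged = flag_outlier_intervals(make_intervals([0, 1, 2]), threshold=0)
        assert len(flagged) == 2 and len(kept) == 1

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            flag_outlier_intervals([], threshold=-1)


class TestAICSelection:
    def test_intercept_only_aic_from_brute_force_likelihood(self):
        intervals = make_intervals([0, 1, 2])
        table = aic_model_selection(intervals, [ModelSpec("attack_count")])
        lnl = sum(stats.poisson.logpmf(c, 1.0) for c in [0, 1, 2])
        assert table.table["aic"].iloc[0] == pytest.approx(2 * 1 - 2 * lnl, abs=1e-8)
        assert table.table["delta"].iloc[0] == 0.0

    def test_table_sorted_with_deltas_and_tie_break(self):
        cfg = SimConfig()
        intervals, _ = simulate_attack_process(cfg, 31)
        viable = [iv for iv in intervals if iv.viable]
        table = aic_model_selection(
            viable,
            [
                ModelSpec("attack_count"),
                ModelSpec("attack_count", ("diel_bin",)),
                ModelSpec("attack_count", ("diel_bin", "site_year")),
            ],
        ).table
        aics = table["aic"].to_numpy()
        assert np.all(np.diff(aics) >= 0)
        assert table["delta"].iloc[0] == 0.0
        assert (table["delta"] >= 0).all()

    def test_failed_candidate_recorded_in_row(self):
        df = intervals_to_frame(make_intervals([0, 1, 2]))
        df = df.drop(columns=["site_year"])
        table = aic_model_selection(
            df, [ModelSpec("attack_count"), ModelSpec("attack_count", ("site_year",))]
        ).table
        failed = table[~table["converged"]]
        assert len(failed) == 1
        assert "site_year" in failed["model"].iloc[0]
        assert failed["message"].iloc[0] != ""

    def test_mixed_responses_rejected(self):
        with pytest.raises(ValueError, match="mix responses"):
            aic_model_selection([], [ModelSpec("attack_count"), ModelSpec("outcome")])

    def test_real_diel_effect_beats_null_in_most_replicates(self):
        """With strong diel rate differences the diel model wins on AIC."""
        cfg = SimConfig(
            n_individuals=5,
            half_hour_fraction=0.0,
            hours_per_deployment=96,
            viable_fraction=1.0,
            individual_sd=0.0,
        )
        wins = 0
        n_rep = 40
        for rep in range(n_rep):
            intervals, _ = simulate_attack_process(cfg, 1000 + rep)
            table = aic_model_selection(
                intervals, [ModelSpec("attack_count"), ModelSpec("attack_count", ("diel_bin",))]
            ).table
            wins += table["model"].iloc[0] == "diel_bin"
        assert wins / n_rep >= 0.95


@pytest.fixture(scope="module")
def mixed_data():
    cfg = SimConfig(individual_sd=0.5)
    intervals, _ = simulate_attack_process(cfg, 3)
    return [iv for iv in intervals if iv.viable]


@pytest.fixture(scope="module")
def mixed_fit(mixed_data):
    return fit_attack_rate_model(
        mixed_data, ModelSpec("attack_count", ("diel_bin",), random_individual=True)
    )


class TestRandomIntercept:
    def test_quadrature_matches_numerical_integration(self, mixed_data, mixed_fit):
        """GH marginal likelihood equals brute-force quad integration per group."""
        df = intervals_to_frame(mixed_data)
        y = df["attack_count"].to_numpy(float)
        offset = np.log(df["exposure_h"].to_numpy(float))
        X = np.ones((len(df), 1))
        groups, idx = np.unique(df["individual_id"], return_inverse=True)
        beta, log_sigma = np.array([-0.7]), np.log(0.4)
        gh = marginal_loglik(
            np.append(beta, log_sigma), y, X, offset, idx, len(groups), "poisson"
        )
        sigma = np.exp(log_sigma)
        oracle = 0.0
        for g in range(len(groups)):
            mask = idx == g
            yg, og = y[mask], offset[mask]

            def integrand(u, yg=yg, og=og):
                eta = beta[0] + og + u
                ll = np.sum(yg * eta - np.exp(eta) - gammaln(yg + 1))
                return np.exp(ll) * stats.norm.pdf(u, 0, sigma)

            val, _ = quad(integrand, -8 * sigma, 8 * sigma)
            oracle += np.log(val)
        assert gh == pytest.approx(oracle, abs=1e-6)

    def test_mixed_aic_identity_and_k(self, mixed_fit):
        assert mixed_fit.k == 4 + 1  # intercept + 3 bin contrasts + sigma
        assert mixed_fit.aic == pytest.approx(
            2 * mixed_fit.k - 2 * mixed_fit.log_likelihood, abs=1e-6
        )

    def test_matches_lme4_reference(self, mixed_data, mixed_fit, tmp_path):
        """Cross-implementation check against glmer (adaptive GH, 25 nodes).

        glmer reports logLik relative to the saturated Poisson model, so the
        full-likelihood value is adjusted by the saturated term before
        comparing.
        """
        df = intervals_to_frame(mixed_data)
        csv = tmp_path / "intervals.csv"
        df.to_csv(csv, index=False)
        script = f"""
suppressMessages(library(lme4))
d <- read.csv("{csv}")
m <- glmer(attack_count ~ factor(diel_bin) + (1|individual_id) + offset(log(exposure_h)),
           data=d, family=poisson, nAGQ=25)
cat(sprintf("%.8f %.8f", as.numeric(logLik(m)), fixef(m)[["(Intercept)"]]))
"""
        proc = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert proc.returncode == 0, proc.stderr
        r_llf, r_intercept = map(float, proc.stdout.split())
        y = df["attack_count"].to_numpy(float)
        yp = y[y > 0]
        saturated = float(np.sum(yp * np.log(yp) - yp - gammaln(yp + 1)))
        assert mixed_fit.log_likelihood - saturated == pytest.approx(r_llf, abs=1e-3)
        assert mixed_fit.coefficients["estimate"].iloc[0] == pytest.approx(
            r_intercept, abs=1e-3
        )


def test_cell_probability_estimators_unbiased_over_replicates():
    """Water-position cell estimates average to the generating truth (3 MC SE)."""
    cfg = SimConfig(
        success_probs_by_bin=None,
        individual_sd=0.0,
        bin_rate_multipliers={b: 1.0 for b in DielBin},
        viable_fraction=1.0,
    )
    spec = ModelSpec("outcome", ("water_position",))
    estimates = []
    for rep in range(200):
        _, attacks = simulate_attack_process(cfg, 5000 + rep)
        if not any(a.water_position == "submerged" for a in attacks):
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # boundary cells at study scale are fine
            fit = fit_capture_success_model(attacks, spec)
        cells = fit.cell_predictions.set_index("water_position")["mean"]
        estimates.append(cells["submerged"])
    estimates = np.asarray(estimates)
    se_mean = estimates.std(ddof=1) / np.sqrt(len(estimates))
    assert abs(estimates.mean() - 0.76) < 3 * se_mean + 1e-3
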