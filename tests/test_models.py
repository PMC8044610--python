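"""Bayesian fits against closed forms, grid-integration oracles and truth."""

import numpy as np
import pandas as pd
import pytest

import echosdt as es
from echosdt.models import counts_log_likelihood

SEED = 17


def make_cell_trials(task, distance, n_signal, yes_signal, n_noise, yes_noise,
                     participant="p01"):
    """Hand-build one (task, distance) cell with exact response counts."""
    if task == es.TASK_DETECTION:
        sig_stim, noise_stim = "left_reflector", "no_reflector"
        yes_resp, no_resp = "yes", "no"
    else:
        sig_stim, noise_stim = "left_reflector", "right_reflector"
        yes_resp, no_resp = "left", "right"
    rows = []
    for stim, n, k in ((sig_stim, n_signal, yes_signal), (noise_stim, n_noise, yes_noise)):
        for i in range(n):
            rows.append(
                {
                    "participant_id": participant,
                    "task": task,
                    "day": 1,
                    "session": 1,
                    "trial": len(rows) + 1,
                    "distance_m": distance,
                    "stimulus": stim,
                    "response": yes_resp if i < k else no_resp,
                }
            )
    return pd.DataFrame(rows)


def grid_posterior_moments(n1, k1, n0, k0, lim=12.0, m=801):
    """Exact (to quadrature) posterior mean/sd of (d', c) for one cell."""
    d = np.linspace(-lim, lim, m)
    c = np.linspace(-lim, lim, m)
    D, C = np.meshgrid(d, c, indexing="ij")
    logp = counts_log_likelihood(n1, k1, n0, k0, D, C) - (D**2 + C**2) / 18.0
    w = np.exp(logp - logp.max())
    w /= w.sum()
    means = ((w * D).sum(), (w * C).sum())
    sds = (
        np.sqrt((w * (D - means[0]) ** 2).sum()),
        np.sqrt((w * (C - means[1]) ** 2).sum()),
    )
    return means, sds


class TestHpdInterval:
    def test_normal_calibration(self):
        x = np.random.default_rng(SEED).standard_normal(1_000_000)
        lo, hi = es.hpd_interval(x, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.02)
        assert hi == pytest.approx(1.96, abs=0.02)

    def test_constant_samples_zero_width(self):
        lo, hi = es.hpd_interval(np.full(500, 2.5), 0.95)
        assert lo == hi == 2.5

    def test_uniform_width(self):
        x = np.random.default_rng(SEED).uniform(0, 1, 1_000_000)
        lo, hi = es.hpd_interval(x, 0.95)
        assert hi - lo == pytest.approx(0.95, abs=0.01)

    def test_order_invariant_and_asymmetric_for_skew(self):
        rng = np.random.default_rng(SEED)
        x = rng.gamma(2.0, 1.0, 50_000)
        lo, hi = es.hpd_interval(x, 0.9)
        assert (lo, hi) == es.hpd_interval(rng.permutation(x), 0.9)
        # HPD of a right-skewed sample sits left of the equal-tail interval
        assert lo < np.quantile(x, 0.05)
        # mode region is inside
        assert lo < 1.0 < hi

    def test_matches_arviz_hdi(self):
        import arviz as az

        x = np.random.default_rng(3).gamma(3.0, 2.0, 100_000)
        lo, hi = es.hpd_interval(x, 0.95)
        ref = az.hdi(x, hdi_prob=0.95)
        assert lo == pytest.approx(ref[0], abs=0.05)
        assert hi == pytest.approx(ref[1], abs=0.05)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            es.hpd_interval(np.arange(50), 0.95)  # too few draws
        with pytest.raises(ValueError):
            es.hpd_interval(np.arange(1000), 1.5)


class TestLikelihood:
    def test_cell_counts(self, small_trials):
        counts = es.cell_counts(small_trials)
        total = (counts["n_signal"] + counts["n_noise"]).sum()
        assert total == len(small_trials)
        assert set(t for t, _ in counts.index) == set(es.TASKS)

    def test_counts_likelihood_equals_trialwise_bernoulli(self, small_trials):
        """Sufficient-statistic log-likelihood == sum of per-trial
        log p_yes terms computed directly from the observation model."""
        counts = es.cell_counts(small_trials)
        s = es.signal_indicator(small_trials)
        y = es.response_indicator(small_trials)
        rng = np.random.default_rng(SEED)
        for (task, x), row in counts.iterrows():
            d, c = rng.normal(0, 1.5), rng.normal(0, 0.5)
            fast = counts_log_likelihood(
                row["n_signal"], row["yes_signal"], row["n_noise"], row["yes_noise"], d, c
            )
            in_cell = (small_trials["task"] == task) & (
                small_trials["distance_m"] == x
            )
            slow = 0.0
            params = es.SdtParams(d, c)
            for si, yi in zip(s[in_cell.to_numpy()], y[in_cell.to_numpy()]):
                p = es.p_yes(params, int(si))
                slow += np.log(p if yi else 1.0 - p)
            assert fast == pytest.approx(slow, abs=1e-9)


class TestCategoricalFit:
    def test_posterior_matches_grid_oracle(self, fast_sampler):
        trials = pd.concat(
            [
                make_cell_trials(es.TASK_DETECTION, 2.0, 150, 120, 150, 40),
                make_cell_trials(es.TASK_LOCALIZATION, 2.0, 150, 100, 150, 60),
            ],
            ignore_index=True,
        )
        fit = es.fit_categorical(trials, fast_sampler)
        (md, mc), (sd, sc) = grid_posterior_moments(150, 120, 150, 40)
        d_draws = fit.draws["d_prime[detection,2.00]"]
        c_draws = fit.draws["criterion[detection,2.00]"]
        assert d_draws.mean() == pytest.approx(md, abs=0.05)
        assert c_draws.mean() == pytest.approx(mc, abs=0.05)
        assert d_draws.std() == pytest.approx(sd, abs=0.05)
        assert c_draws.std() == pytest.approx(sc, abs=0.05)

    def test_medians_match_closed_form_at_large_n(self, fast_sampler):
        """With n = 2,000 per cell and interior rates the posterior median
        collapses onto the closed-form probit estimates."""
        cells = [
            (es.TASK_DETECTION, 1.0, 1000, 820, 1000, 310),
            (es.TASK_DETECTION, 3.0, 1000, 640, 1000, 420),
            (es.TASK_LOCALIZATION, 1.0, 1000, 700, 1000, 350),
            (es.TASK_LOCALIZATION, 3.0, 1000, 560, 1000, 460),
        ]
        trials = pd.concat(
            [make_cell_trials(*cell) for cell in cells], ignore_index=True
        )
        fit = es.fit_categorical(trials, fast_sampler)
        for task, x, n1, k1, n0, k0 in cells:
            rates = es.RatePair(k1 / n1, k0 / n0)
            assert fit.summaries.loc[f"d_prime[{task},{x:.2f}]", "median"] == pytest.approx(
                es.dprime_from_rates(rates), abs=0.1
            )
            assert fit.summaries.loc[f"criterion[{task},{x:.2f}]", "median"] == pytest.approx(
                es.criterion_from_rates(rates), abs=0.1
            )

    def test_prior_dominates_single_trial_cell(self, fast_sampler):
        """One yes-on-signal trial per cell: the posterior stays close to
        the Normal(0, 3) prior (checked against exact grid integration —
        the single trial still tilts d' up by about one unit)."""
        trials = pd.concat(
            [
                make_cell_trials(es.TASK_DETECTION, 2.0, 1, 1, 0, 0),
                make_cell_trials(es.TASK_LOCALIZATION, 2.0, 1, 1, 0, 0),
            ],
            ignore_index=True,
        )
        fit = es.fit_categorical(trials, fast_sampler)
        (md, mc), (sd, sc) = grid_posterior_moments(1, 1, 0, 0)
        d = fit.draws["d_prime[detection,2.00]"]
        c = fit.draws["criterion[detection,2.00]"]
        assert d.mean() == pytest.approx(md, abs=0.2)
        assert c.mean() == pytest.approx(mc, abs=0.2)
        assert d.std() == pytest.approx(sd, abs=0.2)
        assert 2.5 < d.std() < 3.3  # prior sd is 3

    def test_boundary_cell_stays_finite(self, fast_sampler):
        """An all-yes cell (H = 1) breaks the closed form but the Bayesian
        posterior is proper, just wide."""
        trials = pd.concat(
            [
                make_cell_trials(es.TASK_DETECTION, 1.0, 60, 60, 60, 0),
                make_cell_trials(es.TASK_LOCALIZATION, 1.0, 60, 40, 60, 20),
            ],
            ignore_index=True,
        )
        with pytest.raises(es.BoundaryRateError):
            es.dprime_from_rates(es.RatePair(1.0, 0.0))
        fit = es.fit_categorical(trials, fast_sampler)
        row = fit.summaries.loc["d_prime[detection,1.00]"]
        assert np.isfinite(row["median"])
        assert row["median"] > 3.0
        assert row["hpd_high"] - row["hpd_low"] > 1.0

    def test_requires_both_tasks_and_complete_cells(self, fast_sampler):
        only_det = make_cell_trials(es.TASK_DETECTION, 2.0, 20, 10, 20, 10)
        with pytest.raises(ValueError, match="both tasks"):
            es.fit_categorical(only_det, fast_sampler)
        uneven = pd.concat(
            [
                make_cell_trials(es.TASK_DETECTION, 1.0, 10, 5, 10, 5),
                make_cell_trials(es.TASK_DETECTION, 2.0, 10, 5, 10, 5),
                make_cell_trials(es.TASK_LOCALIZATION, 1.0, 10, 5, 10, 5),
            ],
            ignore_index=True,
        )
        with pytest.raises(ValueError, match=r"empty cell.*2\.00"):
            es.fit_categorical(uneven, fast_sampler)

    def test_rejects_multiple_participants(self, fast_sampler):
        a = make_cell_trials(es.TASK_DETECTION, 2.0, 5, 3, 5, 2, participant="a")
        b = make_cell_trials(es.TASK_DETECTION, 2.0, 5, 3, 5, 2, participant="b")
        with pytest.raises(ValueError, match="one participant"):
            es.fit_categorical(pd.concat([a, b]), fast_sampler)


class TestExponentialFit:
    def test_flat_truth_rate_covers_zero(self, fast_sampler):
        """If d' does not change with distance the posterior for the decay
        rate must concentrate near 0."""
        design = es.make_design(distances_m=(1.0, 2.5, 4.0), days=2,
                                sessions_per_day=5, reps_per_distance_per_session=25)
        obs = es.ObserverParams.exponential(1.5, 0.0, 1.5, 0.0, 0.0, 0.0)
        trials = es.analysis_subset(
            es.simulate_experiment(design, obs, ["p01"], seed=23), design
        )
        fit = es.fit_exponential(trials, fast_sampler)
        row = fit.summaries.loc["alpha1"]
        assert row["hpd_low"] < 0.0 < row["hpd_high"]
        assert abs(row["median"]) < 0.3

    def test_cross_model_consistency(self, small_trials, fast_sampler):
        """When the truth is exponential, the exponential fit's predicted
        d' curve and the categorical per-cell posteriors must agree within
        their joint uncertainty at every design distance."""
        fc = es.fit_categorical(small_trials, fast_sampler)
        fe = es.fit_exponential(small_trials, fast_sampler)
        a0, a1 = fe.draws["alpha0"], fe.draws["alpha1"]
        for x in fc.sampler_meta["distances"]:
            pred = a0 * np.exp(a1 * x)
            plo, phi = es.hpd_interval(pred, 0.95)
            cat = fc.summaries.loc[f"d_prime[detection,{x:.2f}]"]
            # intervals overlap
            assert max(plo, cat["hpd_low"]) <= min(phi, cat["hpd_high"])

    def test_recovers_generator_truth(self, small_trials, fast_sampler):
        fit = es.fit_exponential(small_trials, fast_sampler)
        truth = {"alpha0": 3.0, "alpha1": -0.4, "beta0": 2.0, "beta1": -0.6,
                 "c0": 0.1, "c1": -0.2}
        for name, val in truth.items():
            med = fit.summaries.loc[name, "median"]
            lo, hi = fit.summaries.loc[name, "hpd_low"], fit.summaries.loc[name, "hpd_high"]
            width = hi - lo
            assert abs(med - val) < width, f"{name}: median {med} far from {val}"


@pytest.fixture(scope="module")
def contrast_fits(fast_sampler):
    # 150 trials per cell at three distances; detection truth above
    # localization truth, gap shrinking with distance
    design = es.make_design(distances_m=(1.0, 2.44, 4.25))
    obs = es.ObserverParams.exponential(3.0, -0.4, 2.0, -0.6, -0.2, 0.3)
    trials = es.analysis_subset(
        es.simulate_experiment(design, obs, ["p05"], seed=31), design
    )
    fc = es.fit_categorical(trials, fast_sampler)
    fe = es.fit_exponential(trials, fast_sampler)
    return fc, fe


class TestContrastsAndBias:
    def test_contrast_sign_pattern(self, contrast_fits):
        fc, _ = contrast_fits
        table = es.task_contrasts(fc)
        assert list(table["distance_m"]) == [1.0, 2.44, 4.25]
        assert table["median"].iloc[0] > 0.0
        assert table["median"].iloc[0] > table["median"].iloc[-1]
        assert (table["hpd_low"] <= table["median"]).all()
        assert (table["median"] <= table["hpd_high"]).all()

    def test_contrast_is_drawwise(self, contrast_fits):
        fc, _ = contrast_fits
        table = es.task_contrasts(fc)
        x = 1.0
        diff = (
            fc.draws["d_prime[detection,1.00]"] - fc.draws["d_prime[localization,1.00]"]
        )
        row = table[table["distance_m"] == x].iloc[0]
        assert row["median"] == pytest.approx(float(np.median(diff)), abs=1e-12)

    def test_identical_tasks_contrast_covers_zero(self, fast_sampler):
        design = es.make_design(distances_m=(1.0, 2.44, 4.25))
        obs = es.ObserverParams.exponential(2.0, -0.4, 2.0, -0.4, 0.0, 0.0)
        trials = es.analysis_subset(
            es.simulate_experiment(design, obs, ["p01"], seed=41), design
        )
        fit = es.fit_categorical(trials, fast_sampler)
        table = es.task_contrasts(fit)
        covers = ((table["hpd_low"] <= 0) & (0 <= table["hpd_high"])).sum()
        assert covers >= len(table) - 1  # 95% intervals; allow one miss

    def test_bias_recovery_and_model_agreement(self, contrast_fits):
        """Truth c0 = -0.2, c1 = 0.3: the between-task difference is -0.5
        in both models, and the two models' per-task biases agree."""
        fc, fe = contrast_fits
        table = es.bias_table(fc, fe)
        m2 = table[(table["model"] == "exponential") & (table["quantity"] == "c_difference")].iloc[0]
        assert m2["hpd_low"] <= -0.5 <= m2["hpd_high"]
        assert m2["median"] == pytest.approx(-0.5, abs=0.15)
        for task in es.TASKS:
            m1 = table[(table["model"] == "categorical") & (table["quantity"] == f"c_{task}")].iloc[0]
            m2t = table[(table["model"] == "exponential") & (table["quantity"] == f"c_{task}")].iloc[0]
            assert m1["median"] == pytest.approx(m2t["median"], abs=0.15)

    def test_type_errors(self, contrast_fits, fast_sampler):
        fc, fe = contrast_fits
        with pytest.raises(ValueError, match="categorical"):
            es.task_contrasts(fe)
        with pytest.raises(ValueError, match="categorical fit, exponential fit"):
            es.bias_table(fe, fc)
        other = pd.concat(
            [
                make_cell_trials(es.TASK_DETECTION, 2.0, 30, 20, 30, 10, participant="zz"),
                make_cell_trials(es.TASK_LOCALIZATION, 2.0, 30, 20, 30, 10, participant="zz"),
            ],
            ignore_index=True,
        )
        fe_other = es.fit_exponential(other, fast_sampler)
        with pytest.raises(ValueError, match="mismatch"):
            es.bias_table(fc, fe_other)


def test_fit_is_deterministic_given_seed(fast_sampler):
    trials = pd.concat(
        [
            make_cell_trials(es.TASK_DETECTION, 2.0, 40, 30, 40, 10),
            make_cell_trials(es.TASK_LOCALIZATION, 2.0, 40, 25, 40, 15),
        ],
        ignore_index=True,
    )
    a = es.fit_exponential(trials, fast_sampler)
    b = es.fit_exponential(trials, fast_sampler)
    pd.testing.assert_frame_equal(a.summaries, b.summaries)
    np.testing.assert_array_equal(a.draws["alpha0"], b.draws["alpha0"])
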