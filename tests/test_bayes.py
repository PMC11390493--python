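import numpy as np
import pandas as pd
import pytest

from cpet_entropy.bayes import (
    DegenerateDenominatorError,
    PosteriorDraws,
    PriorSpec,
    convergence_report,
    delta_vt1,
    fit_hierarchical,
    percent_diff_hr_vs_mingas,
    percent_diff_puberty,
    percent_diff_sex,
    prior_nu_mass,
    split_rhat,
)
from cpet_entropy.synthetic import simulate_entropy_observations


def _cells_vt1(mus):
    out = []
    for (sex, side), mu in mus.items():
        out.append(
            ({"metric": "vo2", "pubertal": "early", "sex": sex, "side": side}, mu, 0.2)
        )
    return out


@pytest.fixture(scope="module")
def recovery_fit():
    """Seeded 4-cell Student-t recovery fixture (truth μ 1.8/2.0/2.2/2.4)."""
    truth = {
        ("male", "before"): 1.8,
        ("male", "after"): 2.0,
        ("female", "before"): 2.2,
        ("female", "after"): 2.4,
    }
    y = simulate_entropy_observations(_cells_vt1(truth), nu=5, n_per_cell=40, seed=7)
    post = fit_hierarchical(y, chains=4, draws_per_chain=500, warmup=500, seed=11)
    return truth, post


class TestPriorNuMass:
    def test_mass_in_0_25_is_about_99_percent(self):
        assert prior_nu_mass(0, 25) == pytest.approx(0.99, abs=0.005)

    def test_total_mass_and_median(self):
        assert prior_nu_mass(0, np.inf) == pytest.approx(1.0)
        assert prior_nu_mass(0, np.e) == pytest.approx(0.5)

    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            prior_nu_mass(3, 3)


class TestFit:
    def test_parameter_recovery(self, recovery_fit):
        truth, post = recovery_fit
        mu_mean = post.mu_flat().mean(axis=0)
        for cell, m in zip(post.cells, mu_mean):
            metric, pub, sex, side = cell
            assert m == pytest.approx(truth[(sex, side)], abs=0.10)

    def test_sigma_inside_prior_support_nu_positive(self, recovery_fit):
        _, post = recovery_fit
        assert post.sigma.min() > post.priors.sigma_low
        assert post.sigma.max() < post.priors.sigma_high
        assert post.nu.min() > 0

    def test_total_draw_count(self, recovery_fit):
        _, post = recovery_fit
        assert post.n_draws == 4 * 500

    def test_convergence_diagnostics_pass(self, recovery_fit):
        _, post = recovery_fit
        report, ok = convergence_report(post)
        assert ok and post.converged
        assert report.r_hat.max() <= 1.01
        assert report.ess.min() >= 400

    def test_determinism_same_seed(self):
        y = simulate_entropy_observations(
            _cells_vt1({("male", "before"): 2.0, ("male", "after"): 1.8}),
            nu=5, n_per_cell=10, seed=1,
        )
        kw = dict(chains=2, draws_per_chain=100, warmup=150, seed=5)
        a = fit_hierarchical(y, **kw)
        b = fit_hierarchical(y, **kw)
        assert np.array_equal(a.mu, b.mu)
        assert np.array_equal(a.sigma, b.sigma)
        assert np.array_equal(a.nu, b.nu)

    def test_empty_cell_error_names_cell(self):
        y = simulate_entropy_observations(
            _cells_vt1({("male", "before"): 2.0, ("male", "after"): 1.8,
                        ("female", "before"): 2.1}),
            nu=5, n_per_cell=10, seed=1,
        )
        with pytest.raises(ValueError, match="female"):
            fit_hierarchical(y)

    def test_mcmc_means_match_independent_ensemble_sampler(self, recovery_fit):
        """Cross-check NUTS against emcee run on the same log posterior."""
        emcee = pytest.importorskip("emcee")
        truth, post = recovery_fit
        from cpet_entropy.bayes import _log_posterior_factory

        y = simulate_entropy_observations(_cells_vt1(truth), nu=5, n_per_cell=40, seed=7)
        factors = ["metric", "pubertal", "sex", "side"]
        cells = post.cells
        pos = {c: i for i, c in enumerate(cells)}
        idx = np.array([pos[t] for t in zip(*(y[f] for f in factors))])
        logp_grad = _log_posterior_factory(
            y["sampen"].to_numpy(), idx, len(cells), post.priors
        )
        ndim = 2 * len(cells) + 1
        rng = np.random.default_rng(0)
        p0 = np.concatenate([post.mu_flat().mean(axis=0), np.zeros(len(cells)), [np.log(5)]])
        walkers = p0 + 0.05 * rng.standard_normal((8 * ndim, ndim))
        sampler = emcee.EnsembleSampler(8 * ndim, ndim, lambda th: logp_grad(th)[0])
        np.random.seed(2)  # emcee draws from the global numpy state
        sampler.run_mcmc(walkers, 2000, progress=False)
        chain = sampler.get_chain(discard=1000, flat=True)
        mu_ref = chain[:, : len(cells)].mean(axis=0)
        np.testing.assert_allclose(post.mu_flat().mean(axis=0), mu_ref, atol=0.03)


class TestConvergenceReport:
    def _dummy(self, mu):
        chains, draws, cells = mu.shape
        return PosteriorDraws(
            cells=[("vo2", "early", "male", "before")] * cells,
            factors=("metric", "pubertal", "sex", "side"),
            mu=mu,
            sigma=np.full_like(mu, 0.2),
            nu=np.full(mu.shape[:2], 5.0),
            priors=PriorSpec(),
            variant="vt1",
            divergences=0,
            converged=True,
            seed=0,
        )

    def test_disjoint_constant_chains_fail(self):
        mu = np.stack([np.zeros((100, 1)), np.ones((100, 1))])
        report, ok = convergence_report(self._dummy(mu))
        assert not ok
        assert report.loc[report.parameter.str.startswith("mu"), "r_hat"].iloc[0] > 1.01

    def test_single_chain_errors(self):
        mu = np.zeros((1, 100, 1))
        with pytest.raises(ValueError):
            convergence_report(self._dummy(mu))

    def test_split_rhat_near_one_for_iid(self):
        rng = np.random.default_rng(4)
        assert split_rhat(rng.standard_normal((4, 500))) == pytest.approx(1.0, abs=0.02)


def _manual_draws(mu_by_cell, variant="vt1"):
    """PosteriorDraws with hand-set μ draws (σ, ν filler)."""
    cells = list(mu_by_cell)
    draws = np.stack([np.asarray(mu_by_cell[c], dtype=float) for c in cells], axis=-1)
    mu = draws[None, :, :]  # one chain
    factors = ("metric", "pubertal", "sex", "side") if variant == "vt1" else (
        "metric", "pubertal", "sex")
    return PosteriorDraws(
        cells=cells,
        factors=factors,
        mu=mu,
        sigma=np.full_like(mu, 0.2),
        nu=np.full(mu.shape[:2], 5.0),
        priors=PriorSpec(),
        variant=variant,
        divergences=0,
        converged=True,
        seed=0,
    )


class TestContrasts:
    def test_delta_vt1_hand_counts(self):
        post = _manual_draws({
            ("vo2", "early", "male", "before"): [0.0, 0.0, 0.0, 0.0],
            ("vo2", "early", "male", "after"): [-0.2, 0.1, 0.3, 0.4],
        })
        c = delta_vt1(post, "vo2", "male", "early")
        assert c.prob_geq_zero == pytest.approx(0.75)
        np.testing.assert_allclose(c.draws, [-0.2, 0.1, 0.3, 0.4])

    def test_delta_vt1_all_negative_gives_zero_probability(self):
        post = _manual_draws({
            ("hr", "early", "male", "before"): [2.0, 2.1, 2.2],
            ("hr", "early", "male", "after"): [0.4, 0.5, 0.6],
        })
        assert delta_vt1(post, "hr", "male", "early").prob_geq_zero == 0.0

    def test_delta_vt1_split_draws(self):
        post = _manual_draws({
            ("rr", "late", "female", "before"): [0.0, 0.0, 0.0, 0.0],
            ("rr", "late", "female", "after"): [-1.0, -1.0, 1.0, 1.0],
        })
        assert delta_vt1(post, "rr", "female", "late").prob_geq_zero == 0.5

    def test_missing_cell_raises(self):
        post = _manual_draws({("vo2", "early", "male", "before"): [1.0]})
        with pytest.raises(KeyError):
            delta_vt1(post, "vo2", "male", "early")

    def test_percent_diff_sex_hand_value(self):
        post = _manual_draws({
            ("hr", "early", "male", "before"): [1.8],
            ("hr", "early", "female", "before"): [2.0],
        })
        c = percent_diff_sex(post, "hr", "early", "before")
        assert c.draws[0] == pytest.approx(-10.0)

    def test_percent_diff_sex_identical_cells(self):
        post = _manual_draws({
            ("hr", "early", "male", "before"): [2.0, 2.1],
            ("hr", "early", "female", "before"): [2.0, 2.1],
        })
        c = percent_diff_sex(post, "hr", "early", "before")
        assert c.point == 0.0 and c.prob_geq_zero == 1.0

    def test_percent_diff_sex_degenerate_denominator(self):
        post = _manual_draws({
            ("hr", "early", "male", "before"): [1.8, 1.8],
            ("hr", "early", "female", "before"): [1e-9, 2.0],
        })
        with pytest.raises(DegenerateDenominatorError):
            percent_diff_sex(post, "hr", "early", "before")

    def test_percent_diff_puberty_hand_value_and_contract(self):
        post = _manual_draws(
            {("hr", "early", "female"): [2.0], ("hr", "late", "female"): [1.7]},
            variant="whole",
        )
        c = percent_diff_puberty(post, "hr", "female")
        assert c.draws[0] == pytest.approx((1.7 - 2.0) / 1.7 * 100)
        vt1_post = _manual_draws({("hr", "early", "female", "before"): [2.0]})
        with pytest.raises(ValueError, match="whole"):
            percent_diff_puberty(vt1_post, "hr", "female")

    def test_hr_vs_mingas_hand_value(self):
        post = _manual_draws({
            ("hr", "early", "male", "before"): [0.5],
            ("vo2", "early", "male", "before"): [2.0],
            ("vco2", "early", "male", "before"): [2.5],
        })
        c = percent_diff_hr_vs_mingas(post, "male", "early", "before")
        assert c.draws[0] == pytest.approx(-75.0)

    def test_hr_vs_mingas_min_is_per_draw(self):
        post = _manual_draws({
            ("hr", "early", "male", "before"): [1.0, 1.0],
            ("vo2", "early", "male", "before"): [2.0, 4.0],
            ("vco2", "early", "male", "before"): [4.0, 2.0],
        })
        c = percent_diff_hr_vs_mingas(post, "male", "early", "before")
        np.testing.assert_allclose(c.draws, [-50.0, -50.0])

    def test_prob_geq_plus_prob_less_is_one(self):
        rng = np.random.default_rng(8)
        draws = rng.standard_normal(500)
        post = _manual_draws({
            ("vo2", "early", "male", "before"): np.zeros(500),
            ("vo2", "early", "male", "after"): draws,
        })
        c = delta_vt1(post, "vo2", "male", "early")
        assert c.prob_geq_zero + np.mean(c.draws < 0) == pytest.approx(1.0)
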