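"""Model/Results layer: posterior summaries, diagnostics, and fitting behaviour."""

import warnings

import numpy as np
import pandas as pd
import pytest

import discardcast as dc
from discardcast import (
    DiscardModel,
    ReducedDiscardModel,
    check_convergence,
    summarize_posterior,
)


class TestSummarizePosterior:
    def test_constant_draws_collapse_interval(self):
        out = summarize_posterior(np.full((200, 3), 7.0))
        assert (out["median"] == 7.0).all()
        assert (out["lo"] == 7.0).all() and (out["hi"] == 7.0).all()

    def test_known_quantiles_of_1_to_100(self):
        draws = np.arange(1.0, 101.0)[:, None]
        out = summarize_posterior(draws)
        assert out["median"].iloc[0] == pytest.approx(50.5)
        assert out["lo"].iloc[0] == pytest.approx(np.quantile(np.arange(1.0, 101.0), 0.025))
        assert out["hi"].iloc[0] == pytest.approx(np.quantile(np.arange(1.0, 101.0), 0.975))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        draws = rng.normal(size=(500, 2))
        out1 = summarize_posterior(draws)
        out2 = summarize_posterior(draws[rng.permutation(500)])
        pd.testing.assert_frame_equal(out1, out2)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            summarize_posterior(np.zeros((50, 2)))

    def test_ordering_invariant(self):
        rng = np.random.default_rng(3)
        out = summarize_posterior(rng.lognormal(size=(400, 5)))
        assert (out["lo"] <= out["median"]).all()
        assert (out["median"] <= out["hi"]).all()


class TestCheckConvergence:
    def test_identical_chains_rhat_near_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=1000)
        report = check_convergence({"theta": np.stack([x, x])})
        assert report["rhat"].iloc[0] == pytest.approx(1.0, abs=0.02)
        assert bool(report["pass"].iloc[0])

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 1000)
        b = rng.normal(50, 1, 1000)
        report = check_convergence({"theta": np.stack([a, b])})
        assert report["rhat"].iloc[0] > 1.05
        assert not bool(report["pass"].iloc[0])

    def test_ess_bounded_by_total_draws(self):
        rng = np.random.default_rng(3)
        draws = rng.normal(size=(2, 500, 3))
        report = check_convergence({"theta": draws})
        assert (report["ess"] <= 2 * 500).all()

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            check_convergence({"theta": np.zeros((1, 100))})


class TestFullModel:
    def test_requires_discards(self, scenario):
        obs = [o.without_discards() for _, o in scenario["reference"]]
        with pytest.raises(ValueError):
            DiscardModel(obs, scenario["mls"])

    def test_posterior_shapes_and_ordering(self, quick_fit):
        d = quick_fit.draws("D")
        assert d.shape[1:] == (5, 34)
        s = quick_fit.series_summary("D")
        assert (s["lo"] <= s["median"]).all() and (s["median"] <= s["hi"]).all()

    def test_summary_table_contains_structural_params(self, quick_fit):
        idx = quick_fit.summary().index
        assert "sl50_star" in idx and "h" in idx and "rl50[cod]" in idx

    def test_posterior_predictive_landings_bracket_observations(self, full_fit, scenario):
        s = full_fit.series_summary("L")
        frac = []
        for truth, obs in scenario["reference"]:
            sel = s[s["species"] == truth.species]
            inside = ((obs.landings >= sel["lo"].to_numpy())
                      & (obs.landings <= sel["hi"].to_numpy()))
            frac.append(inside.mean())
        assert np.mean(frac) >= 0.8

    def test_zero_noise_limit_recovers_discards(self):
        # tiny observation noise: posterior median D within 2% of truth.
        # The saturated state-space cannot learn the noise scale from one
        # realisation, so the known scale enters through the precision prior.
        sig = 0.005
        sc = dc.reference_scenario(n_reference=3, n_other=0, n_years=12, seed=5,
                                   sigma_index=sig, sigma_landings=sig,
                                   sigma_discards=sig)
        priors = dc.full_model_priors(precision_gamma=(2.0, 2.0 * sig ** 2))
        model = DiscardModel.from_scenario(sc, priors=priors)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(draws=1500, warmup=1500, chains=2, seed=2)
        for k, (truth, _) in enumerate(sc["reference"]):
            med = np.median(res.draws("D")[:, k, :], axis=0)
            assert np.max(np.abs(med / truth.discards - 1)) < 0.02

    def test_determinism_given_seed(self, scenario):
        model = DiscardModel.from_scenario(scenario)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = model.fit(draws=120, warmup=100, chains=1, seed=9)
            b = model.fit(draws=120, warmup=100, chains=1, seed=9)
        assert np.array_equal(a.draws("D"), b.draws("D"))


class TestReducedModel:
    def test_requires_reference_fit(self, scenario):
        _, obs = scenario["other"][0]
        with pytest.raises(ValueError):
            ReducedDiscardModel(obs, None, 25.0, 0.874)

    def test_matching_q_path_gets_maximal_weight(self, scenario, full_fit):
        # a landings-only copy of a reference species should weight its own
        # Q series highest (cross-validation structure, single species)
        truth, obs = scenario["reference"][4]
        reduced = ReducedDiscardModel(
            obs.without_discards(), full_fit.reference_logq(),
            scenario["mls"][truth.species], full_fit.h, value_class="high",
            reference_species=full_fit.species)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = reduced.fit(draws=800, warmup=800, chains=2, seed=3)
        assert int(np.argmax(res.weights_mean)) == 4

    def test_prior_dominance_for_high_value_q(self, full_fit, scenario):
        # data generated with q from the informative prior leave the
        # posterior mean near the prior mean (~0.104)
        sc = dc.reference_scenario(n_reference=5, n_other=1, n_years=34, seed=21,
                                   q_beta=(1.4, 12.0))
        truth, obs = sc["other"][0]
        reduced = ReducedDiscardModel(obs, full_fit.reference_logq(),
                                      sc["mls"][truth.species], full_fit.h,
                                      value_class="high")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = reduced.fit(draws=600, warmup=600, chains=2, seed=4)
        prior_mean = 1.4 / (1.4 + 12.0)
        assert abs(res.draws("q").mean() - prior_mean) < 0.05

    def test_all_index_missing_completes_with_flags(self, full_fit, scenario):
        truth, obs = scenario["other"][0]
        blind = dc.FisheryObservations(
            obs.species, obs.years, np.full(obs.years.size, np.nan),
            obs.landings, None, obs.composition)
        reduced = ReducedDiscardModel(blind, full_fit.reference_logq(),
                                      scenario["mls"][truth.species], full_fit.h,
                                      value_class="high")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = reduced.fit(draws=200, warmup=200, chains=2, seed=5)
        assert res.flags["all_index_missing"]
        assert res.flags["index_missing_years"] == obs.years.size
        # pinned q: every draw equals the prior mean in every year
        prior_mean = 1.4 / (1.4 + 12.0)
        assert np.allclose(res.draws("q"), prior_mean)

    def test_information_ordering_discard_intervals_widen(self, full_fit, scenario):
        # withholding the discard series must widen the D intervals
        truth, obs = scenario["reference"][1]
        k = 1
        full_d = full_fit.draws("D")[:, k, :]
        full_width = np.quantile(full_d, 0.975, 0) - np.quantile(full_d, 0.025, 0)
        reduced = ReducedDiscardModel(
            obs.without_discards(), full_fit.reference_logq(),
            scenario["mls"][truth.species], full_fit.h, value_class="high",
            reference_species=full_fit.species)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = reduced.fit(draws=800, warmup=800, chains=2, seed=6)
        red_d = res.draws("D")
        red_width = np.quantile(red_d, 0.975, 0) - np.quantile(red_d, 0.025, 0)
        assert np.median(red_width / full_width) > 1.0
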