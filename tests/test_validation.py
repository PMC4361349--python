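"""Validation procedures: q-from-age, logit-mean comparison, sensitivity,
assemblage aggregation and variance explained."""

import numpy as np
import pandas as pd
import pytest

from discardcast import (
    LengthWeightParams,
    SelectivityOgive,
    aggregate_assemblage,
    compare_p,
    predicted_discards,
    q_from_age,
    sensitivity,
    variance_explained,
)

LW = LengthWeightParams(0.01, 3.0)


class TestQFromAge:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["year", "age", "n_landed_thousands",
                                           "w_landed_kg", "n_discarded_thousands",
                                           "w_discarded_kg"])

    def test_worked_example(self):
        # MLS 30 -> threshold 0.01*31^3 = 297.9 g; only the 500 g age counts
        rec = self._frame([(2000, 1, 0, 0.2, 0, 0.2),
                           (2000, 2, 900, 0.5, 100, 0.5)])
        q = q_from_age(rec, mls=30.0, lw=LW, increment=1.0)
        assert q[2000] == pytest.approx(0.1)

    def test_zero_discards_above_threshold(self):
        rec = self._frame([(2000, 2, 900, 0.5, 0, 0.0)])
        assert q_from_age(rec, 30.0, LW)[2000] == pytest.approx(0.0)

    def test_everything_discarded_gives_one(self):
        rec = self._frame([(2000, 2, 0, 0.0, 100, 0.5)])
        assert q_from_age(rec, 30.0, LW)[2000] == pytest.approx(1.0)

    def test_no_supra_threshold_class_is_missing(self):
        rec = self._frame([(2000, 1, 900, 0.1, 100, 0.1)])
        assert np.isnan(q_from_age(rec, 30.0, LW)[2000])

    def test_values_bounded(self):
        rng = np.random.default_rng(8)
        rows = [(yr, age, rng.integers(0, 1000), rng.uniform(0.05, 2.0),
                 rng.integers(0, 1000), rng.uniform(0.05, 2.0))
                for yr in range(2000, 2010) for age in range(1, 6)]
        q = q_from_age(self._frame(rows), 30.0, LW)
        ok = q.dropna()
        assert ((ok >= 0) & (ok <= 1)).all()


class TestCompareP:
    def test_logit_mean_cases(self):
        frags = pd.DataFrame({"species": ["a", "a", "b", "b", "c"],
                              "p_observed": [0.5, 0.5, 0.1, 0.9, 0.3]})
        out = compare_p({"a": 0.4, "b": 0.6, "c": 0.25}, frags).set_index("species")
        assert out.loc["a", "observed_logit_mean"] == pytest.approx(0.5)
        assert out.loc["b", "observed_logit_mean"] == pytest.approx(0.5)
        assert out.loc["c", "observed_logit_mean"] == pytest.approx(0.3)

    def test_p_equal_one_excluded(self):
        frags = pd.DataFrame({"species": ["a", "a"], "p_observed": [0.5, 1.0]})
        out = compare_p({"a": 0.4}, frags)
        assert out["n_fragments"].iloc[0] == 1

    def test_species_without_fragments_omitted(self):
        frags = pd.DataFrame({"species": ["a"], "p_observed": [0.5]})
        out = compare_p({"a": 0.4, "zzz": 0.2}, frags)
        assert list(out["species"]) == ["a"]


class TestSensitivity:
    @staticmethod
    def _forward_fit(config):
        """Deterministic stand-in fit: forward-model discards under a config."""
        rng = np.random.default_rng(config["seed"])
        lengths = np.arange(5.0, 61.0)
        pi = np.exp(-0.5 * ((lengths - config["mean_length"]) / config["sd_length"]) ** 2)
        pi /= pi.sum()
        cap = SelectivityOgive(config["sl50"], 6)
        ret = SelectivityOgive(config["rl50"], 6)
        d = predicted_discards(300.0, 20.0, cap, ret, pi, lengths, 0.1)
        return np.full((10, 1), d) + 0.0 * rng.random()

    def _config(self, **kw):
        base = {"seed": 0, "sl50": 15.0, "rl50": 23.0, "mean_length": 25.0,
                "sd_length": 7.0}
        base.update(kw)
        return base

    def test_zero_delta_zero_change(self):
        out = sensitivity(self._forward_fit, self._config(), "rl50", 0.0)
        assert out["percent_change"] == 0.0

    def test_rl50_increase_never_decreases_discards(self):
        out = sensitivity(self._forward_fit, self._config(), "rl50", 0.10)
        assert out["percent_change"] >= 0.0

    def test_narrow_length_range_more_sensitive(self):
        narrow = sensitivity(self._forward_fit,
                             self._config(mean_length=24.0, sd_length=2.0),
                             "rl50", 0.10)
        wide = sensitivity(self._forward_fit,
                           self._config(mean_length=24.0, sd_length=12.0),
                           "rl50", 0.10)
        assert narrow["percent_change"] > wide["percent_change"]

    def test_unknown_parameter_rejected(self):
        with pytest.raises(KeyError):
            sensitivity(self._forward_fit, self._config(), "nope", 0.1)


class TestAggregateAssemblage:
    def test_draw_constant_totals(self):
        draws = {"a": {"C": np.full((200, 3), 100.0), "D": np.full((200, 3), 60.0)},
                 "b": {"C": np.full((200, 3), 50.0), "D": np.full((200, 3), 40.0)}}
        out = aggregate_assemblage(draws)
        assert np.allclose(out["total_D"]["median"], 100.0)
        assert np.allclose(out["total_D"]["lo"], out["total_D"]["hi"])
        assert np.allclose(out["overall_p"]["median"], 100.0 / 150.0)

    def test_drawwise_totals_match_naive_script(self):
        rng = np.random.default_rng(4)
        draws = {s: {"C": rng.lognormal(4, 0.3, (300, 5)),
                     "D": None, "q": rng.uniform(0, 0.3, (300, 5))}
                 for s in ("a", "b", "c")}
        for s in draws:
            draws[s]["D"] = draws[s]["C"] * rng.uniform(0.3, 0.9, (300, 5))
        out = aggregate_assemblage(draws)
        naive_p = np.empty((300, 5))
        for i in range(300):
            tot_c = sum(draws[s]["C"][i] for s in draws)
            tot_d = sum(draws[s]["D"][i] for s in draws)
            naive_p[i] = tot_d / tot_c
        assert np.allclose(out["_draws"]["overall_p"], naive_p, atol=1e-10)
        # intervals are quantiles of the summed draws
        assert np.allclose(out["overall_p"]["median"],
                           np.quantile(naive_p, 0.5, axis=0))

    def test_quantity_size_split_sums_to_discards(self):
        rng = np.random.default_rng(5)
        draws = {}
        for s in ("a", "b"):
            C = rng.lognormal(4, 0.2, (200, 4))
            q = rng.uniform(0, 0.2, (200, 4))
            D = C * (q + rng.uniform(0, 0.5, (200, 4)) * (1 - q))
            draws[s] = {"C": C, "D": D, "q": q}
        out = aggregate_assemblage(draws)
        total = out["quantity_component"]["mean"] + out["size_component"]["mean"]
        assert np.allclose(total, out["total_D"]["mean"], rtol=1e-10)

    def test_group_shares_partition_to_one(self):
        rng = np.random.default_rng(6)
        draws = {s: {"C": rng.lognormal(4, 0.2, (150, 3)),
                     "D": rng.lognormal(3, 0.2, (150, 3))}
                 for s in ("a", "b", "c")}
        out = aggregate_assemblage(draws, groups={"a": "reference", "b": "non-TAC",
                                                  "c": "non-TAC"})
        shares = out["group_discard_shares"]
        total = shares["reference"]["mean"] + shares["non-TAC"]["mean"]
        assert np.allclose(total, 1.0, atol=1e-10)


class TestVarianceExplained:
    def test_perfect_fit(self):
        assert variance_explained([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_hand_computed_toy(self):
        model = [1.0, 2.0, 3.0]
        obs = [1.1, 1.9, 3.2]
        ss_tot = np.sum((np.array(obs) - np.mean(obs)) ** 2)
        expected = 1 - 0.06 / ss_tot
        assert variance_explained(model, obs) == pytest.approx(expected, abs=1e-10)

    def test_bad_constant_model_can_go_negative(self):
        assert variance_explained([10.0, 10.0, 10.0], [1.0, 2.0, 3.0]) < 0

    def test_zero_observed_variance_flagged(self):
        with pytest.raises(ValueError):
            variance_explained([1, 2, 3], [5, 5, 5])

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            variance_explained([1, np.nan, 3], [1, 2, 3])
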