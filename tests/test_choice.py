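"""Tests of the weighted conditional logit, Halton draws, mixed logit by maximum
simulated likelihood, attribute screening, and the likelihood-ratio test."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from outletchoice.choice import (
    HaltonConfig,
    drop_collinear,
    fit_conditional_logit,
    fit_mixed_logit,
    halton_draws,
    halton_sequence,
    lr_test,
    screen_attributes,
    simulated_choice_probabilities,
)
from outletchoice.errors import DataError, IdentificationError
from outletchoice.synthetic import CHOICE_ATTRIBUTES

from conftest import make_choice_sets

ATTRS = list(CHOICE_ATTRIBUTES)
RANDOM_ATTRS = ["distance_km", "n_methods", "is_public"]


def small_instance(seed=0, n=5, n_alt=3):
    """Random 5-chooser x 3-alternative instance with two attributes and weights."""
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n):
        z = rng.normal(size=(n_alt, 2))
        chosen = rng.integers(n_alt)
        frames.append(pd.DataFrame({
            "respondent_id": f"R{i:05d}",
            "outlet_id": [f"O{m}" for m in range(n_alt)],
            "distance_km": np.abs(z[:, 0]),
            "n_methods": np.round(3 + z[:, 1]),
            "chosen": (np.arange(n_alt) == chosen).astype(int),
        }))
    cs = pd.concat(frames, ignore_index=True)
    w = pd.DataFrame({"respondent_id": [f"R{i:05d}" for i in range(n)],
                      "weight": rng.uniform(0.5, 2.0, n)})
    return cs, w


def brute_force_loglik(cs, attributes, beta, weights=None):
    """Explicit per-chooser enumeration of the conditional-logit likelihood."""
    total = 0.0
    for rid, grp in cs.groupby("respondent_id"):
        util = grp[attributes].to_numpy() @ np.asarray(beta)
        p = np.exp(util) / np.exp(util).sum()
        w = 1.0 if weights is None else float(
            weights.set_index("respondent_id").loc[rid, "weight"]
        )
        total += w * np.log(p[grp.chosen.to_numpy() == 1][0])
    return total


class TestConditionalLogit:
    def test_loglik_matches_brute_force(self):
        cs, w = small_instance()
        fit = fit_conditional_logit(cs, ["distance_km", "n_methods"], w)
        assert fit.loglik == pytest.approx(
            brute_force_loglik(cs, ["distance_km", "n_methods"], fit.params.to_numpy(), w),
            abs=1e-10,
        )

    def test_matches_statsmodels_oracle(self, choice_study):
        from statsmodels.discrete.conditional_models import ConditionalLogit

        _, cs = choice_study
        attrs = ["distance_km", "n_methods", "is_public"]
        fit = fit_conditional_logit(cs, attrs, None)
        codes, _ = pd.factorize(cs.respondent_id)
        res = ConditionalLogit(cs.chosen.to_numpy(), cs[attrs].to_numpy(), groups=codes).fit(disp=False)
        # statsmodels stops at a looser gradient tolerance; 1e-4 is far below SEs
        assert fit.params.to_numpy() == pytest.approx(res.params, abs=1e-4)
        assert fit.loglik == pytest.approx(res.llf, abs=1e-4)

    def test_balanced_choices_give_zero_coefficient(self):
        # half choose near, half choose far; same distance contrast everywhere
        chosen = np.array([0, 1] * 50)
        cs = make_choice_sets({"distance_km": [0.5, 1.5]}, chosen)
        fit = fit_conditional_logit(cs, ["distance_km"])
        assert abs(fit.params.iloc[0]) < 1e-6

    def test_recovery_of_known_coefficient(self):
        rng = np.random.default_rng(4)
        n = 4000
        z = rng.integers(0, 2, size=(n, 3)).astype(float)
        util = z * 1.0 + rng.gumbel(size=(n, 3))
        chosen = util.argmax(axis=1)
        rows = []
        for i in range(n):
            for m in range(3):
                rows.append({"respondent_id": f"R{i:05d}", "outlet_id": f"O{m}",
                             "open7": z[i, m], "chosen": int(m == chosen[i])})
        fit = fit_conditional_logit(pd.DataFrame(rows), ["open7"])
        assert abs(fit.params["open7"] - 1.0) <= 3 * fit.bse["open7"]

    def test_within_set_constant_attribute_rejected(self):
        cs = make_choice_sets({"distance_km": [1.0, 1.0]}, np.zeros(20, dtype=int))
        with pytest.raises(IdentificationError, match="distance_km"):
            fit_conditional_logit(cs, ["distance_km"])

    def test_probabilities_shift_invariant(self, choice_study):
        # adding an alternative-constant shift within each set leaves the fit alone
        _, cs = choice_study
        attrs = ["distance_km", "n_methods"]
        base = fit_conditional_logit(cs, attrs)
        shifted = cs.copy()
        per_resp = shifted.groupby("respondent_id")["distance_km"].transform("mean")
        shifted["distance_km"] = shifted["distance_km"] - per_resp
        fit = fit_conditional_logit(shifted, attrs)
        assert fit.params.to_numpy() == pytest.approx(base.params.to_numpy(), abs=1e-6)
        assert fit.loglik == pytest.approx(base.loglik, abs=1e-6)


class TestScreening:
    def test_noise_attribute_usually_dropped(self, choice_study):
        # an irrelevant attribute's Wald p-value is ~Uniform(0,1), so backward
        # elimination at p_drop=0.3 drops it with probability ~0.7
        study, cs = choice_study
        rng = np.random.default_rng(17)
        dropped = 0
        n_reps = 60
        for rep in range(n_reps):
            noisy = cs.copy()
            noisy["noise"] = rng.normal(size=len(noisy))
            retained, _ = screen_attributes(
                noisy, ["distance_km", "n_methods", "is_public", "noise"], p_drop=0.3
            )
            dropped += int("noise" not in retained)
            assert "distance_km" in retained  # protected
        assert dropped / n_reps >= 0.55

    def test_strong_attributes_all_retained(self, choice_study):
        _, cs = choice_study
        retained, log = screen_attributes(cs, ["distance_km", "is_public"], p_drop=0.3)
        assert retained == ["distance_km", "is_public"]
        assert (log.action == "retain").sum() == 2

    def test_collinear_attribute_removed_prefit(self, choice_study):
        _, cs = choice_study
        noisy = cs.copy()
        noisy["twice_distance"] = 2.0 * noisy["distance_km"]
        retained, log = screen_attributes(
            noisy, ["distance_km", "twice_distance", "is_public"], p_drop=0.3
        )
        assert "twice_distance" not in retained
        assert (log.action == "drop_collinear").any()
        kept, dropped = drop_collinear(noisy, ["distance_km", "twice_distance"])
        assert kept == ["distance_km"] and dropped == ["twice_distance"]


class TestHalton:
    def test_base_two_sequence(self):
        assert halton_sequence(0, 3) == pytest.approx([0.5, 0.25, 0.75])

    def test_burn_discards_initial_points(self):
        assert halton_sequence(0, 2, burn=1) == pytest.approx([0.25, 0.75])

    def test_mapped_draws_standard_normal(self):
        draws = halton_draws(HaltonConfig(n_draws=1000, seed=0), 1, 1)
        assert abs(draws.mean()) < 0.05
        assert abs(draws.std() - 1.0) < 0.05

    def test_deterministic_given_config(self):
        cfg = HaltonConfig(n_draws=50, burn=5, seed=3)
        a = halton_draws(cfg, 10, 4)
        b = halton_draws(cfg, 10, 4)
        assert np.array_equal(a, b)
        assert a.shape == (10, 50, 4)

    def test_many_dimensions_supported(self):
        draws = halton_draws(HaltonConfig(n_draws=10, seed=0), 3, 12)
        assert draws.shape == (3, 10, 12)
        assert np.isfinite(draws).all()


class TestMixedLogit:
    def test_empty_random_set_equals_conditional_logit(self, choice_study):
        _, cs = choice_study
        attrs = ["distance_km", "n_methods", "is_public"]
        clog = fit_conditional_logit(cs, attrs)
        mixl = fit_mixed_logit(cs, attrs, [], halton=HaltonConfig(n_draws=5, seed=0))
        assert mixl.params.to_numpy() == pytest.approx(clog.params.to_numpy(), abs=1e-6)
        assert mixl.loglik == pytest.approx(clog.loglik, abs=1e-6)

    def test_objective_at_zero_sd_equals_clogit_objective(self):
        from outletchoice.choice import _ChoiceData, _msl_objective, clogit_loglik

        cs, w = small_instance(seed=2)
        attrs = ["distance_km", "n_methods"]
        data = _ChoiceData(cs, attrs, w)
        beta = np.array([-0.5, 0.3])
        eta = halton_draws(HaltonConfig(n_draws=20, seed=0), data.n_groups, 1)
        f, _ = _msl_objective(np.concatenate([beta, [0.0]]), data, np.array([0]), eta)
        assert -f == pytest.approx(clogit_loglik(beta, data), abs=1e-10)

    def test_simulated_probabilities_sum_to_one(self, choice_study):
        _, cs = choice_study
        attrs = ["distance_km", "n_methods", "is_public"]
        mixl = fit_mixed_logit(
            cs, attrs, ["distance_km"], halton=HaltonConfig(n_draws=50, seed=1)
        )
        probs = simulated_choice_probabilities(mixl, cs)
        sums = probs.groupby("respondent_id")["prob"].sum()
        assert np.allclose(sums, 1.0, atol=1e-8)

    def test_doubling_draws_is_stable(self, choice_study):
        _, cs = choice_study
        attrs = ["distance_km", "n_methods", "is_public"]
        f1 = fit_mixed_logit(cs, attrs, RANDOM_ATTRS, halton=HaltonConfig(n_draws=100, seed=2))
        f2 = fit_mixed_logit(cs, attrs, RANDOM_ATTRS, halton=HaltonConfig(n_draws=200, seed=2))
        diff = np.abs(f1.params.to_numpy() - f2.params.to_numpy())
        assert (diff < f1.bse[attrs].to_numpy()).all()

    def test_low_draw_count_warns(self):
        cs, w = small_instance(seed=3, n=30)
        with pytest.warns(UserWarning, match="draws"):
            fit_mixed_logit(cs, ["distance_km"], ["distance_km"], w,
                            halton=HaltonConfig(n_draws=10, seed=0))

    def test_random_attrs_must_be_subset(self):
        cs, _ = small_instance()
        with pytest.raises(DataError):
            fit_mixed_logit(cs, ["distance_km"], ["is_public"])


class TestLRTest:
    def _fits(self, ll_clog, ll_mix, n_random=3):
        cs, w = small_instance(seed=5, n=20)
        attrs = ["distance_km", "n_methods"]
        clog = fit_conditional_logit(cs, attrs, w)
        mixl = fit_mixed_logit(cs, attrs, attrs[:n_random],
                               halton=HaltonConfig(n_draws=30, seed=0), weights=w)
        clog.loglik, mixl.loglik = ll_clog, ll_mix
        mixl.random_attributes = [f"a{i}" for i in range(n_random)]
        return clog, mixl

    def test_chi_square_oracle(self):
        clog, mixl = self._fits(-100.0, -95.0, n_random=3)
        stat, df, p = lr_test(clog, mixl)
        assert stat == pytest.approx(10.0)
        assert df == 3
        assert p == pytest.approx(stats.chi2.sf(10.0, 3), abs=1e-12)
        assert p == pytest.approx(0.0186, abs=5e-4)

    def test_equal_likelihoods(self):
        clog, mixl = self._fits(-100.0, -100.0, n_random=2)
        stat, _, p = lr_test(clog, mixl)
        assert stat == 0.0 and p == 1.0

    def test_statistic_floored_at_zero(self):
        clog, mixl = self._fits(-100.0, -100.5, n_random=2)
        stat, _, p = lr_test(clog, mixl)
        assert stat == 0.0 and p == 1.0

    def test_non_nested_rejected(self):
        clog, mixl = self._fits(-100.0, -95.0)
        mixl.attributes = ["distance_km"]
        with pytest.raises(DataError):
            lr_test(clog, mixl)
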