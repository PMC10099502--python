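"""Tests of the synthetic study generator: determinism, geometric containment,
degenerate distributions, and agreement of simulated frequencies with the
closed-form choice probabilities they are drawn from."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from outletchoice.errors import ConfigurationError, DataError
from outletchoice.synthetic import (
    CHOICE_ATTRIBUTES,
    AttributeModel,
    CovariateModel,
    SiteConfig,
    default_truth,
    generate_outlets,
    generate_respondents,
    generate_study,
    kenya_like,
    selection_probabilities,
    simulate_outlet_choice,
    simulate_selection,
    uganda_like,
)

from conftest import make_choice_sets


def site(n_resp=100, **kw):
    base = dict(
        site_id="t",
        n_outlets_by_type={"public": 10, "private": 20, "pharmacy": 15},
        outer_ring_radius=5.0,
        inner_ring_radius=2.0,
        choice_radius=3.0,
        n_respondents=n_resp,
    )
    base.update(kw)
    return SiteConfig(**base)


@pytest.fixture(scope="module")
def attrs():
    return kenya_like().attributes


class TestOutlets:
    def test_counts_and_containment(self, attrs):
        out = generate_outlets(site(), attrs, seed=1)
        assert len(out) == 45
        assert (np.hypot(out.x_km, out.y_km) <= 5.0).all()
        assert out.outlet_type.value_counts().to_dict() == {
            "pharmacy": 15, "private": 20, "public": 10
        }

    def test_deterministic_given_seed(self, attrs):
        a = generate_outlets(site(), attrs, seed=42)
        b = generate_outlets(site(), attrs, seed=42)
        pd.testing.assert_frame_equal(a, b)
        c = generate_outlets(site(), attrs, seed=43)
        assert not a.equals(c)

    def test_degenerate_prevalence(self, attrs):
        model = attrs.by_type["public"]
        forced = dataclasses.replace(model, prevalence={**model.prevalence, "fp_signage": 1.0})
        am = AttributeModel(by_type={**attrs.by_type, "public": forced})
        out = generate_outlets(site(), am, seed=3)
        assert (out.loc[out.outlet_type == "public", "fp_signage"] == 1).all()

    def test_empty_supply_is_an_error(self, attrs):
        cfg = site(n_outlets_by_type={"public": 0, "private": 0, "pharmacy": 0})
        with pytest.raises(DataError, match="empty supply"):
            generate_outlets(cfg, attrs, seed=1)

    def test_attribute_domains(self, attrs):
        out = generate_outlets(site(), attrs, seed=5)
        assert out.n_methods.between(1, 12).all()
        assert (out.price_ocp >= 0).all() and (out.price_injection >= 0).all()


class TestRespondents:
    def test_containment_and_count(self):
        r = generate_respondents(site(n_resp=200), CovariateModel(), seed=1)
        assert len(r) == 200
        assert (np.hypot(r.x_km, r.y_km) <= 2.0).all()

    def test_degenerate_parity(self):
        cm = CovariateModel(parity_probs=(1.0, 0.0, 0.0, 0.0))
        r = generate_respondents(site(), cm, seed=2)
        assert (r.parity == 0).all()

    def test_deterministic(self):
        a = generate_respondents(site(), CovariateModel(), seed=9)
        b = generate_respondents(site(), CovariateModel(), seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_covariate_spec(self):
        with pytest.raises(ConfigurationError):
            CovariateModel(parity_probs=(0.5, 0.2, 0.2, 0.2))
        with pytest.raises(ConfigurationError):
            CovariateModel(married_prob=1.5)


class TestSelection:
    def test_zero_coefficients_give_uniform_sixths(self):
        truth = default_truth()
        coefs = truth.selection_coefs * 0.0
        truth = dataclasses.replace(truth, selection_coefs=coefs)
        r = generate_respondents(site(n_resp=60_000), CovariateModel(), seed=4)
        cats = simulate_selection(r, truth, seed=4)
        shares = cats.value_counts(normalize=True)
        se = np.sqrt((1 / 6) * (5 / 6) / 60_000)
        assert np.allclose(shares.sort_index(), 1 / 6, atol=3 * se)

    def test_married_effect_matches_closed_form(self):
        truth = default_truth()
        coefs = truth.selection_coefs * 0.0
        coefs.loc[6, "married"] = 2.0
        truth = dataclasses.replace(truth, selection_coefs=coefs)
        r = generate_respondents(site(n_resp=20_000), CovariateModel(), seed=5)
        cats = simulate_selection(r, truth, seed=5)
        married = r.married == 1
        share_m = (cats[married] == 6).mean()
        share_u = (cats[~married] == 6).mean()
        assert share_m > share_u
        # closed-form oracle: p6 = e^2/(5+e^2) for married, 1/6 for unmarried
        p_m = np.exp(2.0) / (5 + np.exp(2.0))
        se_m = np.sqrt(p_m * (1 - p_m) / married.sum())
        assert abs(share_m - p_m) < 3 * se_m
        probs = selection_probabilities(r, coefs)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_dimension_mismatch_raises(self):
        truth = default_truth()
        coefs = truth.selection_coefs.rename(columns={"married": "nonexistent"})
        truth = dataclasses.replace(truth, selection_coefs=coefs)
        r = generate_respondents(site(n_resp=10), CovariateModel(), seed=1)
        with pytest.raises(DataError, match="nonexistent"):
            simulate_selection(r, truth, seed=1)

    def test_single_respondent_reproducible(self):
        truth = default_truth()
        r = generate_respondents(site(n_resp=1), CovariateModel(), seed=8)
        a = simulate_selection(r, truth, seed=8)
        b = simulate_selection(r, truth, seed=8)
        assert a.iloc[0] == b.iloc[0]


class TestOutletChoice:
    def _respondents(self, n):
        return pd.DataFrame({"respondent_id": [f"R{i:05d}" for i in range(n)]})

    def test_binary_logit_oracle(self):
        # two outlets identical except distance 0.5 vs 1.5, weight -1, no mixing:
        # closer outlet chosen with probability e/(1+e) ~ 0.731
        n = 50_000
        cs = make_choice_sets({"distance_km": [0.5, 1.5]}, np.zeros(n, dtype=int))
        truth = dataclasses.replace(
            default_truth(), beta_mean={"distance_km": -1.0}, beta_sd={}
        )
        chosen, draws, empty = simulate_outlet_choice(self._respondents(n), cs, truth, seed=3)
        assert not empty
        p = np.exp(1.0) / (1.0 + np.exp(1.0))
        share = (chosen == "O000").mean()
        assert abs(share - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_identical_alternatives_uniform(self):
        n = 30_000
        cs = make_choice_sets({"distance_km": [1.0, 1.0, 1.0]}, np.zeros(n, dtype=int))
        truth = dataclasses.replace(default_truth(), beta_mean={"distance_km": -2.0}, beta_sd={})
        chosen, _, _ = simulate_outlet_choice(self._respondents(n), cs, truth, seed=6)
        shares = chosen.value_counts(normalize=True)
        se = np.sqrt((1 / 3) * (2 / 3) / n)
        assert np.allclose(shares, 1 / 3, atol=3 * se)

    def test_matches_conditional_logit_probabilities(self):
        # with beta_sd = 0 the simulated frequencies follow the closed-form
        # softmax over each choice set
        n = 30_000
        z = {"distance_km": [0.2, 1.0, 2.5], "is_public": [0.0, 1.0, 0.0]}
        cs = make_choice_sets(z, np.zeros(n, dtype=int))
        truth = dataclasses.replace(
            default_truth(), beta_mean={"distance_km": -1.0, "is_public": 1.5}, beta_sd={}
        )
        chosen, _, _ = simulate_outlet_choice(self._respondents(n), cs, truth, seed=9)
        util = -1.0 * np.array(z["distance_km"]) + 1.5 * np.array(z["is_public"])
        p = np.exp(util) / np.exp(util).sum()
        shares = chosen.value_counts(normalize=True).reindex([f"O{m:03d}" for m in range(3)])
        for m in range(3):
            se = np.sqrt(p[m] * (1 - p[m]) / n)
            assert abs(shares.iloc[m] - p[m]) < 3 * se

    def test_empty_choice_set_reported(self):
        cs = make_choice_sets({"distance_km": [0.5, 1.5]}, np.zeros(2, dtype=int))
        resp = self._respondents(3)  # R00002 has no rows in cs
        truth = dataclasses.replace(
            default_truth(), beta_mean={"distance_km": -1.0}, beta_sd={}
        )
        chosen, _, empty = simulate_outlet_choice(resp, cs, truth, seed=1)
        assert empty == ["R00002"]
        assert "R00002" not in chosen.index


class TestStudy:
    def test_invariants(self, small_study):
        st = small_study
        assert st.respondents.category.isin(range(1, 7)).all()
        linked = st.respondents.dropna(subset=["chosen_outlet_id"])
        assert linked.chosen_outlet_id.isin(st.outlets.outlet_id).all()
        assert set(linked.respondent_id) == set(
            st.respondents.loc[st.respondents.category.isin((5, 6)), "respondent_id"]
        )
        by_resp = st.choice_sets.groupby("respondent_id")["chosen"].sum()
        assert (by_resp == 1).all()

    def test_end_to_end_determinism(self):
        a = generate_study(kenya_like(n_respondents=150, seed=3), seed=3)
        b = generate_study(kenya_like(n_respondents=150, seed=3), seed=3)
        pd.testing.assert_frame_equal(a.respondents, b.respondents)
        pd.testing.assert_frame_equal(a.outlets, b.outlets)
        pd.testing.assert_frame_equal(a.choice_sets, b.choice_sets)

    def test_uganda_preset_shape(self):
        st = generate_study(uganda_like(n_respondents=100, seed=2), seed=2)
        assert st.outlets.outlet_type.value_counts()["private"] > 20
        assert (st.choice_sets.loc[st.choice_sets.out_of_radius == 0, "distance_km"] <= 2.0).all()
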