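"""Rating, consistency and moderation models on generated data."""

import numpy as np
import pandas as pd
import pytest

import facepref as fp
from facepref.models import (
    SOI_MODERATORS,
    fit_choice_moderation_model,
)


def _config(**kw):
    defaults = dict(n_countries=12, participants_per_country=25, seed=21,
                    soi_missing_rate=0.0)
    defaults.update(kw)
    return fp.GeneratorConfig(**defaults)


class TestDifferenceScores:
    def test_basic_arithmetic(self):
        ratings = pd.DataFrame(
            {
                "participant_id": [1, 1, 2, 2, 3, 3, 4, 4],
                "judgement": "attractiveness",
                "cue_set": "E",
                "level": ["high", "low"] * 4,
                "rating": [5, 3, 4, 4, 1, 7, 7, 1],
            }
        )
        out = fp.difference_scores(ratings).set_index("participant_id")["diff"]
        assert out[1] == 2
        assert out[2] == 0
        assert out[3] == -6  # floor of the range
        assert out[4] == 6

    def test_participant_missing_one_level_omitted(self):
        ratings = pd.DataFrame(
            {
                "participant_id": [1, 1, 2],
                "judgement": "attractiveness",
                "cue_set": "E",
                "level": ["high", "low", "high"],
                "rating": [5, 3, 6],
            }
        )
        out = fp.difference_scores(ratings)
        assert out["participant_id"].tolist() == [1]

    def test_antisymmetric_under_label_swap(self, small_dataset):
        ratings = small_dataset["ratings"]
        swapped = ratings.copy()
        swapped["level"] = swapped["level"].map(
            {"low": "high", "high": "low", "medium": "medium"}
        )
        d1 = fp.difference_scores(ratings).set_index(
            ["participant_id", "judgement", "cue_set"]
        )["diff"]
        d2 = fp.difference_scores(swapped).set_index(
            ["participant_id", "judgement", "cue_set"]
        )["diff"]
        pd.testing.assert_series_equal(d1, -d2)


class TestRatingModel:
    def test_noiseless_limit_recovers_exact_effect(self):
        cfg = _config(
            rating_effect=2.0,
            rating_sd_participant=0.0,
            rating_sd_country=0.0,
            rating_sd_residual=0.0,
            delta_sd_participant=0.0,
            delta_sd_country=0.0,
        )
        ds = fp.generate_dataset(cfg)
        fit = fp.fit_rating_model(ds["ratings"], ds["participants"],
                                  "attractiveness", "P")
        assert fit.term("level (high-low)")["estimate"] == pytest.approx(2.0, abs=1e-6)

    def test_null_effect_within_two_ses(self):
        cfg = _config(rating_effect=0.0, participants_per_country=70, seed=31)
        ds = fp.generate_dataset(cfg)
        fit = fp.fit_rating_model(ds["ratings"], ds["participants"],
                                  "femininity", "E")
        row = fit.term("level (high-low)")
        assert abs(row["estimate"]) <= 2 * row["se"]

    def test_identical_ratings_degenerate_error(self):
        cfg = _config(
            rating_effect=0.0, rating_sd_participant=0.0, rating_sd_country=0.0,
            rating_sd_residual=0.0,
        )
        ds = fp.generate_dataset(cfg)
        with pytest.raises(ValueError, match="degenerate"):
            fp.fit_rating_model(ds["ratings"], ds["participants"],
                                "attractiveness", "E")

    def test_consistency_of_estimator_as_n_grows(self):
        # the level-coefficient spread must shrink and stay near truth
        ses, errors = [], []
        for n_per, seed in ((17, 1), (67, 2), (267, 3)):
            cfg = _config(participants_per_country=n_per, seed=seed,
                          rating_effect=0.5)
            ds = fp.generate_dataset(cfg)
            fit = fp.fit_rating_model(ds["ratings"], ds["participants"],
                                      "attractiveness", "textbook")
            row = fit.term("level (high-low)")
            ses.append(row["se"])
            errors.append(abs(row["estimate"] - 0.5))
            assert errors[-1] <= 3 * row["se"]
        assert ses[2] < ses[0]


class TestConsistencyModel:
    def test_shared_latent_taste_yields_positive_coefficient(self):
        cfg = _config(
            participants_per_country=84,  # ~1000 raters
            seed=41,
            delta0=0.0,
            delta_sd_participant=1.0,
            rating_effect=0.0,
            rating_slope_sd_participant=1.0,
            task_coupling=1.0,
        )
        ds = fp.generate_dataset(cfg)
        diffs = fp.difference_scores(ds["ratings"])
        fit = fp.fit_consistency_model(diffs, ds["choices"], ds["participants"],
                                       "attractiveness", "E")
        row = fit.term("choice_score")
        assert row["estimate"] > 0
        assert row["p"] < 0.05

    def test_independent_tasks_near_zero(self):
        cfg = _config(participants_per_country=84, seed=43,
                      delta_sd_participant=1.0)
        ds = fp.generate_dataset(cfg)
        diffs = fp.difference_scores(ds["ratings"])
        fit = fp.fit_consistency_model(diffs, ds["choices"], ds["participants"],
                                       "femininity", "P")
        row = fit.term("choice_score")
        assert abs(row["estimate"]) <= 2 * row["se"]

    def test_all_zero_diffs_flagged_degenerate(self):
        cfg = _config(
            rating_effect=0.0, rating_sd_participant=0.0, rating_sd_country=0.0,
            rating_sd_residual=0.0,
        )
        ds = fp.generate_dataset(cfg)
        diffs = fp.difference_scores(ds["ratings"])
        fit = fp.fit_consistency_model(diffs, ds["choices"], ds["participants"],
                                       "attractiveness", "E")
        assert fit.term("choice_score")["estimate"] == 0.0
        assert not fit.converged
        assert any("degenerate" in n for n in fit.notes)

    def test_no_overlap_raises(self, small_dataset):
        diffs = fp.difference_scores(small_dataset["ratings"])
        diffs = diffs.assign(participant_id=diffs["participant_id"] + 10_000)
        with pytest.raises(ValueError, match="overlap"):
            fp.fit_consistency_model(
                diffs, small_dataset["choices"], small_dataset["participants"]
            )


class TestChoiceModeration:
    def test_null_moderator_within_two_ses(self):
        cfg = _config(participants_per_country=60, seed=51)
        ds = fp.generate_dataset(cfg)
        for link in ("adjacent", "cumulative"):
            fit = fit_choice_moderation_model(
                ds["choices"], ds["participants"],
                ("age", "self_health"), "attractiveness", "E", link=link,
            )
            row = fit.term("self_health_z")
            assert abs(row["estimate"]) <= 2 * row["se"]

    def test_planted_slope_recovered_by_matched_link(self):
        cfg = _config(
            participants_per_country=80, seed=53,
            delta0=0.0, delta_sd_participant=0.0, delta_sd_country=0.0,
            moderator_slopes={"self_attractiveness": 0.4},
        )
        ds = fp.generate_dataset(cfg)
        fit = fit_choice_moderation_model(
            ds["choices"], ds["participants"],
            ("age", "sex", "self_attractiveness"), "attractiveness", "textbook",
            link="adjacent",
        )
        row = fit.term("self_attractiveness_z")
        assert row["ci_low"] <= 0.4 <= row["ci_high"]

    def test_soi_battery_uses_only_nonmissing_soi(self):
        cfg = _config(soi_missing_rate=0.3, seed=55)
        ds = fp.generate_dataset(cfg)
        fit = fit_choice_moderation_model(
            ds["choices"], ds["participants"], SOI_MODERATORS,
            "attractiveness", "E",
        )
        n_complete = ds["participants"]["soi_score"].notna().sum()
        assert fit.n_obs == n_complete
        assert fit.n_obs < len(ds["participants"])


class TestRatingModeration:
    def test_null_interaction_within_two_ses(self):
        cfg = _config(participants_per_country=60, seed=61)
        ds = fp.generate_dataset(cfg)
        fit = fp.fit_rating_moderation_model(
            ds["ratings"], ds["participants"], ("age", "self_health"),
            "attractiveness", "E",
        )
        for term in fit.headline_terms:
            row = fit.term(term)
            assert abs(row["estimate"]) <= 2.5 * row["se"]

    def test_constant_moderator_flagged_non_estimable(self):
        cfg = _config(seed=63)
        ds = fp.generate_dataset(cfg)
        participants = ds["participants"].copy()
        participants["self_health"] = 4.0
        fit = fp.fit_rating_moderation_model(
            ds["ratings"], participants, ("age", "self_health"),
            "attractiveness", "E",
        )
        assert any("self_health" in n and "non-estimable" in n for n in fit.notes)
        row = fit.fixed_effects[fit.fixed_effects["term"] == "level_x:self_health_z"]
        assert np.isnan(row["estimate"].iloc[0])

    def test_model_scheme_enumerable_with_unique_ids(self, small_dataset):
        # the 2 tasks x 2 judgements x 5 cue sets scheme must be enumerable
        # and carry distinct model ids (checked on one battery, two cells)
        ids = set()
        for judgement in ("attractiveness", "femininity"):
            fit = fp.fit_rating_moderation_model(
                small_dataset["ratings"], small_dataset["participants"],
                ("age",), judgement, "all_cycles",
            )
            ids.add(fit.model_id)
        assert len(ids) == 2
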