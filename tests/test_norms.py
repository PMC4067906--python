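"""Rating aggregation, subgroup splits, contrasts, and covariates."""

import numpy as np
import pandas as pd
import pytest

from stimchar.fixtures import SampleSpec, SurveySpec, simulate_survey
from stimchar.norms import (
    aggregate,
    category_contrast,
    covariate_correlation,
    filter_participants,
    hunger_average,
    with_hunger,
)

VAS = ("complexity_vas", "valence_vas", "arousal_vas", "palatability_vas",
       "desire_vas")


def make_rating(participant, image, food=True, **values):
    row = {
        "participant_id": participant,
        "image_id": image,
        "familiarity": values.get("familiarity", True),
        "recognizability": values.get("recognizability", True),
    }
    for scale in VAS:
        default = 50.0 if (food or scale not in
                           ("palatability_vas", "desire_vas")) else np.nan
        row[scale] = values.get(scale, default)
    return row


def zero_noise_spec(**kw):
    defaults = dict(
        samples=(SampleSpec("s", 20, 2, 6, completion=1.0),),
        n_food_images=10,
        n_nonfood_images=4,
        latent_priors={s: (40.0, 0.0) for s in VAS},
        within_sd=0.0,
        meat_p=0.0,
        male_desire_shift=0.0,
        vegetarian_meat_palatability_shift=0.0,
        vegetarian_meat_desire_shift=0.0,
        hunger_desire_slope=0.0,
        seed=7,
    )
    defaults.update(kw)
    return SurveySpec(**defaults)


class TestFilterParticipants:
    def frame(self):
        rows = []
        # p1: 3 complete food ratings -> retained at threshold 3
        for i in range(3):
            rows.append(make_rating("p1", f"food_{i}"))
        # p2: 2 complete + 5 partial food ratings -> removed
        for i in range(2):
            rows.append(make_rating("p2", f"food_{i}"))
        for i in range(2, 7):
            rows.append(make_rating("p2", f"food_{i}", desire_vas=np.nan))
        # p3: many non-food ratings only -> removed at threshold 3
        for i in range(6):
            rows.append(make_rating("p3", f"nonfood_{i}", food=False))
        # ensure nonfood images are recognized as non-food
        return pd.DataFrame(rows)

    def test_threshold_three_keeps_exactly_complete_raters(self):
        is_food = {f"food_{i}": True for i in range(7)} | {
            f"nonfood_{i}": False for i in range(6)
        }
        out = filter_participants(self.frame(), 3, is_food=is_food)
        assert set(out["participant_id"]) == {"p1"}

    def test_threshold_zero_keeps_everyone(self):
        out = filter_participants(self.frame(), 0)
        assert set(out["participant_id"]) == {"p1", "p2", "p3"}

    def test_food_status_inferred_from_food_scales(self):
        out = filter_participants(self.frame(), 3)
        assert set(out["participant_id"]) == {"p1"}


class TestAggregate:
    def test_mean_and_n(self):
        rows = [
            make_rating(f"p{i}", "img", valence_vas=v)
            for i, v in enumerate([10.0, 20.0, 30.0])
        ]
        out = aggregate(pd.DataFrame(rows))
        cell = out[(out.image_id == "img") & (out.scale == "valence_vas")]
        assert cell["mean"].iloc[0] == pytest.approx(20.0)
        assert cell["n"].iloc[0] == 3

    def test_percent_yes(self):
        rows = [
            make_rating(f"p{i}", "img", familiarity=f)
            for i, f in enumerate([True, True, False])
        ]
        out = aggregate(pd.DataFrame(rows))
        cell = out[(out.image_id == "img") & (out.scale == "familiarity")]
        assert cell["mean"].iloc[0] == pytest.approx(66.6667, abs=1e-3)

    def test_permutation_invariance(self, rng):
        rows = [
            make_rating(f"p{i}", f"img{i % 3}", valence_vas=float(v))
            for i, v in enumerate(rng.integers(1, 101, 30))
        ]
        frame = pd.DataFrame(rows)
        shuffled = frame.sample(frac=1.0, random_state=3).reset_index(
            drop=True
        )
        a = aggregate(frame)
        b = aggregate(shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_subgroup_ns_partition_overall_n(self):
        data = simulate_survey(zero_noise_spec())
        out = aggregate(data.ratings, data.profiles, ["gender"])
        overall = out[out.subgroup == "all"]
        by_gender = out[out.subgroup != "all"]
        merged = by_gender.groupby(["image_id", "scale"])["n"].sum()
        for (image_id, scale), n in merged.items():
            ref = overall[
                (overall.image_id == image_id) & (overall.scale == scale)
            ]["n"].iloc[0]
            assert n == ref

    def test_unknown_subgroup_factor_is_config_error(self):
        data = simulate_survey(zero_noise_spec())
        with pytest.raises(ValueError, match="shoe_size"):
            aggregate(data.ratings, data.profiles, ["shoe_size"])

    def test_zero_noise_survey_recovers_latent_means_exactly(self):
        data = simulate_survey(zero_noise_spec())
        out = aggregate(data.ratings)
        vas_rows = out[out.scale.isin(VAS) & (out.subgroup == "all")]
        assert (vas_rows["mean"] == 40.0).all()

    def test_average_raters_per_image_matches_design_expectation(self):
        spec = zero_noise_spec(
            samples=(SampleSpec("s", 60, 4, 12, completion=1.0),),
            n_food_images=24, n_nonfood_images=12,
        )
        data = simulate_survey(spec)
        raters = data.ratings.groupby("image_id").size()
        # 60 raters x 12 food picks over 24 images = 30 expected; same
        # for non-food (60 x 4 / 12 = 20).
        food = raters[raters.index.str.startswith("food")]
        nonfood = raters[raters.index.str.startswith("nonfood")]
        assert food.mean() == pytest.approx(30.0)
        assert nonfood.mean() == pytest.approx(20.0)


class TestCategoryContrast:
    def test_identical_groups_give_zero_t_and_d(self):
        rows = []
        for p in ("p1", "p2", "p3"):
            rows.append(make_rating(p, "a1", valence_vas=42.0))
            rows.append(make_rating(p, "b1", valence_vas=42.0))
        res = category_contrast(
            pd.DataFrame(rows), {"a1": "a", "b1": "b"}, "valence_vas"
        )
        assert res.t == 0.0
        assert res.d_z == 0.0
        assert res.df == 2

    def test_recovers_injected_difference(self):
        rows = []
        rng = np.random.default_rng(5)
        for i in range(40):
            base = rng.normal(50, 5)
            rows.append(
                make_rating(
                    f"p{i}", "a1",
                    valence_vas=base + 6.0 + rng.normal(0, 0.5),
                )
            )
            rows.append(make_rating(f"p{i}", "b1", valence_vas=base))
        res = category_contrast(
            pd.DataFrame(rows), {"a1": "a", "b1": "b"}, "valence_vas"
        )
        assert res.mean_a - res.mean_b == pytest.approx(6.0, abs=0.5)
        assert res.p < 1e-6

    def test_participants_missing_one_group_excluded(self):
        rows = [
            make_rating("p1", "a1"), make_rating("p1", "b1"),
            make_rating("p2", "a1"), make_rating("p2", "b1"),
            make_rating("p3", "a1"),  # never rated group b
        ]
        res = category_contrast(
            pd.DataFrame(rows), {"a1": "a", "b1": "b"}, "valence_vas"
        )
        assert res.n_participants == 2

    def test_no_participant_spanning_both_groups_is_error(self):
        rows = [make_rating("p1", "a1"), make_rating("p2", "b1")]
        with pytest.raises(ValueError):
            category_contrast(
                pd.DataFrame(rows), {"a1": "a", "b1": "b"}, "valence_vas"
            )

    def test_d_conventions_relate_through_their_definitions(self):
        rows = []
        rng = np.random.default_rng(11)
        for i in range(30):
            rows.append(
                make_rating(f"p{i}", "a1", valence_vas=rng.normal(55, 8))
            )
            rows.append(
                make_rating(f"p{i}", "b1", valence_vas=rng.normal(50, 8))
            )
        res = category_contrast(
            pd.DataFrame(rows), {"a1": "a", "b1": "b"}, "valence_vas"
        )
        assert res.d_z == pytest.approx(
            res.t / np.sqrt(res.n_participants), rel=1e-9
        )
        assert res.d_av == pytest.approx(
            (res.mean_a - res.mean_b) / ((res.sd_a + res.sd_b) / 2), rel=1e-9
        )


class TestCovariateCorrelation:
    def test_perfect_covariate_gives_r_one(self):
        rows, profs = [], []
        for i, v in enumerate([20.0, 40.0, 60.0, 80.0]):
            rows.append(make_rating(f"p{i}", "img", desire_vas=v))
            profs.append({"participant_id": f"p{i}", "hunger": v})
        res = covariate_correlation(
            pd.DataFrame(rows), pd.DataFrame(profs), "hunger", "desire_vas"
        )
        assert res.r == pytest.approx(1.0)

    def test_constant_covariate_rejected(self):
        rows, profs = [], []
        for i in range(4):
            rows.append(make_rating(f"p{i}", "img", desire_vas=float(i)))
            profs.append({"participant_id": f"p{i}", "hunger": 30.0})
        with pytest.raises(ValueError):
            covariate_correlation(
                pd.DataFrame(rows), pd.DataFrame(profs), "hunger",
                "desire_vas",
            )

    def test_independent_covariate_near_zero_over_replicates(self):
        rs = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            rows = [
                make_rating(f"p{i}", "img", desire_vas=rng.normal(50, 10))
                for i in range(30)
            ]
            profs = pd.DataFrame(
                {
                    "participant_id": [f"p{i}" for i in range(30)],
                    "hunger": rng.normal(30, 10, 30),
                }
            )
            rs.append(
                covariate_correlation(
                    pd.DataFrame(rows), profs, "hunger", "desire_vas"
                ).r
            )
        assert abs(np.mean(rs)) < 3 / np.sqrt(30 * len(rs))


class TestHungerAverage:
    @pytest.mark.parametrize(
        "pre,post,expected", [(20, 40, 30.0), (1, 100, 50.5)]
    )
    def test_mean_of_both(self, pre, post, expected):
        res = hunger_average(pre, post)
        assert res.value == expected
        assert not res.single_source

    def test_single_source_flagged(self):
        res = hunger_average(50, None)
        assert res.value == 50.0
        assert res.single_source

    def test_both_missing_propagates_nan(self):
        assert np.isnan(hunger_average(None, np.nan).value)

    def test_with_hunger_adds_column(self):
        profiles = pd.DataFrame(
            {
                "participant_id": ["p1", "p2"],
                "hunger_pre": [20, np.nan],
                "hunger_post": [40, 60],
            }
        )
        out = with_hunger(profiles)
        assert list(out["hunger"]) == [30.0, 60.0]
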