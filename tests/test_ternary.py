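"""Centroid statistic and its three p-value routes against independent oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import facepref as fp
from facepref.ternary import TernaryComposition, _int_statistic


def brute_force_p(counts, tie_rule="geq"):
    """Independent oracle: enumerate all 3^n per-rater choice assignments."""
    n = sum(counts)
    obs = _int_statistic(np.array(counts), n)

    def T(outcome):
        c = [outcome.count(j) for j in range(3)]
        return _int_statistic(np.array(c), n)

    hits = 0
    for outcome in itertools.product(range(3), repeat=n):
        t = T(outcome)
        if (t >= obs) if tie_rule == "geq" else (t > obs):
            hits += 1
    return hits / 3**n


class TestCentroidVector:
    def test_centroid_is_zero(self):
        mag, _ = fp.centroid_vector((5, 5, 5))
        assert mag == pytest.approx(0.0, abs=1e-15)

    def test_vertex_is_circumradius(self):
        mag, point = fp.centroid_vector((1, 0, 0))
        assert mag == pytest.approx(1 / math.sqrt(3), rel=1e-12)
        assert point == pytest.approx([0.0, 0.0])

    def test_coordinate_and_closed_form_agree(self):
        # published textbook-cycle attractiveness proportions
        p = np.array([0.2964, 0.3101, 0.3935])
        counts = np.round(p * 10_000).astype(int)
        mag, _ = fp.centroid_vector(tuple(counts))
        closed = math.sqrt(np.sum((p - 1 / 3) ** 2) / 2)
        assert mag == pytest.approx(closed, rel=1e-6)

    @given(st.permutations([3, 7, 19]))
    def test_label_symmetry(self, perm):
        base_mag, _ = fp.centroid_vector((3, 7, 19))
        mag, _ = fp.centroid_vector(tuple(perm))
        assert mag == pytest.approx(base_mag, rel=1e-12)
        assert fp.exact_multinomial_p(tuple(perm)) == pytest.approx(
            fp.exact_multinomial_p((3, 7, 19)), rel=1e-12
        )

    @given(
        st.tuples(
            st.integers(0, 12), st.integers(0, 12), st.integers(0, 12)
        ).filter(lambda c: sum(c) >= 2 and max(c) < sum(c))
    )
    def test_moving_toward_vertex_never_decreases_magnitude(self, counts):
        a, b, c = counts
        # move one unit from the smallest positive cell to the largest cell
        arr = list(counts)
        src = min((i for i in range(3) if arr[i] > 0), key=lambda i: arr[i])
        dst = max(range(3), key=lambda i: arr[i])
        if src == dst:
            return
        before, _ = fp.centroid_vector(tuple(arr))
        arr[dst] += 1
        arr[src] -= 1
        after, _ = fp.centroid_vector(tuple(arr))
        assert after >= before - 1e-12


class TestTallyChoices:
    def test_counts_each_level_once(self, small_dataset):
        comp = fp.tally_choices(
            small_dataset["choices"], "attractiveness", "textbook"
        )
        assert comp.n == len(small_dataset["participants"])

    def test_simple_tally(self):
        import pandas as pd

        choices = pd.DataFrame(
            {
                "participant_id": [1, 2, 3],
                "judgement": "attractiveness",
                "cue_set": "E",
                "chosen_level": ["low", "medium", "high"],
            }
        )
        comp = fp.tally_choices(choices, "attractiveness", "E")
        assert tuple(comp) == (1, 1, 1)

    def test_duplicate_participant_raises(self):
        import pandas as pd

        choices = pd.DataFrame(
            {
                "participant_id": [1, 1],
                "judgement": "attractiveness",
                "cue_set": "E",
                "chosen_level": ["low", "high"],
            }
        )
        with pytest.raises(ValueError, match="duplicate"):
            fp.tally_choices(choices, "attractiveness", "E")

    def test_empty_cell_raises_with_cell_name(self):
        import pandas as pd

        choices = pd.DataFrame(
            {"participant_id": [], "judgement": [], "cue_set": [], "chosen_level": []}
        )
        with pytest.raises(ValueError, match="femininity"):
            fp.tally_choices(choices, "femininity", "P")


class TestExactEnumeration:
    def test_single_observation_symmetric(self):
        assert fp.exact_multinomial_p((1, 0, 0)) == pytest.approx(1.0)

    def test_two_observations_vertex(self):
        # outcomes: 3 vertex outcomes w.p. 1/9 each beat 3 mixed w.p. 2/9
        assert fp.exact_multinomial_p((2, 0, 0)) == pytest.approx(3 / 9)

    @pytest.mark.parametrize("counts", [(2, 0, 0), (1, 1, 0), (4, 1, 1), (2, 2, 2)])
    def test_matches_brute_force_assignment_enumeration(self, counts):
        for rule in ("geq", "gt"):
            assert fp.exact_multinomial_p(counts, tie_rule=rule) == pytest.approx(
                brute_force_p(counts, rule), rel=1e-9
            )

    @given(
        st.tuples(st.integers(0, 10), st.integers(0, 10), st.integers(0, 10)).filter(
            lambda c: sum(c) >= 1
        )
    )
    def test_gt_never_exceeds_geq(self, counts):
        assert fp.exact_multinomial_p(counts, "gt") <= fp.exact_multinomial_p(
            counts, "geq"
        ) + 1e-12

    def test_large_n_refused(self):
        with pytest.raises(ValueError, match="mc_randomisation_test"):
            fp.exact_multinomial_p((100, 100, 100))


class TestMonteCarlo:
    def test_centroid_composition_p_is_one(self):
        res = fp.mc_randomisation_test((457, 457, 457), n_sim=2000, seed=0)
        assert res.p_value == 1.0

    def test_textbook_attractiveness_cell_significant(self):
        res = fp.mc_randomisation_test((406, 425, 540), n_sim=10_000, seed=1)
        assert res.p_value < 0.001

    @pytest.mark.parametrize("counts", [(4, 1, 1), (10, 6, 4), (7, 7, 6)])
    def test_within_three_mc_ses_of_exact(self, counts):
        exact = fp.exact_multinomial_p(counts)
        res = fp.mc_randomisation_test(counts, n_sim=50_000, seed=7)
        se = math.sqrt(exact * (1 - exact) / 50_000)
        assert abs(res.p_value - exact) <= 3 * se + 1e-12

    def test_seed_reproducible(self):
        a = fp.mc_randomisation_test((30, 20, 10), n_sim=5000, seed=42)
        b = fp.mc_randomisation_test((30, 20, 10), n_sim=5000, seed=42)
        assert a.p_value == b.p_value
        assert a.exceedances == b.exceedances

    def test_smoothed_p_reported(self):
        res = fp.mc_randomisation_test((40, 10, 10), n_sim=1000, seed=3)
        assert res.p_value_smoothed == pytest.approx(
            (res.exceedances + 1) / 1001
        )


class TestChiSquareClosedForm:
    def test_centroid_gives_one(self):
        assert fp.chi_square_p((457, 457, 457)) == pytest.approx(1.0)

    def test_published_ep_attractiveness_counts(self):
        # X^2 = 3318/457, p = exp(-X^2/2)
        x2 = 3318 / 457
        assert fp.chi_square_p((495, 414, 462)) == pytest.approx(
            math.exp(-x2 / 2), rel=1e-9
        )


class TestEstimatorInterface:
    def test_methods_agree_on_small_composition(self):
        comp = TernaryComposition(12, 6, 2)
        mc = fp.TernaryRandomisationTest(n_sim=50_000, seed=5, method="mc").fit(comp)
        exact = fp.TernaryRandomisationTest(method="exact").fit(comp)
        se = math.sqrt(exact.p_value_ * (1 - exact.p_value_) / 50_000)
        assert abs(mc.p_value_ - exact.p_value_) <= 3 * se + 1e-12
        assert mc.magnitude_ == pytest.approx(exact.magnitude_)

    def test_get_set_params_roundtrip(self):
        est = fp.TernaryRandomisationTest(n_sim=123, tie_rule="gt")
        params = est.get_params()
        est2 = fp.TernaryRandomisationTest().set_params(**params)
        assert est2.n_sim == 123 and est2.tie_rule == "gt"

    def test_invalid_composition_rejected(self):
        with pytest.raises(ValueError):
            TernaryComposition(-1, 2, 3)
        with pytest.raises(ValueError):
            TernaryComposition(0, 0, 0)
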