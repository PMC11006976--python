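import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedtol import (
    GerminationTrial,
    InvalidInputError,
    MissingLevelError,
    TreatmentScheme,
    cold_weight,
    compute_indices,
    drought_weight,
    germination_index,
    saline_weight,
    tolerance_index,
)
from seedtol.germination import saline_index_literal, trials_from_frame, indices_to_frame

from .oracles import flat_loop_indices


def make_trial(counts, experiment="drought", level=1, value=0.0, seeds=50, rep=1, pop="P01"):
    return GerminationTrial(pop, experiment, level, value, rep, tuple(counts), seeds)


class TestGerminationIndex:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([10], 10.0),                  # all on day 1
            ([0, 0, 0], 0.0),              # nothing germinated
            ([5, 3, 2], 5 / 1 + 3 / 2 + 2 / 3),
        ],
    )
    def test_speed_weighted_count(self, counts, expected):
        assert germination_index(make_trial(counts)) == pytest.approx(expected, abs=1e-4)

    def test_negative_count_names_dish(self):
        with pytest.raises(InvalidInputError, match="population='P07'"):
            make_trial([3, -1], pop="P07")

    def test_overflow_beyond_dish_size_rejected(self):
        with pytest.raises(InvalidInputError, match="exceeds"):
            make_trial([30, 30], seeds=50)

    def test_day_span_limits(self):
        with pytest.raises(InvalidInputError):
            make_trial([])
        with pytest.raises(InvalidInputError):
            make_trial([1] * 16)

    @settings(derandomize=True, max_examples=50)
    @given(
        counts=st.lists(st.integers(min_value=0, max_value=3), min_size=1, max_size=15),
        k=st.integers(min_value=1, max_value=5),
    )
    def test_scale_equivariance(self, counts, k):
        gi = germination_index(make_trial(counts, seeds=45))
        gi_k = germination_index(make_trial([k * c for c in counts], seeds=45 * k))
        assert gi_k == pytest.approx(k * gi, rel=1e-12, abs=1e-12)


class TestWeights:
    @pytest.mark.parametrize(
        "w, expected", [(0.0, 1.0), (-0.3, 1.3), (-0.6, 1.6), (-0.9, 1.9), (-1.2, 2.2)]
    )
    def test_drought_grid(self, w, expected):
        assert drought_weight(w) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "t, expected", [(25, 1.0), (20, 1.25), (15, 25 / 15), (10, 2.5), (5, 5.0)]
    )
    def test_cold_grid(self, t, expected):
        assert cold_weight(t, 25.0) == pytest.approx(expected, abs=1e-4)

    @pytest.mark.parametrize(
        "s, level, expected",
        [(0, 1, 1.0), (50, 2, 5.0), (100, 3, 10.0), (150, 4, 15.0), (200, 5, 20.0)],
    )
    def test_saline_grid(self, s, level, expected):
        assert saline_weight(s, level) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            drought_weight(0.5)
        with pytest.raises(InvalidInputError):
            cold_weight(0.0)
        with pytest.raises(InvalidInputError):
            cold_weight(-5.0)
        with pytest.raises(InvalidInputError):
            saline_weight(100, 6)
        with pytest.raises(InvalidInputError):
            saline_weight(-1, 2)

    def test_all_weights_at_least_one(self):
        scheme = TreatmentScheme()
        for exp in ("drought", "cold", "saline"):
            for level in range(1, 6):
                assert scheme.weight(exp, level) >= 1.0


class TestToleranceIndex:
    def test_unit_gi_drought(self):
        assert tolerance_index([1] * 5, [1, 1.3, 1.6, 1.9, 2.2]) == pytest.approx(1.6)

    def test_unit_gi_cold(self):
        weights = [1, 1.25, 25 / 15, 2.5, 5]
        assert tolerance_index([1] * 5, weights) == pytest.approx(2.2833, abs=1e-3)

    def test_unit_gi_saline(self):
        assert tolerance_index([1] * 5, [1, 5, 10, 15, 20]) == pytest.approx(10.2)

    def test_zero_germination(self):
        assert tolerance_index([0] * 5, [1, 1.3, 1.6, 1.9, 2.2]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            tolerance_index([1, 1, 1], [1, 1, 1])

    def test_literal_saline_reading_drops_control(self):
        assert saline_index_literal([1] * 5, [1, 5, 10, 15, 20]) == pytest.approx(10.0)

    @settings(derandomize=True, max_examples=50)
    @given(gi=st.lists(st.floats(0, 50), min_size=5, max_size=5))
    def test_weight_floor(self, gi):
        """All weights >= 1, so each index is at least the unweighted mean GI."""
        for weights in ([1, 1.3, 1.6, 1.9, 2.2], [1, 1.25, 25 / 15, 2.5, 5], [1, 5, 10, 15, 20]):
            assert tolerance_index(gi, weights) >= sum(gi) / 5 - 1e-9

    @settings(derandomize=True, max_examples=50)
    @given(
        gi=st.lists(st.floats(0, 50), min_size=5, max_size=5),
        level=st.integers(min_value=0, max_value=4),
        bump=st.floats(0.1, 10),
    )
    def test_monotone_in_any_level(self, gi, level, bump):
        weights = [1, 1.3, 1.6, 1.9, 2.2]
        bumped = list(gi)
        bumped[level] += bump
        assert tolerance_index(bumped, weights) >= tolerance_index(gi, weights)


def full_germination_trials(pop="P01", reps=(1,)):
    scheme = TreatmentScheme()
    return [
        make_trial([50], experiment=exp, level=level,
                   value=scheme.levels(exp)[level - 1], rep=rep, pop=pop)
        for exp in ("drought", "cold", "saline")
        for level in range(1, 6)
        for rep in reps
    ]


class TestComputeIndices:
    def test_full_germination_closed_form(self):
        """GI=50 at every level scales the unit-GI values by 50."""
        [result] = compute_indices(full_germination_trials())
        assert result.gdti == pytest.approx(80.0)
        assert result.gcti == pytest.approx(50 * (1 + 1.25 + 25 / 15 + 2.5 + 5) / 5, abs=0.01)
        assert result.gsti == pytest.approx(510.0)

    def test_literal_gsti_switch(self):
        [result] = compute_indices(full_germination_trials(), gsti_interpretation="literal")
        assert result.gsti == pytest.approx(500.0)  # control GI dropped

    def test_zero_germination_everywhere(self):
        scheme = TreatmentScheme()
        trials = [
            make_trial([0, 0], experiment=exp, level=level,
                       value=scheme.levels(exp)[level - 1])
            for exp in ("drought", "cold", "saline")
            for level in range(1, 6)
        ]
        [result] = compute_indices(trials)
        assert (result.gdti, result.gcti, result.gsti) == (0.0, 0.0, 0.0)

    def test_control_only_germination(self):
        """Only the unstressed level germinates: index = GI_1 / 5."""
        scheme = TreatmentScheme()
        trials = [
            make_trial([20] if level == 1 else [0], experiment=exp, level=level,
                       value=scheme.levels(exp)[level - 1])
            for exp in ("drought", "cold", "saline")
            for level in range(1, 6)
        ]
        [result] = compute_indices(trials)
        assert result.gdti == pytest.approx(4.0)
        assert result.gcti == pytest.approx(4.0)
        assert result.gsti == pytest.approx(4.0)

    def test_missing_level_is_structured_error(self):
        trials = [t for t in full_germination_trials() if
                  not (t.experiment == "cold" and t.level_index == 3)]
        with pytest.raises(MissingLevelError) as exc:
            compute_indices(trials)
        assert ("P01", "cold", 3) in exc.value.missing

    def test_population_mean_averages_gi_first(self):
        scheme = TreatmentScheme()
        trials = []
        for rep, counts in ((1, [50]), (2, [0])):
            for exp in ("drought", "cold", "saline"):
                for level in range(1, 6):
                    trials.append(
                        make_trial(counts, experiment=exp, level=level,
                                   value=scheme.levels(exp)[level - 1], rep=rep)
                    )
        [result] = compute_indices(trials, aggregation="population_mean")
        assert result.replicate == 0
        assert result.gdti == pytest.approx(40.0)  # mean GI of 25 at every level

    def test_matches_flat_loop_oracle_on_demo21(self, demo21_trials):
        expected = flat_loop_indices(demo21_trials)
        frame = indices_to_frame(compute_indices(demo21_trials))
        assert len(frame) == len(expected)
        for row in frame.itertuples():
            gdti, gcti, gsti = expected[(row.population_id, row.replicate)]
            assert row.GDTI == pytest.approx(gdti, abs=1e-9)
            assert row.GCTI == pytest.approx(gcti, abs=1e-9)
            assert row.GSTI == pytest.approx(gsti, abs=1e-9)


def test_trials_from_frame_round_trip(demo21_trials):
    from seedtol.simulate import trials_to_frame

    frame = trials_to_frame(demo21_trials)
    rebuilt = trials_from_frame(frame)
    assert {
        (t.population_id, t.experiment, t.level_index, t.replicate): t.daily_counts
        for t in rebuilt
    } == {
        (t.population_id, t.experiment, t.level_index, t.replicate): t.daily_counts
        for t in demo21_trials
    }
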