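"""Virtual-population generator: maturation functions, weights, sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chqdose import population as pop


class TestMaturationFunctions:
    @pytest.mark.parametrize(
        "fn", [pop.ontogeny_cyp3a4, pop.ontogeny_cyp2c8, pop.gfr_maturation]
    )
    def test_adult_identity_is_exact(self, fn):
        for age in (18.0, 25.0, 30.0, 40.0, 64.9):
            assert fn(age) == 1.0

    @pytest.mark.parametrize(
        "fn", [pop.ontogeny_cyp3a4, pop.ontogeny_cyp2c8, pop.gfr_maturation]
    )
    def test_nondecreasing_on_fine_age_grid(self, fn):
        grid = np.linspace(0.0, 18.0, 1000)
        vals = fn(grid)
        assert np.all(np.diff(vals) >= -1e-12)
        assert np.all(vals > 0)

    @pytest.mark.parametrize(
        "fn", [pop.ontogeny_cyp3a4, pop.ontogeny_cyp2c8, pop.gfr_maturation]
    )
    def test_negative_age_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(-0.1)

    def test_cyp3a4_birth_value_is_configured_immature_fraction(self):
        # at birth the sigmoid collapses to its f_birth parameter
        assert pop.ontogeny_cyp3a4(0.0) == pytest.approx(
            pop.DEFAULT_ONTOGENY.cyp3a4.f_birth
        )
        assert pop.ontogeny_cyp3a4(0.0) < 0.5

    def test_cyp2c8_birth_value_below_adult(self):
        assert pop.ontogeny_cyp2c8(0.0) == pytest.approx(
            pop.DEFAULT_ONTOGENY.cyp2c8.f_birth
        )
        assert pop.ontogeny_cyp2c8(0.0) < 1.0

    def test_gfr_birth_value_matches_pma_sigmoid_at_term(self):
        # PMA sigmoid evaluated at 40 weeks: 40^h / (40^h + 47.7^h)
        g = pop.DEFAULT_ONTOGENY.gfr
        expected = 40.0**g.hill / (40.0**g.hill + g.pma50_weeks**g.hill)
        assert pop.gfr_maturation(0.0) == pytest.approx(expected)
        assert 0.0 < pop.gfr_maturation(0.0) < 0.6

    def test_monotonicity_examples(self):
        assert pop.ontogeny_cyp3a4(0.5) <= pop.ontogeny_cyp3a4(5.0)
        assert pop.gfr_maturation(1.0 / 12.0) < pop.gfr_maturation(1.0)

    @given(
        a=st.floats(min_value=0.0, max_value=18.0),
        b=st.floats(min_value=0.0, max_value=18.0),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_pairwise_monotonicity_property(self, a, b):
        lo, hi = min(a, b), max(a, b)
        for fn in (pop.ontogeny_cyp3a4, pop.ontogeny_cyp2c8, pop.gfr_maturation):
            assert fn(lo) <= fn(hi) + 1e-12


class TestWeights:
    def test_adult_zero_spread_is_reference_75kg(self, rng):
        assert pop.sample_weight(30.0, "male", rng, cv=0.0) == 75.0
        assert pop.sample_weight(30.0, "female", rng, cv=0.0) == 75.0

    def test_neonate_zero_spread_matches_table_median(self, rng):
        table = pop.load_growth_table()
        for sex in ("male", "female"):
            expected = float(
                table[(table.sex == sex) & (table.age_years == 0)][
                    "median_weight_kg"
                ].iloc[0]
            )
            assert pop.sample_weight(0.0, sex, rng, cv=0.0) == expected
            assert 3.0 <= expected <= 4.0

    def test_same_seed_same_weight(self):
        w1 = pop.sample_weight(4.0, "female", np.random.default_rng(7))
        w2 = pop.sample_weight(4.0, "female", np.random.default_rng(7))
        assert w1 == w2
        assert w1 > 0

    def test_interpolation_between_table_rows(self, rng):
        table = pop.load_growth_table()
        m = table[table.sex == "male"]
        w5 = float(m[m.age_years == 5]["median_weight_kg"].iloc[0])
        w6 = float(m[m.age_years == 6]["median_weight_kg"].iloc[0])
        assert w5 < pop.sample_weight(5.5, "male", rng, cv=0.0) < w6


class TestPopulationSampling:
    def test_adult_spec_counts_and_age_bounds(self):
        spec = pop.PopulationSpec(pop.ADULT, 10, 40, seed=1)
        trials = pop.sample_population(spec)
        subjects = [s for t in trials for s in t]
        assert len(trials) == 10 and len(subjects) == 400
        assert all(18.0 <= s.age < 65.0 for s in subjects)

    def test_seed_reproducibility_bit_identical(self):
        spec = pop.PopulationSpec(pop.CHILD_6_MO_5_Y, 3, 17, seed=42)
        assert pop.sample_population(spec) == pop.sample_population(spec)

    def test_different_seeds_differ(self):
        a = pop.sample_population(pop.PopulationSpec(pop.ADULT, 1, 5, seed=1))
        b = pop.sample_population(pop.PopulationSpec(pop.ADULT, 1, 5, seed=2))
        assert a != b

    def test_female_fraction_near_half(self):
        spec = pop.PopulationSpec(pop.NEONATE, 1, 1000, seed=3)
        subjects = pop.sample_population(spec)[0]
        frac = np.mean([s.sex == "female" for s in subjects])
        assert abs(frac - 0.5) < 0.05

    def test_maturation_fields_match_functions(self):
        spec = pop.PopulationSpec(pop.INFANT_1_6_MO, 1, 10, seed=9)
        for s in pop.sample_population(spec)[0]:
            assert s.f_cyp3a4 == pytest.approx(pop.ontogeny_cyp3a4(s.age))
            assert s.f_gfr == pytest.approx(pop.gfr_maturation(s.age))

    def test_adult_subjects_fully_mature(self):
        spec = pop.PopulationSpec(pop.ADULT, 1, 20, seed=4)
        for s in pop.sample_population(spec)[0]:
            assert s.f_cyp3a4 == s.f_cyp2c8 == s.f_gfr == 1.0

    def test_export_frame_columns(self):
        spec = pop.PopulationSpec(pop.CHILD_5_12_Y, 2, 3, seed=0)
        frame = pop.population_to_frame(pop.sample_population(spec))
        assert list(frame.columns) == [
            "trial_id", "subject_id", "age_years", "sex", "weight_kg",
            "f_cyp3a4", "f_cyp2c8", "f_gfr",
        ]
        assert len(frame) == 6

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            pop.PopulationSpec(pop.ADULT, 0, 10)
        with pytest.raises(ValueError):
            pop.PopulationSpec(pop.ADULT, 1, 10, prop_female=1.5)
        with pytest.raises(ValueError):
            pop.AgeGroupSpec("bad", 5.0, 5.0)
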