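import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ligfid.repeat_instability import (InstabilityConfig, PeakTable,
                                       call_modal, cohort_expansion,
                                       compare_groups, expansion_index,
                                       significance_tier, to_repeat_units)
from ligfid.synthetic_data import NoiseModel, TraceSpec, make_cohort, \
    make_fragment_trace

SELF = InstabilityConfig(reference_policy="self_modal")


def brute_force_index(positions, heights, reference, threshold=0.05):
    """Literal four-step reference implementation of the expansion index."""
    positions = np.asarray(positions, float)
    heights = np.asarray(heights, float)
    retained = [(p, h) for p, h in zip(positions, heights)
                if h >= threshold * heights.max()]          # (1) threshold
    above = [(p, h) for p, h in retained if p > reference]  # (2) above reference
    total = sum(h for _, h in above)
    if total == 0:
        return 0.0
    return sum(h / total * (p - reference) for p, h in above)  # (3) + (4)


class TestToRepeatUnits:
    def test_plain_conversion(self):
        t = PeakTable("s", [300.0, 303.0, 306.0], [1.0, 2.0, 3.0],
                      position_units="bp")
        out = to_repeat_units(t, InstabilityConfig(bp_offset=0.0))
        np.testing.assert_array_equal(out.positions, [100, 101, 102])
        assert out.position_units == "repeats"

    def test_repeats_table_passes_through(self):
        t = PeakTable("s", [100.0, 101.0], [1.0, 2.0])
        assert to_repeat_units(t) is t

    def test_collisions_merge_by_height(self):
        t = PeakTable("s", [300.0, 301.0, 303.0], [1.0, 2.0, 4.0],
                      position_units="bp")
        out = to_repeat_units(t)
        np.testing.assert_array_equal(out.positions, [100, 101])
        np.testing.assert_array_equal(out.heights, [3.0, 4.0])

    def test_bp_twin_equals_repeats_native(self):
        """Index via bp conversion equals the index computed on a
        repeats-native twin of the same trace."""
        spec = TraceSpec(expansion_mean=5.0, expansion_dispersion=2.0)
        noise = NoiseModel(height_cv=0.0, seed=0)
        rep_table, _ = make_fragment_trace(spec, noise)
        bp_table, _ = make_fragment_trace(spec, noise, units="bp")
        converted = to_repeat_units(bp_table)
        a = expansion_index(rep_table, spec.inherited_repeat, SELF)
        b = expansion_index(converted, spec.inherited_repeat, SELF)
        assert a.expansion_index == pytest.approx(b.expansion_index)


class TestCallModal:
    def test_tallest_peak(self):
        t = PeakTable("s", [100, 101, 102], [1.0, 5.0, 2.0])
        assert call_modal(t) == 101

    def test_exact_tie_breaks_to_smaller_repeat(self):
        t = PeakTable("s", [100, 101, 102], [5.0, 1.0, 5.0])
        assert call_modal(t) == 100

    def test_stable_generator_trace_modal_is_inherited(self):
        spec = TraceSpec(stable_fraction=0.9, expansion_mean=5.0)
        table, _ = make_fragment_trace(spec, NoiseModel(height_cv=0.0, seed=1))
        assert call_modal(table) == spec.inherited_repeat


class TestExpansionIndex:
    def test_single_peak_at_reference_is_zero(self):
        t = PeakTable("s", [100.0], [7.0])
        res = expansion_index(t, 100.0, SELF)
        assert res.expansion_index == 0.0
        assert res.n_peaks_retained == 0

    def test_hand_example_four_thirds(self):
        t = PeakTable("s", [100, 101, 102], [10.0, 4.0, 2.0])
        res = expansion_index(t, 100.0, SELF)
        assert res.expansion_index == pytest.approx(4 / 3)
        assert res.n_peaks_retained == 2
        assert res.weights == pytest.approx({101.0: 2 / 3, 102.0: 1 / 3})

    @pytest.mark.parametrize("height,included", [
        (0.4, False),   # 4% of max: excluded
        (0.5, True),    # exactly 5%: included (>= comparison)
        (0.6, True),    # 6%: included
    ])
    def test_threshold_boundary(self, height, included):
        t = PeakTable("s", [100, 101], [10.0, height])
        res = expansion_index(t, 100.0, SELF)
        assert (res.n_peaks_retained == 1) is included

    def test_signed_mode_includes_contractions(self):
        t = PeakTable("s", [99, 100, 101], [3.0, 10.0, 3.0])
        unsigned = expansion_index(t, 100.0, SELF)
        signed = expansion_index(
            t, 100.0, InstabilityConfig(reference_policy="self_modal", signed=True))
        assert unsigned.expansion_index == pytest.approx(1.0)
        assert signed.expansion_index == pytest.approx(0.0)

    def test_suspicious_reference_warns(self):
        t = PeakTable("s", [100, 101], [1.0, 1.0])
        with pytest.warns(UserWarning, match="below the smallest peak"):
            expansion_index(t, 50.0, SELF)

    @settings(deadline=None, max_examples=100)
    @given(data=st.data())
    def test_translation_and_scale_invariance(self, data):
        n = data.draw(st.integers(2, 8))
        start = data.draw(st.integers(50, 150))
        heights = data.draw(st.lists(
            st.floats(0.01, 100), min_size=n, max_size=n))
        shift = data.draw(st.integers(-20, 20))
        scale = data.draw(st.floats(0.01, 1000))
        pos = np.arange(start, start + n, dtype=float)
        ref = float(data.draw(st.integers(start - 2, start + n)))
        base = expansion_index(PeakTable("s", pos, heights), ref, SELF)
        shifted = expansion_index(
            PeakTable("s", pos + shift, heights), ref + shift, SELF)
        scaled = expansion_index(
            PeakTable("s", pos, np.asarray(heights) * scale), ref, SELF)
        assert shifted.expansion_index == pytest.approx(
            base.expansion_index, rel=1e-9, abs=1e-9)
        assert scaled.expansion_index == pytest.approx(
            base.expansion_index, rel=1e-9, abs=1e-9)

    def test_adding_above_threshold_peak_strictly_increases_index(self):
        t = PeakTable("s", [100, 101, 102], [10.0, 4.0, 2.0])
        base = expansion_index(t, 100.0, SELF).expansion_index
        t2 = PeakTable("s", [100, 101, 102, 105], [10.0, 4.0, 2.0, 3.0])
        assert expansion_index(t2, 100.0, SELF).expansion_index > base

    def test_matches_bruteforce_on_random_tables(self):
        """Oracle equivalence with a literal implementation of the four
        stated steps on 1,000 random small peak tables."""
        import warnings

        rng = np.random.default_rng(2024)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            for _ in range(1000):
                n = rng.integers(1, 10)
                pos = np.sort(rng.choice(np.arange(90, 130), size=n,
                                         replace=False))
                heights = rng.uniform(0.01, 50, size=n)
                ref = float(rng.integers(88, 132))
                got = expansion_index(
                    PeakTable("s", pos.astype(float), heights), ref, SELF)
                expect = brute_force_index(pos, heights, ref)
                assert got.expansion_index == pytest.approx(expect, abs=1e-12)


class TestCohort:
    def test_liver_reference_matches_self_modal_for_liver(self):
        tables, _ = make_cohort({"A": 6.0}, 3, NoiseModel(seed=5))
        cohort = cohort_expansion(tables, InstabilityConfig())
        for _, row in cohort[cohort["tissue"] == "liver"].iterrows():
            liver = next(t for t in tables
                         if t.mouse_id == row["mouse"] and t.tissue == "liver")
            self_res = expansion_index(liver, call_modal(liver), SELF)
            assert row["expansion_index"] == pytest.approx(
                self_res.expansion_index)

    def test_missing_liver_trace_names_mouse(self):
        tables, _ = make_cohort({"A": 6.0}, 2, NoiseModel(seed=5))
        tables = [t for t in tables
                  if not (t.mouse_id == "A_m0" and t.tissue == "liver")]
        with pytest.raises(ValueError, match="A_m0"):
            cohort_expansion(tables, InstabilityConfig())

    def test_row_order_invariance(self):
        tables, _ = make_cohort({"A": 6.0, "B": 4.0}, 3, NoiseModel(seed=5))
        a = cohort_expansion(tables, InstabilityConfig())
        b = cohort_expansion(tables[::-1], InstabilityConfig())
        key = ["mouse", "tissue"]
        pd.testing.assert_frame_equal(
            a.sort_values(key).reset_index(drop=True),
            b.sort_values(key).reset_index(drop=True))

    def test_fifteen_percent_genotype_effect_recovered(self):
        """A genotype whose expansion mean is 15% lower shows a mean index
        ratio of about 0.85 over 20 simulated mice."""
        tables, _ = make_cohort({"A": 10.0, "B": 8.5}, 20, NoiseModel(seed=7))
        cohort = cohort_expansion(tables, InstabilityConfig())
        striatum = cohort[cohort["tissue"] == "striatum"]
        means = striatum.groupby("genotype")["expansion_index"].mean()
        assert means["B"] / means["A"] == pytest.approx(0.85, abs=0.04)


class TestCompareGroups:
    def cohort_frame(self, shift=0.0, n=6, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for genotype, delta in (("A", 0.0), ("B", shift)):
            for i in range(n):
                rows.append({"mouse": f"{genotype}{i}", "genotype": genotype,
                             "age_months": 6.0, "tissue": "striatum",
                             "expansion_index": 5.0 + delta + rng.normal(0, 0.5)})
        return pd.DataFrame(rows)

    def test_identical_groups_give_f_near_zero(self):
        frame = self.cohort_frame()
        values = frame[frame["genotype"] == "A"]["expansion_index"].to_numpy()
        frame.loc[frame["genotype"] == "B", "expansion_index"] = values
        out = compare_groups(frame)
        assert out["F"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert out["p_tukey"].iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_two_group_f_equals_t_squared(self):
        frame = self.cohort_frame(shift=1.0, seed=3)
        out = compare_groups(frame)
        a = frame[frame["genotype"] == "A"]["expansion_index"]
        b = frame[frame["genotype"] == "B"]["expansion_index"]
        t_stat, _ = stats.ttest_ind(a, b)
        assert out["F"].iloc[0] == pytest.approx(t_stat ** 2, rel=1e-9)

    def test_singleton_group_skips_stratum_with_warning(self):
        frame = self.cohort_frame().iloc[:7]  # B has a single observation
        with pytest.warns(UserWarning, match="skipped"):
            out = compare_groups(frame)
        assert out.empty

    def test_tier_thresholds(self):
        assert significance_tier(0.2) == "ns"
        assert significance_tier(0.03) == "*"
        assert significance_tier(0.005) == "**"
        assert significance_tier(0.0005) == "***"
        assert significance_tier(0.00005) == "****"
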