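"""Dispersion, sharp/broad classification, tau, grouped expression, directionality."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from promenh import (
    classify_sharpness,
    compare_groups,
    directionality,
    dispersion_index,
    group_expression,
    select_top_groups,
    tau,
)
from promenh.cage import dispersion_table, directionality_table, tau_table


def tags_df(rows):
    return pd.DataFrame(rows, columns=["element_id", "library_id", "strand",
                                       "rel_position", "count"])


class TestDispersionIndex:
    def test_point_mass_is_zero(self):
        assert dispersion_index([7], [100]) == 0.0

    def test_two_point_extremes(self):
        assert dispersion_index([-50, 50], [1, 1]) == pytest.approx(50.0)

    def test_discrete_uniform(self):
        j = np.arange(-50, 51)
        assert dispersion_index(j, np.ones(101)) == pytest.approx(math.sqrt(850))

    def test_no_tags_undefined(self):
        with pytest.raises(ValueError):
            dispersion_index([0, 1], [0, 0])

    def test_translation_with_window_recentering(self, rng):
        """Shifting all positions by a constant leaves s unchanged exactly."""
        pos = rng.integers(-50, 51, size=30)
        cnt = rng.integers(1, 20, size=30)
        assert dispersion_index(pos, cnt) == pytest.approx(
            dispersion_index(pos + 17, cnt), abs=1e-9
        )


class TestClassifySharpness:
    def test_mean_below_threshold_is_sharp(self):
        res = classify_sharpness({"l1": 0.0, "l2": 0.0, "l3": 5.0})
        assert res.mean_dispersion == pytest.approx(5 / 3)
        assert res.label == "sharp"

    def test_no_informative_libraries_unclassified(self):
        assert classify_sharpness({}).label == "unclassified"

    def test_threshold_is_inclusive(self):
        assert classify_sharpness({"l1": 2.5}).label == "sharp"
        assert classify_sharpness({"l1": 2.5000001}).label == "broad"

    def test_table_uses_sense_strand_window(self):
        tags = tags_df([
            ("e1", "l1", "+", 0, 50),          # sharp signal
            ("e1", "l1", "+", 200, 99),        # outside [-50, 50]: ignored
            ("e1", "l1", "-", -40, 99),        # antisense: ignored
            ("e2", "l1", "-", 0, 10),          # only antisense tags
        ])
        table = dispersion_table(tags).set_index("element_id")
        assert table.loc["e1", "label"] == "sharp"
        assert table.loc["e2", "label"] == "unclassified"


class TestGroupExpression:
    LIB_MAP = pd.DataFrame({
        "library_id": ["l1", "l2"],
        "group": ["g1", "g2"],
        "class": ["tissue", "tissue"],
    })

    def test_windowed_tpm_arithmetic(self):
        # l1 total 1000 tags; 7 in window -> TPM 7000 -> log2(1 + 1000*7000)
        tags = tags_df([
            ("e1", "l1", "+", 0, 7),
            ("e2", "l1", "+", 500, 993),  # outside window, pads library total
        ])
        expr = group_expression(tags, self.LIB_MAP.iloc[:1])
        assert expr.loc["e1", "g1"] == pytest.approx(math.log2(1 + 1000 * 7000.0))

    def test_zero_expression_group_is_zero(self):
        tags = tags_df([("e1", "l1", "+", 0, 5)])
        expr = group_expression(tags, self.LIB_MAP)
        assert expr.loc["e1", "g2"] == 0.0

    def test_tags_outside_window_contribute_nothing(self):
        tags = tags_df([("e1", "l1", "+", 150, 5), ("e2", "l1", "+", 0, 5)])
        expr = group_expression(tags, self.LIB_MAP)
        assert expr.loc["e1", "g1"] == 0.0


class TestTau:
    def test_perfectly_specific(self):
        assert tau([1, 0, 0, 0]).tau == pytest.approx(1.0)

    def test_housekeeping(self):
        assert tau([3.5, 3.5, 3.5, 3.5]).tau == pytest.approx(0.0)

    def test_graded_profile(self):
        res = tau([8, 4, 2, 1])
        assert res.tau == pytest.approx(17 / 24)

    def test_all_zero_flagged(self):
        res = tau([0.0, 0.0, 0.0])
        assert not res.defined and math.isnan(res.tau)

    def test_needs_two_groups(self):
        with pytest.raises(ValueError):
            tau([1.0])

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.0, 100.0), min_size=2, max_size=10).filter(
            lambda x: max(x) > 0
        ),
        st.floats(0.01, 50.0),
    )
    def test_scale_invariance(self, x, lam):
        assert tau(np.array(x) * lam).tau == pytest.approx(tau(x).tau, abs=1e-9)

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.5, 100.0), min_size=3, max_size=8))
    def test_concentration_monotonicity(self, x):
        """Moving mass from a non-maximal group to the maximal one never lowers tau."""
        x = np.array(x)
        i_max = int(np.argmax(x))
        i_other = (i_max + 1) % len(x)
        moved = x.copy()
        delta = moved[i_other] / 2
        moved[i_other] -= delta
        moved[i_max] += delta
        assert tau(moved).tau >= tau(x).tau - 1e-9


class TestTopGroups:
    def test_selection_and_ties(self):
        expr = pd.DataFrame({"gb": [5.0, 5.0], "ga": [5.0, 5.0], "gc": [0.5, 0.5]},
                            index=["e1", "e2"])
        assert select_top_groups(expr, n_top=2) == ["ga", "gb"]  # tie -> lexicographic
        assert select_top_groups(expr, n_top=10) == ["ga", "gb", "gc"]


class TestDirectionality:
    def test_balanced(self):
        tags = tags_df([("e1", "l1", "+", 10, 10), ("e1", "l1", "-", -10, 10)])
        assert directionality(tags).directionality == pytest.approx(0.0)

    def test_unidirectional_bound(self):
        tags = tags_df([("e1", "l1", "+", 10, 25)])
        assert directionality(tags).directionality == pytest.approx(1.0)

    def test_arithmetic(self):
        tags = tags_df([("e1", "l1", "+", 50, 30), ("e1", "l1", "-", -50, 10)])
        assert directionality(tags).directionality == pytest.approx(0.5)

    def test_window_boundaries(self):
        # midpoint tag counts as forward; tags beyond +/-200 are excluded
        tags = tags_df([
            ("e1", "l1", "+", 0, 1),
            ("e1", "l1", "+", 200, 1),
            ("e1", "l1", "+", 201, 99),
            ("e1", "l1", "-", -200, 1),
            ("e1", "l1", "-", -201, 99),
            ("e1", "l1", "-", 0, 99),  # reverse tag at midpoint not in [-200, 0)
        ])
        res = directionality(tags)
        assert (res.forward, res.reverse) == (2, 1)

    def test_no_tags_undefined(self):
        res = directionality(tags_df([("e1", "l1", "+", 500, 3)]))
        assert not res.defined and math.isnan(res.directionality)

    def test_antisymmetry_under_strand_mirror(self, rng):
        """Mirroring every tag to the other strand flips the sign exactly,
        and |directionality| never exceeds 1."""
        for _ in range(20):
            n = int(rng.integers(1, 8))
            rows = []
            for _ in range(n):
                strand = "+" if rng.random() < 0.5 else "-"
                pos = int(rng.integers(0, 200)) if strand == "+" else int(rng.integers(-200, 0))
                rows.append(("e1", "l1", strand, pos, int(rng.integers(1, 30))))
            # mirror (strand, p) -> (other strand, -(p+1)) maps the forward
            # window [0, 199] onto the reverse window [-200, -1] and back
            mirrored = [("e1", "l1", "-" if s == "+" else "+", -(p + 1), c)
                        for (_, _, s, p, c) in rows]
            fwd = directionality(tags_df(rows))
            rev = directionality(tags_df(mirrored))
            assert fwd.defined and rev.defined
            assert rev.directionality == pytest.approx(-fwd.directionality)
            assert abs(fwd.directionality) <= 1.0


class TestRecovery:
    def test_sharp_and_broad_profiles_classify_correctly(self, rng):
        """Spiked profiles classify sharp, Normal(0, 20) profiles broad,
        >= 95% each at 200 tags per library."""
        rows = []
        for i in range(100):
            sharp = i < 50
            for lib in ("l1", "l2"):
                n = 200
                pos = (rng.integers(-1, 2, size=n) if sharp
                       else np.clip(np.round(rng.normal(0, 20, size=n)), -50, 50).astype(int))
                for p, c in zip(*np.unique(pos, return_counts=True)):
                    rows.append((f"e{i:03d}", lib, "+", int(p), int(c)))
        table = dispersion_table(tags_df(rows)).set_index("element_id")
        sharp_ok = sum(table.loc[f"e{i:03d}", "label"] == "sharp" for i in range(50))
        broad_ok = sum(table.loc[f"e{i:03d}", "label"] == "broad" for i in range(50, 100))
        assert sharp_ok >= 48 and broad_ok >= 48
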