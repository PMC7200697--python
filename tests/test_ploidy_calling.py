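"""Ploidy windows, normalization, composition calculus and group comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ploidyscope import ploidy_calling as pc
from conftest import make_cell_table


class TestPloidyWindows:
    @pytest.mark.parametrize(
        "value, expected",
        [
            (1.0, "2n"),
            (2.0, "4n"),
            (3.5, "8n"),
            (2.7, "unassigned"),  # the undefined (2.5, 3] gap
            (0.4, "unassigned"),  # sub-diploid debris
            (1.5, "4n"),  # closed-left boundary
            (2.5, "unassigned"),  # open-right boundary of the 4n window
            (0.5, "2n"),
            (3.0, "unassigned"),  # octoploid window is strictly > 3
        ],
    )
    def test_window_assignment(self, value, expected):
        assert pc.DEFAULT_BINS.classify([value])[0] == expected

    def test_negative_value_names_nucleus(self):
        with pytest.raises(ValueError, match="nuc7"):
            pc.call_nuclear_ploidy([1.0, -0.2], nucleus_ids=["nuc3", "nuc7"])

    def test_windows_cover_all_nonnegative_values(self):
        values = np.linspace(0, 10, 2001)
        classes = pc.DEFAULT_BINS.classify(values)
        assert set(classes) <= {"2n", "4n", "8n", "unassigned"}


class TestNormalization:
    def test_reference_median_is_one(self):
        ref = np.full(20, 500.0)
        out = pc.normalize_intensities([500.0, 1000.0], ref)
        np.testing.assert_allclose(out, [1.0, 2.0])

    def test_median_oracle(self):
        """Reference {9, 10, 11, 100}: median 10.5, so 21 a.u. -> 2.0."""
        out = pc.normalize_intensities([21.0], [9, 10, 11, 100], min_reference=4)
        assert out[0] == pytest.approx(2.0)

    def test_too_few_references_refused(self):
        with pytest.raises(pc.NormalizationError, match="reference"):
            pc.normalize_intensities([1.0], [1.0] * 9, min_reference=10)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(1e-3, 1e3), seed=st.integers(0, 1000))
    def test_global_rescaling_changes_no_call(self, scale, seed):
        rng = np.random.default_rng(seed)
        raw = rng.uniform(10, 400, 200)
        ref = rng.uniform(40, 60, 30)
        base = pc.DEFAULT_BINS.classify(pc.normalize_intensities(raw, ref))
        scaled = pc.DEFAULT_BINS.classify(
            pc.normalize_intensities(raw * scale, ref * scale)
        )
        assert (base == scaled).all()


class TestCompositionCalculus:
    @pytest.mark.parametrize(
        "mono, p2n, expected",
        [
            (6.6, 66.7, 4.4),  # BALB/cJ-like cardiomyocytes
            (14.3, 37.6, 5.4),  # BALB/cByJ-like cardiomyocytes
            (13.1, 69.9, 9.2),  # F1 males from high-strain mothers
            (42.6, 26.8, 11.4),  # BALB/cByJ-like hepatocytes
        ],
    )
    def test_diploid_cell_product(self, mono, p2n, expected):
        assert round(pc.diploid_cell_percentage(mono, p2n), 1) == expected

    def test_summarize_sample_product(self):
        """1000 cells, 66 mononuclear of which 44 diploid -> 6.6% mono,
        66.7% mono-2n, 4.4% diploid cells."""
        cells, calls = make_cell_table(
            [(44, 1, "2n"), (22, 1, "4n"), (934, 2, "2n")]
        )
        comp = pc.summarize_sample(cells, calls, "cardiomyocyte")
        assert comp.n_cells_counted == 1000
        assert comp.mononuclear_fraction == pytest.approx(6.6)
        assert comp.mono_pct2n == pytest.approx(100 * 44 / 66)
        assert round(comp.diploid_cell_fraction, 1) == 4.4
        assert comp.binuclear_fraction == pytest.approx(93.4)

    def test_all_binuclear_diploid(self):
        cells, calls = make_cell_table([(400, 2, "2n")])
        comp = pc.summarize_sample(cells, calls, "cardiomyocyte")
        assert comp.mononuclear_fraction == 0.0
        assert comp.diploid_cell_fraction == 0.0
        assert comp.cell_class_distribution["2x2n"] == pytest.approx(100.0)

    def test_subgroup_distributions_conserve_mass(self):
        cells, calls = make_cell_table(
            [(50, 1, "2n"), (20, 1, "4n"), (10, 1, "unassigned"),
             (200, 2, "2n"), (40, 2, "8n"), (30, 2, "unassigned")]
        )
        comp = pc.summarize_sample(cells, calls, "cardiomyocyte")
        assert sum(comp.mono_dist.values()) == pytest.approx(100.0, abs=1e-9)
        assert sum(comp.bi_dist.values()) == pytest.approx(100.0, abs=1e-9)
        # cells with unassigned nuclei are the remainder of the cell classes
        assert sum(comp.cell_class_distribution.values()) == pytest.approx(
            100.0 * (350 - 40) / 350
        )

    def test_multinucleate_cells_flagged_and_excluded(self):
        cells, calls = make_cell_table([(90, 1, "2n"), (210, 2, "2n")])
        extra = pd.DataFrame(
            [
                dict(cell_id=9999, cell_type="cardiomyocyte",
                     nucleus_ids=(100000, 100001, 100002), n_nuclei=3,
                     viable=True, qc="multi")
            ]
        )
        cells = pd.concat([cells, extra], ignore_index=True)
        with pytest.warns(UserWarning, match="flagged"):
            comp = pc.summarize_sample(cells, calls, "cardiomyocyte", min_cells=301)
        assert comp.n_cells_counted == 300
        assert comp.n_multi_excluded == 1
        assert comp.below_min_cells
        assert comp.mononuclear_fraction == pytest.approx(30.0)

    def test_viability_filter(self):
        cells, calls = make_cell_table([(100, 1, "2n")])
        cells.loc[:49, "viable"] = False
        comp = pc.summarize_sample(cells, calls, "cardiomyocyte", min_cells=0)
        assert comp.n_cells_counted == 50


class TestCombineSubgroups:
    def test_trivial_all_diploid(self):
        out = pc.combine_subgroups(
            {"2n": 100.0, "4n": 0.0, "8n": 0.0},
            {"2n": 100.0, "4n": 0.0, "8n": 0.0},
            10.0,
            90.0,
        )
        assert out["1x2n"] == pytest.approx(10.0)
        assert out["2x2n"] == pytest.approx(90.0)
        assert sum(out.values()) == pytest.approx(100.0)

    def test_printed_product(self):
        out = pc.combine_subgroups(
            {"2n": 66.7, "4n": 30.0, "8n": 3.3},
            {"2n": 90.0, "4n": 9.0, "8n": 1.0},
            6.6,
            93.4,
        )
        assert round(out["1x2n"], 1) == 4.4

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_matches_brute_force_expansion(self, data):
        """Random valid inputs equal the direct 6-term expansion."""
        def dist(label):
            # two sorted cut points partition 100% into three nonneg shares
            cuts = sorted(
                data.draw(
                    st.lists(st.floats(0.0, 100.0), min_size=2, max_size=2),
                    label=label,
                )
            )
            vals = [cuts[0], cuts[1] - cuts[0], 100.0 - cuts[1]]
            return dict(zip(("2n", "4n", "8n"), vals))

        mono_dist, bi_dist = dist("mono"), dist("bi")
        mono_frac = data.draw(st.floats(0.0, 100.0), label="mono_frac")
        out = pc.combine_subgroups(mono_dist, bi_dist, mono_frac, 100.0 - mono_frac)
        expected = {}
        for k in ("2n", "4n", "8n"):
            expected[f"1x{k}"] = mono_frac * mono_dist[k] / 100.0
            expected[f"2x{k}"] = (100.0 - mono_frac) * bi_dist[k] / 100.0
        for key, val in expected.items():
            assert out[key] == pytest.approx(val, abs=1e-9)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            pc.combine_subgroups(
                {"2n": 110.0, "4n": -10.0, "8n": 0.0},
                {"2n": 100.0, "4n": 0.0, "8n": 0.0},
                50.0,
                50.0,
            )


class TestCompareGroups:
    def test_identical_groups(self):
        res = pc.compare_groups([1, 2, 3], [1, 2, 3])
        assert res.t == 0.0
        assert res.p == 1.0
        assert res.df == 4

    def test_hand_computed_t(self):
        """A={4,5,6} vs B={1,2,3}: pooled-variance t = 3/sqrt(2/3) = 3.674."""
        res = pc.compare_groups([4, 5, 6], [1, 2, 3])
        assert res.t == pytest.approx(3.674, abs=1e-3)
        assert res.df == 4

    def test_matches_scipy(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 6)
        res = pc.compare_groups(a, b)
        t_ref, p_ref = stats.ttest_ind(a, b, equal_var=True)
        assert res.t == pytest.approx(float(t_ref))
        assert res.p == pytest.approx(float(p_ref))

    def test_degenerate_zero_variance_unequal_means(self):
        res = pc.compare_groups([2.0, 2.0], [1.0, 1.0])
        assert res.degenerate
        assert res.p == 0.0
        assert np.isinf(res.t)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            pc.compare_groups([1.0], [1.0, 2.0])
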