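import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import newsecm as ne

from conftest import make_table


def two_sample_table(totals=(100.0, 200.0)):
    a, b = totals
    return make_table(
        [[a * 0.4, b * 0.1], [a * 0.6, b * 0.9]],
        {"s1": ("m", "labeled", "eluate", 1), "s2": ("m", "labeled", "eluate", 2)},
    )


class TestTotalIntensityNormalize:
    def test_two_samples_scale_to_group_average(self):
        table = two_sample_table((100, 200))
        out = ne.total_intensity_normalize(table, ne.NormalizationScheme.across_selected())
        totals = out.sample_totals()
        assert totals.tolist() == pytest.approx([150.0, 150.0])
        # scale factors 150/100 = 1.5 and 150/200 = 0.75
        assert out.intensities["s1"].tolist() == pytest.approx([60.0, 90.0])
        assert out.intensities["s2"].tolist() == pytest.approx([15.0, 135.0])

    def test_single_sample_group_is_identity(self):
        table = make_table([[3.0], [7.0]], {"s1": ("m", "labeled", "eluate", 1)})
        out = ne.total_intensity_normalize(table, ne.NormalizationScheme.across_selected())
        pd.testing.assert_frame_equal(out.intensities, table.intensities)

    def test_four_group_layout_normalizes_within_groups(self):
        # hand computation on a toy table: within each (model, treatment)
        # group post-totals equal the group average; groups keep distinct totals
        meta = {
            "a1": ("m1", "labeled", "eluate", 1),
            "a2": ("m1", "labeled", "eluate", 2),
            "b1": ("m1", "vehicle", "eluate", 1),
            "b2": ("m1", "vehicle", "eluate", 2),
            "c1": ("m2", "labeled", "eluate", 1),
            "c2": ("m2", "labeled", "eluate", 2),
            "d1": ("m2", "vehicle", "eluate", 1),
            "d2": ("m2", "vehicle", "eluate", 2),
        }
        values = np.array(
            [
                [10, 30, 1, 3, 100, 300, 5, 15],
                [10, 10, 1, 1, 100, 100, 5, 5],
                [20, 40, 2, 4, 200, 400, 10, 20],
                [0, 0, 0, 0, 0, 0, 0, 0],
                [60, 20, 6, 2, 600, 200, 30, 10],
            ],
            dtype=float,
        )
        table = make_table(values, meta)
        out = ne.total_intensity_normalize(
            table, ne.NormalizationScheme.within_treatment_groups()
        )
        totals = out.sample_totals()
        assert totals["a1"] == pytest.approx(totals["a2"]) == pytest.approx(100.0)
        assert totals["b1"] == pytest.approx(totals["b2"]) == pytest.approx(10.0)
        assert totals["c1"] == pytest.approx(totals["c2"]) == pytest.approx(1000.0)
        assert totals["d1"] == pytest.approx(totals["d2"]) == pytest.approx(50.0)
        # zeros stay zero
        assert (out.intensities.iloc[3] == 0).all()

    def test_zero_total_sample_is_named(self):
        table = make_table(
            [[0.0, 1.0]], {"s1": ("m", "labeled", "eluate", 1), "s2": ("m", "labeled", "eluate", 2)}
        )
        with pytest.raises(ValueError, match="s1"):
            ne.total_intensity_normalize(table, ne.NormalizationScheme.across_selected())

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        data=st.lists(
            st.lists(st.floats(0.001, 1e6, allow_nan=False), min_size=2, max_size=4),
            min_size=2,
            max_size=6,
        ),
        scale=st.floats(0.01, 100.0),
    )
    def test_conservation_idempotence_equivariance(self, data, scale):
        arr = np.array([row[:2] + [1.0] for row in data], dtype=float)
        table = make_table(
            arr,
            {"s1": ("m", "labeled", "eluate", 1), "s2": ("m", "labeled", "eluate", 2),
             "s3": ("m", "labeled", "eluate", 3)},
        )
        scheme = ne.NormalizationScheme.across_selected()
        pre_totals = table.sample_totals()
        out = ne.total_intensity_normalize(table, scheme)
        # conservation: every post-total equals the pre-normalization mean
        assert np.allclose(out.sample_totals(), pre_totals.mean(), rtol=1e-9)
        # idempotence
        again = ne.total_intensity_normalize(out, scheme)
        assert np.allclose(again.intensities, out.intensities, rtol=1e-9)
        # scale equivariance: rescaling one sample changes nothing post-normalization
        scaled = table.intensities.copy()
        scaled["s2"] = scaled["s2"] * scale
        out2 = ne.total_intensity_normalize(table.with_intensities(scaled), scheme)
        ratio = out2.sample_totals() / out.sample_totals()
        assert np.allclose(out2.intensities["s2"] / ratio["s2"], out.intensities["s2"], rtol=1e-9)


class TestPrefilter:
    def table(self):
        values = np.array(
            [
                [1, 2, 3, 0, 0, 0],  # 3 nonzero | 0 nonzero -> qualitative
                [1, 2, 3, 4, 5, 6],  # all nonzero -> testable
                [1, 0, 0, 4, 5, 6],  # 1 | 3 -> qualitative
                [1, 2, 0, 4, 5, 0],  # 2 | 2 -> testable
            ],
            dtype=float,
        )
        meta = {f"a{i}": ("m", "labeled", "eluate", i) for i in range(1, 4)}
        meta.update({f"b{i}": ("m", "vehicle", "eluate", i) for i in range(1, 4)})
        return make_table(values, meta)

    def test_detection_split(self):
        table = self.table()
        testable, qualitative = ne.prefilter_min_nonzero(
            table, ["a1", "a2", "a3"], ["b1", "b2", "b3"], k=2
        )
        assert list(testable.intensities.index) == ["P001_HUMAN", "P003_HUMAN"]
        assert list(qualitative.intensities.index) == ["P000_HUMAN", "P002_HUMAN"]

    def test_partition_is_exact(self):
        table = self.table()
        testable, qualitative = ne.prefilter_min_nonzero(
            table, ["a1", "a2", "a3"], ["b1", "b2", "b3"], k=2
        )
        union = set(testable.intensities.index) | set(qualitative.intensities.index)
        inter = set(testable.intensities.index) & set(qualitative.intensities.index)
        assert union == set(table.intensities.index)
        assert not inter

    def test_k_zero_keeps_everything_testable(self):
        table = self.table()
        testable, qualitative = ne.prefilter_min_nonzero(
            table, ["a1", "a2", "a3"], ["b1", "b2", "b3"], k=0
        )
        assert qualitative.n_proteins == 0
        assert testable.n_proteins == table.n_proteins

    def test_too_small_group_rejected(self):
        table = self.table()
        with pytest.raises(ValueError, match="fewer than k"):
            ne.prefilter_min_nonzero(table, ["a1"], ["b1", "b2"], k=2)


class TestGrubbs:
    def test_constant_vector_has_no_outlier(self):
        assert ne.grubbs_outliers([5.0, 5.0, 5.0, 5.0]) == []

    def test_clear_outlier_flagged(self):
        # closed-form check: G = |10 - 3.25| / sd compared to the t-based
        # critical value at alpha = 0.05, n = 4
        x = [1.0, 1.0, 1.0, 10.0]
        g = abs(10 - np.mean(x)) / np.std(x, ddof=1)
        assert g > ne.grubbs_critical_value(4, 0.05)
        assert ne.grubbs_outliers(x) == [3]

    def test_at_most_one_flag_per_pass_and_tie_breaks_low_index(self):
        # symmetric extremes inflate the sd enough that the default level
        # rejects nothing; at a permissive level exactly one of the tied
        # extremes is flagged per pass, and the lower index wins
        x = [-10.0, 0.0, 0.1, -0.1, 10.0]
        assert ne.grubbs_outliers(x, alpha=0.05) == []
        flagged = ne.grubbs_outliers(x, alpha=0.9, iterate=False)
        assert flagged == [0]

    def test_iterate_removes_sequentially(self):
        # one gross and one moderate outlier on the same side: the moderate
        # one is masked in the first pass and only falls in the second
        x = [1.0, 1.1, 0.9, 1.0, 1.2, 10.0, 4.0]
        assert ne.grubbs_outliers(x, iterate=False) == [5]
        assert ne.grubbs_outliers(x, iterate=True) == [5, 6]

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ne.grubbs_outliers([1.0, 2.0])

    def test_type_i_error_at_most_alpha_plus_tolerance(self):
        rng = np.random.default_rng(42)
        n_sim = 10_000
        flags = sum(
            bool(ne.grubbs_outliers(rng.normal(size=8), alpha=0.05))
            for _ in range(n_sim)
        )
        rate = flags / n_sim
        mc_tol = 3 * np.sqrt(0.05 * 0.95 / n_sim)
        assert rate <= 0.05 + mc_tol
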