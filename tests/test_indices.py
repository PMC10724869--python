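"""Asymmetry indices: analytic examples, oracle equivalence, invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats

from asymkit import (
    compute_index_tables,
    distance_index,
    laterality_index,
    subtraction_index,
)
from asymkit.simulate import TOY4_LEFT, TOY4_RIGHT


def brute_force_di(left, right, mode="all"):
    """Independent reference: explicit loops + textbook Pearson correlation."""
    n = len(left)
    out = np.full(n, np.nan)
    for i in range(n):
        js = [j for j in range(n) if j != i] if mode == "all" else list(range(i + 1, n))
        if len(js) < 3:
            continue
        vl = [abs(left[i] - left[j]) for j in js]
        vr = [abs(right[i] - right[j]) for j in js]
        if np.std(vl) == 0 or np.std(vr) == 0:
            continue
        r, _ = stats.pearsonr(vl, vr)
        out[i] = 1 - abs(r)
    return out


finite_vectors = hnp.arrays(
    np.float64, 34, elements=st.floats(0.5, 1e4, allow_nan=False)
)


class TestDistanceIndex:
    def test_mirror_hemispheres_give_zero(self, rng):
        left = rng.uniform(1, 100, 34)
        assert distance_index(left, left).max() == 0.0

    @pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
    def test_proportional_hemispheres_give_zero(self, rng, c):
        left = rng.uniform(1, 100, 34)
        np.testing.assert_allclose(distance_index(left, c * left), 0, atol=1e-12)

    def test_toy4_matches_hand_computed_pearson(self):
        left, right = np.array(TOY4_LEFT), np.array(TOY4_RIGHT)
        di = distance_index(left, right)
        # ROI 1: V_L=(1,3,7), V_R=(1,3,6) -> r = 15.333/sqrt(18.667*12.667)
        r = 46 / 3 / np.sqrt((56 / 3) * (38 / 3))
        assert di[0] == pytest.approx(1 - r, abs=1e-12)
        assert di[0] == pytest.approx(0.0029, abs=2e-4)
        np.testing.assert_allclose(di, brute_force_di(left, right), atol=1e-12)

    def test_zero_variance_vector_flagged_missing(self):
        # a constant hemisphere makes every difference vector zero-variance
        right = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        assert np.isnan(distance_index(np.ones(5), right)).all()

    def test_too_few_rois_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            distance_index(np.ones(3), np.ones(3))

    def test_non_finite_input_rejected(self):
        bad = np.r_[np.nan, np.ones(33)]
        with pytest.raises(ValueError, match="finite"):
            distance_index(bad, np.ones(34))

    def test_upper_mode_matches_bruteforce_and_flags_short_vectors(self, rng):
        left = rng.uniform(1, 100, 34)
        right = left * (1 + rng.normal(0, 0.05, 34))
        di = distance_index(left, right, mode="upper")
        ref = brute_force_di(left, right, mode="upper")
        np.testing.assert_allclose(di, ref, atol=1e-12)
        assert np.isnan(di[-3:]).all()  # vectors of length < 3

    @settings(deadline=None, max_examples=25)
    @given(left=finite_vectors, right=finite_vectors)
    def test_bounds_hold_for_arbitrary_inputs(self, left, right):
        di = distance_index(left, right)
        defined = di[np.isfinite(di)]
        assert ((defined >= 0) & (defined <= 1)).all()


class TestPairwiseIndices:
    def test_laterality_arithmetic(self):
        assert laterality_index(np.full(4, 10.0), np.full(4, 8.0))[0] == pytest.approx(1 / 9)
        assert laterality_index(np.ones(4), np.ones(4)).max() == 0.0

    def test_mixed_sign_curvature_exceeds_one(self):
        li = laterality_index(np.array([0.2]), np.array([-0.1]))
        assert li[0] == pytest.approx(3.0)

    def test_zero_denominator_flagged_missing(self):
        li = laterality_index(np.array([0.1, -0.1]), np.array([0.2, 0.1]))
        assert np.isnan(li[1]) and np.isfinite(li[0])

    def test_subtraction_arithmetic(self):
        si = subtraction_index(np.full(4, 10.0), np.full(4, 8.0))
        np.testing.assert_allclose(si, 2.0)

    @settings(deadline=None, max_examples=25)
    @given(left=finite_vectors, right=finite_vectors,
           c=st.floats(0.1, 50, allow_nan=False))
    def test_common_rescaling_moves_si_only(self, left, right, c):
        """DI and LI are scale invariant; SI scales by the common factor."""
        np.testing.assert_allclose(
            distance_index(c * left, c * right), distance_index(left, right),
            atol=1e-9, rtol=1e-6,
        )
        np.testing.assert_allclose(
            laterality_index(c * left, c * right), laterality_index(left, right),
            atol=1e-12, rtol=1e-9,
        )
        np.testing.assert_allclose(
            subtraction_index(c * left, c * right), c * subtraction_index(left, right),
            rtol=1e-9, atol=1e-9,
        )

    def test_proportionality_blindness_separates_di_from_si(self, rng):
        """right = c*left keeps DI at 0 while SI sees the size difference."""
        left = rng.uniform(10, 1000, 34)
        right = 1.3 * left
        assert distance_index(left, right).max() == pytest.approx(0, abs=1e-12)
        assert (subtraction_index(left, right) > 0).all()


class TestIndexTables:
    def test_mirror_cohort_all_tables_zero(self):
        from asymkit.io import MorphometryTable

        values = pd.DataFrame(
            np.random.default_rng(0).uniform(1, 100, (2, 34)),
            index=["a", "b"], columns=list(__import__("asymkit").APARC_ROIS),
        )
        morph = MorphometryTable("volume", values, values.copy())
        tables = compute_index_tables(morph)
        for table in tables.values():
            assert table.values.to_numpy().max() == 0.0

    def test_di_table_matches_elementwise_bruteforce(self, small_cohort):
        morph = small_cohort.morphometry["volume"]
        table = compute_index_tables(morph, kinds=("DI",))["DI"]
        for subject in list(morph.subjects[:5]):
            ref = brute_force_di(
                morph.left.loc[subject].to_numpy(), morph.right.loc[subject].to_numpy()
            )
            np.testing.assert_allclose(table.values.loc[subject].to_numpy(), ref,
                                       atol=1e-12)

    def test_subject_permutation_permutes_rows_only(self, small_cohort):
        from asymkit.io import MorphometryTable

        morph = small_cohort.morphometry["area"]
        perm = list(morph.subjects[::-1])
        permuted = MorphometryTable(
            "area", morph.left.loc[perm], morph.right.loc[perm]
        )
        t0 = compute_index_tables(morph, kinds=("LI",))["LI"].values
        t1 = compute_index_tables(permuted, kinds=("LI",))["LI"].values
        pd.testing.assert_frame_equal(t0.loc[perm], t1)

    def test_qc_counts_li_above_one(self):
        from asymkit.io import MorphometryTable

        left = np.full((1, 34), 0.2)
        right = np.full((1, 34), 0.15)
        right[0, 0] = -0.1  # sign mix -> LI > 1 at ROI 0
        cols = list(__import__("asymkit").APARC_ROIS)
        morph = MorphometryTable(
            "meancurv",
            pd.DataFrame(left, index=["s"], columns=cols),
            pd.DataFrame(right, index=["s"], columns=cols),
        )
        table = compute_index_tables(morph, kinds=("LI",))["LI"]
        assert table.qc["n_above_one"] == 1

    def test_unknown_kind_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="unknown index kind"):
            compute_index_tables(small_cohort.morphometry["volume"], kinds=("XX",))
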