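import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zratio import ExpressionMatrix, ZScoreMatrix, p_from_z, zratio, zscore_per_sample
from zratio.zratio_core import ZeroVarianceError

from _oracles import normal_two_tailed_p, sample_sd, zratios, zscores_per_sample


def _matrix(values, scale="log2"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"g{i}" for i in range(values.shape[0])],
            columns=[f"s{j}" for j in range(values.shape[1])],
        ),
        scale_tag=scale,
    )


def _zmat(diffs_or_cols, sample_prefix="a"):
    """Build a ZScoreMatrix directly from a gene x sample array."""
    arr = np.atleast_2d(np.asarray(diffs_or_cols, dtype=float)).T
    return ZScoreMatrix(
        pd.DataFrame(
            arr,
            index=[f"g{i}" for i in range(arr.shape[0])],
            columns=[f"{sample_prefix}{j}" for j in range(arr.shape[1])],
        )
    )


class TestZScorePerSample:
    def test_symmetric_three_point_column(self):
        z = zscore_per_sample(_matrix([[6.0], [8.0], [10.0]]))
        np.testing.assert_allclose(z.z["s0"].to_numpy(), [-1.0, 0.0, 1.0])

    def test_constant_column_raises_naming_sample(self):
        with pytest.raises(ZeroVarianceError, match="s0"):
            zscore_per_sample(_matrix([[5.0], [5.0], [5.0]]))

    def test_clip_noop_when_raw_z_within_bound(self):
        # one 0 among nine 10s: raw z of the outlier is -9/sqrt(10) = -2.846,
        # inside [-3, 3], so clipping must not change anything
        col = [[0.0]] + [[10.0]] * 9
        raw = zscore_per_sample(_matrix(col), clip=False)
        clipped = zscore_per_sample(_matrix(col), clip=True)
        assert raw.z["s0"].min() == pytest.approx(-9 / math.sqrt(10), abs=1e-12)
        pd.testing.assert_frame_equal(raw.z, clipped.z)
        assert clipped.clipped and not raw.clipped

    def test_clip_winsorizes_extreme_outlier_to_bound(self):
        # one 0 among nineteen 10s: raw z = -9.5/sqrt(5) = -4.25, clipped to -3
        col = [[0.0]] + [[10.0]] * 19
        raw = zscore_per_sample(_matrix(col), clip=False)
        clipped = zscore_per_sample(_matrix(col), clip=True)
        assert raw.z["s0"].min() < -3.0
        assert clipped.z["s0"].min() == -3.0
        assert clipped.z["s0"].max() <= 3.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_columns_standardized_to_mean_zero_sd_one(self, seed):
        rng = np.random.default_rng(seed)
        z = zscore_per_sample(_matrix(rng.normal(8, 1.5, (15, 4))))
        assert np.all(np.abs(z.z.mean(axis=0)) < 1e-9)
        assert np.all(np.abs(z.z.std(axis=0, ddof=1) - 1) < 1e-9)

    @given(
        st.integers(0, 2**31 - 1),
        st.floats(-5, 5),
        st.floats(0.1, 10),
    )
    @settings(max_examples=25, deadline=None)
    def test_location_scale_invariance(self, seed, shift, scale):
        rng = np.random.default_rng(seed)
        base = rng.normal(8, 1.5, (10, 3))
        transformed = base.copy()
        transformed[:, 0] = base[:, 0] * scale + shift
        z0 = zscore_per_sample(_matrix(base))
        z1 = zscore_per_sample(_matrix(transformed))
        np.testing.assert_allclose(z0.z.to_numpy(), z1.z.to_numpy(), atol=1e-9)

    def test_needs_two_genes(self):
        with pytest.raises(ValueError, match="2 genes"):
            zscore_per_sample(_matrix([[1.0, 2.0]]))


class TestZRatio:
    def test_hand_computed_diffs(self):
        # diffs [0.2, -0.1, 0.5]: deviations {0, -0.3, 0.3}, sample sd 0.3
        out = zratio(_zmat([0.2, -0.1, 0.5]), _zmat([0.0, 0.0, 0.0], "b"))
        np.testing.assert_allclose(
            out["z_ratio"].to_numpy(), [2 / 3, -1 / 3, 5 / 3], atol=5e-10
        )

    def test_equal_group_means_give_zero(self):
        out = zratio(_zmat([0.4, 0.4, 0.9]), _zmat([0.4, 0.1, 0.2], "b"))
        assert out.loc["g0", "z_ratio"] == 0.0
        assert not out.loc["g0", "overexpressed"]

    def test_overexpression_strictly_above_cutoff(self):
        # diffs symmetric around 1.96 with spacing 1 have sample sd exactly 1,
        # so the z_ratios equal the diffs and the middle one sits at the cutoff
        diffs = [0.96, 1.96, 2.96]
        assert sample_sd(diffs) == pytest.approx(1.0, abs=1e-12)
        out = zratio(_zmat(diffs), _zmat([0.0, 0.0, 0.0], "b"))
        np.testing.assert_allclose(out["z_ratio"].to_numpy(), diffs, atol=1e-9)
        assert list(out["overexpressed"]) == [False, False, True]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_antisymmetry_under_group_swap(self, seed):
        rng = np.random.default_rng(seed)
        ds, ctrl = _zmat(rng.normal(0, 1, (8, 3))), _zmat(rng.normal(0, 1, (8, 3)), "b")
        fwd = zratio(ds, ctrl)["z_ratio"].to_numpy()
        rev = zratio(ctrl, ds)["z_ratio"].to_numpy()
        np.testing.assert_array_equal(fwd, -rev)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_transform_invertible_given_sd_of_diffs(self, seed):
        rng = np.random.default_rng(seed)
        ds, ctrl = _zmat(rng.normal(0, 1, (8, 3))), _zmat(rng.normal(0, 1, (8, 3)), "b")
        diffs = (ds.z.mean(axis=1) - ctrl.z.mean(axis=1)).to_numpy()
        sd = np.std(diffs, ddof=1)
        recovered = zratio(ds, ctrl)["z_ratio"].to_numpy() * sd
        np.testing.assert_allclose(recovered, diffs, atol=1e-12)

    def test_identical_diffs_raise(self):
        with pytest.raises(ZeroVarianceError):
            zratio(_zmat([0.3, 0.3, 0.3]), _zmat([0.0, 0.0, 0.0], "b"))

    def test_gene_set_mismatch_raises(self):
        a, b = _zmat([0.1, 0.2]), _zmat([0.1, 0.2, 0.3], "b")
        with pytest.raises(ValueError, match="gene sets"):
            zratio(a, b)

    def test_bh_column_does_not_alter_flags(self):
        rng = np.random.default_rng(3)
        ds, ctrl = _zmat(rng.normal(0, 1, (20, 4))), _zmat(rng.normal(0, 1, (20, 4)), "b")
        plain = zratio(ds, ctrl)
        with_bh = zratio(ds, ctrl, bh_column=True)
        assert "q_bh" in with_bh.columns
        assert list(plain["overexpressed"]) == list(with_bh["overexpressed"])
        assert (with_bh["q_bh"] >= with_bh["p_two_tailed"] - 1e-12).all()


class TestPFromZ:
    def test_zero_gives_one(self):
        assert p_from_z(0.0) == pytest.approx(1.0)

    def test_critical_value(self):
        assert p_from_z(1.96) == pytest.approx(0.05, abs=5e-4)

    @pytest.mark.parametrize("z", [-4.0, -1.3, 0.0, 0.5, 1.96, 3.0, 7.5])
    def test_matches_erfc_oracle(self, z):
        assert p_from_z(z) == pytest.approx(normal_two_tailed_p(z), rel=1e-12)

    def test_non_finite_raises(self):
        with pytest.raises(ValueError):
            p_from_z(float("nan"))


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_zscore_and_zratio_match_literal_reimplementation(self, seed):
        rng = np.random.default_rng(seed)
        ds_rows = rng.normal(8, 1.5, (5, 4))
        ctrl_rows = rng.normal(8, 1.5, (5, 4))
        z = zscore_per_sample(_matrix(ds_rows))
        np.testing.assert_allclose(
            z.z.to_numpy(), np.array(zscores_per_sample(ds_rows.tolist())), atol=1e-9
        )
        out = zratio(
            zscore_per_sample(_matrix(ds_rows)),
            zscore_per_sample(_matrix(ctrl_rows)),
        )
        np.testing.assert_allclose(
            out["z_ratio"].to_numpy(),
            np.array(zratios(ds_rows.tolist(), ctrl_rows.tolist())),
            atol=1e-9,
        )
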