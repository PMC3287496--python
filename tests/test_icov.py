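"""ICOV estimators against independent scalar-loop oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rdpad import (
    add_speckle,
    diamond_window,
    icov,
    icov_dpad,
    icov_rdpad,
    icov_srad,
    q0_schedule,
)
from rdpad.icov import DIAMOND_OFFSETS


# ---------------------------------------------------------------- oracles

def srad_q2_oracle(img, i, j):
    """Scalar re-evaluation of the differential ICOV at one pixel."""
    P = np.pad(img, 1, mode="symmetric")
    I = P[i + 1, j + 1]
    dN = P[i, j + 1] - I
    dS = P[i + 2, j + 1] - I
    dW = P[i + 1, j] - I
    dE = P[i + 1, j + 2] - I
    G2 = (dN**2 + dS**2 + dW**2 + dE**2) / I**2
    L = (dN + dS + dW + dE) / I
    q2 = (0.5 * G2 - L**2 / 16.0) / (1.0 + L / 4.0) ** 2
    return max(q2, 0.0)


def dpad_q2_oracle(window25):
    """25-term brute-force sum: unbiased variance over squared mean."""
    v = np.asarray(window25, dtype=float).ravel()
    assert v.size == 25
    mean = v.sum() / 25.0
    var = sum((x - mean) ** 2 for x in v) / 24.0
    return var / mean**2


def rdpad_q2_oracle(v13):
    """Exhaustive enumeration of all 78 pairwise squared differences."""
    v = np.asarray(v13, dtype=float)
    assert v.size == 13
    num = 0.0
    for m in range(12):
        for n in range(m + 1, 13):
            num += (v[n] - v[m]) ** 2
    return (num / 12.0) / (v**2).sum()


# ------------------------------------------------------------------ tests

@pytest.mark.parametrize("estimator", [icov_srad, icov_dpad, icov_rdpad])
def test_constant_image_gives_zero(estimator):
    field = estimator(np.full((16, 16), 37.0))
    np.testing.assert_allclose(field.q2, 0.0, atol=1e-24)


@pytest.mark.parametrize("estimator", [icov_srad, icov_dpad, icov_rdpad])
@pytest.mark.parametrize("k", [0.5, 3.0, 1000.0])
def test_global_scaling_invariance(estimator, k, random_positive_image):
    base = estimator(random_positive_image).q2
    scaled = estimator(k * random_positive_image).q2
    np.testing.assert_allclose(scaled, base, rtol=1e-10, atol=1e-15)


class TestSRAD:
    def test_ramp_matches_stencil_oracle(self):
        ii, jj = np.mgrid[0:12, 0:12]
        img = (jj + 10).astype(float)
        q2 = icov_srad(img).q2
        for i in range(2, 10):
            for j in range(2, 10):
                assert q2[i, j] == pytest.approx(srad_q2_oracle(img, i, j), abs=1e-14)

    def test_random_image_matches_stencil_oracle(self, random_positive_image):
        q2 = icov_srad(random_positive_image).q2
        for i in range(0, 24, 5):
            for j in range(0, 24, 5):
                expect = srad_q2_oracle(random_positive_image, i, j)
                assert q2[i, j] == pytest.approx(expect, rel=1e-12, abs=1e-14)

    def test_single_bright_pixel_peaks_nearby(self):
        img = np.full((21, 21), 10.0)
        img[10, 10] = 200.0
        q2 = icov_srad(img).q2
        peak = np.unravel_index(np.argmax(q2), q2.shape)
        assert abs(peak[0] - 10) <= 1 and abs(peak[1] - 10) <= 1
        assert q2[peak] > 100 * q2[2, 2]


class TestDPAD:
    def test_single_outlier_window(self):
        img = np.ones((5, 5))
        img[2, 2] = 26.0
        q2 = icov_dpad(img).q2
        # center window covers the whole patch: 24 ones and one 26
        assert q2[2, 2] == pytest.approx(dpad_q2_oracle(img), abs=1e-12)
        assert q2[2, 2] == pytest.approx(6.25, abs=1e-12)

    def test_interior_matches_brute_force(self, rng):
        img = rng.uniform(5.0, 50.0, size=(11, 11))
        q2 = icov_dpad(img).q2
        for i in range(2, 9, 2):
            for j in range(2, 9, 2):
                expect = dpad_q2_oracle(img[i - 2:i + 3, j - 2:j + 3])
                assert q2[i, j] == pytest.approx(expect, rel=1e-12)

    def test_window_size_validation(self):
        with pytest.raises(ValueError):
            icov_dpad(np.ones((8, 8)), size=4)

    @pytest.mark.parametrize("looks", [1.0, 4.0])
    def test_median_q_estimates_speckle_scale(self, looks):
        noisy = add_speckle(np.full((100, 100), 120.0), looks=looks, seed=11)
        q = np.sqrt(icov_dpad(noisy).q2)
        assert np.median(q) == pytest.approx(1.0 / np.sqrt(looks), rel=0.15)


class TestRDPAD:
    def test_single_outlier_diamond(self):
        img = np.ones((7, 7))
        img[3, 3] = 2.0
        q2 = icov_rdpad(img).q2
        v = diamond_window(img, 3, 3)
        assert q2[3, 3] == pytest.approx(rdpad_q2_oracle(v), abs=1e-14)
        assert q2[3, 3] == pytest.approx((12.0 / 12.0) / 16.0, abs=1e-14)

    def test_interior_matches_pair_sum_oracle(self, rng):
        img = rng.uniform(1.0, 30.0, size=(12, 12))
        q2 = icov_rdpad(img).q2
        for i in range(2, 10, 3):
            for j in range(2, 10, 3):
                expect = rdpad_q2_oracle(diamond_window(img, i, j))
                assert q2[i, j] == pytest.approx(expect, rel=1e-12)

    @given(st.permutations(list(range(12))))
    def test_formula_invariant_to_ring_permutation(self, perm):
        v = np.array([3.0, 1, 4, 1, 5, 9, 2, 6, 5, 3, 5, 8, 9])
        ring = v[1:][perm]
        assert rdpad_q2_oracle(np.concatenate([[v[0]], ring])) == pytest.approx(
            rdpad_q2_oracle(v), rel=1e-12
        )

    def test_diamond_window_ordering(self):
        img = np.arange(49, dtype=float).reshape(7, 7) + 1.0
        v = diamond_window(img, 3, 3)
        expect = [img[3 + di, 3 + dj] for di, dj in DIAMOND_OFFSETS]
        np.testing.assert_array_equal(v, expect)
        assert v[0] == img[3, 3]
        assert len(v) == 13

    def test_diamond_window_reflects_at_border(self):
        img = np.arange(36, dtype=float).reshape(6, 6) + 1.0
        v = diamond_window(img, 0, 0)
        assert v[0] == img[0, 0]
        assert len(v) == 13


class TestNoiseScale:
    def test_decay_closed_form(self):
        assert q0_schedule("decay", 1.0, 0.1, 0) == pytest.approx(1.0)
        assert q0_schedule("decay", 1.0, 0.1, 10) == pytest.approx(np.exp(-1.0))

    def test_decay_is_strictly_decreasing(self):
        vals = [q0_schedule("decay", 2.0, 1 / 6, t) for t in range(10)]
        assert all(a > b > 0 for a, b in zip(vals, vals[1:]))

    def test_median_mode_zero_majority(self):
        q2 = np.zeros(101)
        q2[-1] = 4.0
        assert q0_schedule("median", q2_field=q2, t=0) == pytest.approx(0.0, abs=1e-8)

    def test_median_mode_requires_field(self):
        with pytest.raises(ValueError, match="q2 field"):
            q0_schedule("median", t=3)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            icov(np.ones((8, 8)), "laplacian")
        with pytest.raises(ValueError, match="unknown"):
            q0_schedule("linear", t=0)
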