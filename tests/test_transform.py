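"""Unit and property tests for the 1D transform pair.

Every weighted-transform check is validated against an independent direct
O(N^2) evaluation of the defining sums, kept deliberately separate from the
library implementation.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dredct import (
    alpha,
    composite_gain,
    enhance_1d,
    forward_dct,
    forward_dre_dct,
    inverse_dct,
    inverse_dre_dct,
)


# -- independent brute-force oracles --------------------------------------

def dct_bruteforce(x):
    x = np.asarray(x, dtype=float)
    n = len(x)
    y = np.empty(n)
    for k in range(n):
        a = 1 / np.sqrt(2) if k == 0 else 1.0
        y[k] = (
            np.sqrt(2 / n)
            * a
            * sum(x[i] * np.cos((2 * i + 1) * k * np.pi / (2 * n)) for i in range(n))
        )
    return y


def idct_bruteforce(y):
    y = np.asarray(y, dtype=float)
    n = len(y)
    x = np.empty(n)
    for i in range(n):
        x[i] = np.sqrt(2 / n) * sum(
            (1 / np.sqrt(2) if k == 0 else 1.0)
            * y[k]
            * np.cos((2 * i + 1) * k * np.pi / (2 * n))
            for k in range(n)
        )
    return x


def impulse_gain_oracle(n):
    """Per-frequency gain of enhance_1d measured from unit-impulse responses."""
    gains = np.full(n, np.nan)
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        ref = dct_bruteforce(e)
        out = dct_bruteforce(enhance_1d(e))
        for k in range(n):
            if abs(ref[k]) > 1e-9 and np.isnan(gains[k]):
                gains[k] = out[k] / ref[k]
    assert not np.isnan(gains).any()
    return gains


# -- alpha ------------------------------------------------------------------

@pytest.mark.parametrize("k,expected", [(0, 1 / np.sqrt(2)), (1, 1.0), (7, 1.0)])
def test_alpha_values(k, expected):
    assert alpha(k) == pytest.approx(expected, abs=1e-12)


def test_alpha_rejects_negative_index():
    with pytest.raises(ValueError):
        alpha(-1)


# -- forward / inverse examples --------------------------------------------

def test_constant_signal_is_pure_dc():
    for n in (1, 3, 16):
        y = forward_dct(np.full(n, 2.5))
        assert y[0] == pytest.approx(2.5 * np.sqrt(n), abs=1e-12)
        assert np.allclose(y[1:], 0.0, atol=1e-12)


def test_forward_dct_matches_direct_evaluation():
    assert np.allclose(forward_dct([1.0, 0.0]), [1 / np.sqrt(2), 1 / np.sqrt(2)], atol=1e-8)
    x = np.random.default_rng(0).normal(size=11)
    assert np.allclose(forward_dct(x), dct_bruteforce(x), atol=1e-10)


def test_inverse_dct_matches_direct_evaluation():
    assert np.allclose(
        inverse_dct([1 / np.sqrt(2), 1 / np.sqrt(2)]), [1.0, 0.0], atol=1e-8
    )
    y = np.random.default_rng(1).normal(size=9)
    assert np.allclose(inverse_dct(y), idct_bruteforce(y), atol=1e-10)


def test_weighted_forward_scales_coefficients_by_n_over_n_plus_k():
    assert np.allclose(
        forward_dre_dct([1.0, 0.0]), [1 / np.sqrt(2), np.sqrt(2) / 3], atol=1e-8
    )
    rng = np.random.default_rng(2)
    for n in (1, 2, 5, 16):
        x = rng.normal(size=n)
        ref = forward_dct(x)
        got = forward_dre_dct(x)
        k = np.arange(n)
        mask = np.abs(ref) > 1e-12
        assert np.allclose(got[mask], (ref * n / (n + k))[mask], atol=1e-10)


def test_weighted_inverse_factorizes_through_standard_inverse():
    y = np.array([1 / np.sqrt(2), np.sqrt(2) / 3])
    assert np.allclose(inverse_dre_dct(y), [7 / 6, -1 / 6], atol=1e-8)
    rng = np.random.default_rng(3)
    for n in (2, 7, 15):
        y = rng.normal(size=n)
        k = np.arange(n)
        assert np.allclose(
            inverse_dre_dct(y), inverse_dct(y * n / (n - k)), atol=1e-10
        )


def test_weighted_constant_signal_round_trip_is_exact():
    # DC weight is 1 in both directions, so constants are fixed points
    x = np.full(6, 5.0)
    assert np.allclose(forward_dre_dct(x)[1:], 0.0, atol=1e-12)
    assert np.allclose(enhance_1d(x), x, atol=1e-12)


# -- round trip and Parseval (standard pair) --------------------------------

@pytest.mark.parametrize("n", list(range(1, 65)))
def test_standard_pair_round_trip_and_parseval(n):
    x = np.random.default_rng(n).normal(size=n)
    y = forward_dct(x)
    assert np.allclose(inverse_dct(y), x, atol=1e-10)
    assert np.allclose(forward_dct(inverse_dct(x)), x, atol=1e-10)
    assert abs(np.sum(y**2) - np.sum(x**2)) < 1e-10


@settings(derandomize=True, deadline=None, max_examples=30)
@given(
    st.lists(
        st.floats(min_value=-100, max_value=100, allow_nan=False), min_size=1, max_size=64
    )
)
def test_round_trip_property(values):
    x = np.asarray(values)
    assert np.allclose(inverse_dct(forward_dct(x)), x, atol=1e-9)


# -- composite gain ----------------------------------------------------------

def test_composite_gain_closed_form_values():
    assert np.allclose(composite_gain(2), [1.0, 4 / 3], atol=1e-12)
    g16 = composite_gain(16)
    assert g16[0] == pytest.approx(1.0, abs=1e-12)
    assert g16[15] == pytest.approx(256 / 31, abs=1e-9)


@pytest.mark.parametrize("n", [2, 4, 8, 14, 15, 16])
def test_composite_gain_matches_impulse_response_oracle(n):
    assert np.allclose(composite_gain(n), impulse_gain_oracle(n), atol=1e-9)


@pytest.mark.parametrize("n", [2, 8, 16, 32])
def test_composite_gain_monotone_and_at_least_one(n):
    g = composite_gain(n)
    assert g[0] == 1.0
    assert np.all(np.diff(g) > 0)
    assert np.all(g >= 1.0)


# -- enhance_1d properties ---------------------------------------------------

def test_enhance_constant_fixed_point_and_n1_passthrough():
    assert np.allclose(enhance_1d([5.0, 5.0, 5.0, 5.0]), [5.0] * 4, atol=1e-12)
    assert np.allclose(enhance_1d([3.7]), [3.7], atol=1e-14)


def test_enhance_matches_spectral_gain_construction():
    rng = np.random.default_rng(4)
    for n in (2, 4, 8, 14, 15, 16):
        x = rng.normal(size=n)
        expected = inverse_dct(composite_gain(n) * forward_dct(x))
        assert np.allclose(enhance_1d(x), expected, atol=1e-9)


def test_enhance_is_linear():
    rng = np.random.default_rng(5)
    x, z = rng.normal(size=12), rng.normal(size=12)
    a, b = 2.5, -1.25
    assert np.allclose(
        enhance_1d(a * x + b * z), a * enhance_1d(x) + b * enhance_1d(z), atol=1e-9
    )


def test_enhance_preserves_mean_and_amplifies_energy():
    rng = np.random.default_rng(6)
    for n in (2, 5, 16, 31):
        x = rng.normal(size=n)
        out = enhance_1d(x)
        assert abs(out.mean() - x.mean()) < 1e-10
        assert np.sum(out**2) > np.sum(x**2)  # strict: x is non-constant
    x = np.full(8, 1.5)
    assert np.sum(enhance_1d(x) ** 2) == pytest.approx(np.sum(x**2), abs=1e-10)


# -- error contracts ---------------------------------------------------------

@pytest.mark.parametrize(
    "fn", [forward_dct, inverse_dct, forward_dre_dct, inverse_dre_dct, enhance_1d]
)
def test_empty_signal_rejected(fn):
    with pytest.raises(ValueError):
        fn(np.array([]))


def test_nonfinite_signal_rejected():
    with pytest.raises(ValueError):
        forward_dct([1.0, np.nan])


def test_composite_gain_rejects_bad_length():
    with pytest.raises(ValueError):
        composite_gain(0)
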