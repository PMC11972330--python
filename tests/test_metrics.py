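"""Dissimilarity measures: frozen examples, closed-form identities and
brute-force oracle equivalence."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from tempodiff import ConfigError, DataError, MetricParams
from tempodiff.metrics import (
    METRIC_NAMES,
    compute_distance,
    compute_distance_table,
    d_acf,
    d_cdm,
    d_cid,
    d_cor,
    d_dtw,
    d_euclidean,
    d_fourier,
    d_frechet,
    d_intper,
    d_per,
    d_sts,
    d_tam,
)

from _oracles import (
    acf_direct,
    dft_direct,
    dtw_bruteforce,
    frechet_bruteforce,
    periodogram_direct,
    tam_optimal_values,
)
from conftest import TIME7, make_profile_set

series7 = arrays(
    float,
    7,
    elements=st.floats(min_value=0.0, max_value=1.0, allow_nan=False, width=32).map(float),
)


# ---------------------------------------------------------------------------
# frozen examples
# ---------------------------------------------------------------------------
def test_euclidean_examples(rng):
    assert d_euclidean([0, 0, 0], [1, 1, 1]) == pytest.approx(math.sqrt(3), abs=1e-15)
    x, y = rng.random(7), rng.random(7)
    direct = math.sqrt(sum((xi - yi) ** 2 for xi, yi in zip(x, y)))
    assert d_euclidean(x, y, time_vector=TIME7) == pytest.approx(direct, abs=1e-12)


def test_sts_examples(rng):
    # constant shift leaves slopes untouched
    x = rng.random(7)
    assert d_sts(x, x + 3.7, time_vector=TIME7) == pytest.approx(0.0, abs=1e-12)
    assert d_sts([0, 1], [0, 0]) == pytest.approx(1.0)
    # slope-by-slope oracle on the uneven default grid
    x, y = rng.random(7), rng.random(7)
    direct = math.sqrt(
        sum(
            (
                (y[i + 1] - y[i]) / (TIME7[i + 1] - TIME7[i])
                - (x[i + 1] - x[i]) / (TIME7[i + 1] - TIME7[i])
            )
            ** 2
            for i in range(6)
        )
    )
    assert d_sts(x, y, time_vector=TIME7) == pytest.approx(direct, abs=1e-12)


def test_dtw_elastic_alignment():
    # a monotone warp absorbs the one-step lag entirely
    assert d_dtw([0, 0, 1], [0, 1, 1]) == pytest.approx(0.0, abs=1e-15)


def test_tam_frozen_example():
    # hand-traced diagonal-preferred optimal path: 1 horiz, 1 diag, 1 vert
    value = d_tam([0, 1, 0], [1, 0, 1])
    assert value == pytest.approx(4 / 3, abs=1e-12)
    assert round(value, 12) in tam_optimal_values([0, 1, 0], [1, 0, 1])


def test_acf_direct_formula(rng):
    x = np.sin(np.linspace(0, 2 * np.pi, 7))
    y = rng.normal(0.5, 0.05, 7)
    rx, ry = acf_direct(x, 5), acf_direct(y, 5)
    direct = math.sqrt(sum((a - b) ** 2 for a, b in zip(rx, ry)))
    assert d_acf(x, y) == pytest.approx(direct, abs=1e-12)


def test_acf_shift_invariance(rng):
    x = rng.random(7)
    assert d_acf(x, x + 2.5) == pytest.approx(0.0, abs=1e-12)


def test_fourier_dc_coefficient(rng):
    x, y = rng.random(7), rng.random(7)
    d = d_fourier(x, y, params=MetricParams(fourier_n_coef=1))
    assert d == pytest.approx(abs(x.sum() - y.sum()), abs=1e-9)


def test_per_direct_formula(rng):
    x, y = rng.random(7), rng.random(7)
    px, py = periodogram_direct(x, 3), periodogram_direct(y, 3)
    direct = math.sqrt(sum((a - b) ** 2 for a, b in zip(px, py)))
    assert d_per(x, y) == pytest.approx(direct, abs=1e-12)


def test_per_and_intper_shift_invariance(rng):
    x = rng.random(7)
    assert d_per(x, x + 1.23) == pytest.approx(0.0, abs=1e-12)
    assert d_intper(x, x + 1.23) == pytest.approx(0.0, abs=1e-12)


def test_intper_constant_series_ramp_convention():
    # both series have zero power off DC -> matching uniform ramps -> 0
    assert d_intper([0.5] * 7, [0.2] * 7) == pytest.approx(0.0, abs=1e-15)


def test_cid_examples(rng):
    assert math.sqrt(sum(np.diff([0, 1, 0]) ** 2.0)) == pytest.approx(math.sqrt(2))
    # equal-complexity pair: factor is 1 up to epsilon effects
    x = rng.random(7)
    y = x[::-1].copy()
    assert d_cid(x, y) == pytest.approx(d_euclidean(x, y), rel=1e-9)


def test_cor_examples(rng):
    x = rng.random(7)
    assert d_cor(x, 2.0 * x + 1.0) == pytest.approx(0.0, abs=1e-7)
    z = x - x.mean()
    assert d_cor(z, -z) == pytest.approx(2.0, abs=1e-12)
    assert d_cor(np.full(7, 0.3), x) == pytest.approx(math.sqrt(2))


def test_cdm_quantization_symmetry_determinism(rng):
    from tempodiff.metrics import _quantize

    assert _quantize(np.array([1.0]), 8) == bytes([7])
    assert _quantize(np.array([0.0]), 8) == bytes([0])
    x, y = rng.random(7), rng.random(7)
    assert d_cdm(x, y) == d_cdm(y, x)
    assert d_cdm(x, y) == d_cdm(x, y)
    assert d_cdm(x, y, params=MetricParams(cdm_compressor="deflate")) == d_cdm(
        x, y, params=MetricParams(cdm_compressor="deflate")
    )


def test_frechet_bounds(rng):
    x, y = rng.random(7), rng.random(7)
    d = d_frechet(x, y)
    assert max(abs(x[0] - y[0]), abs(x[-1] - y[-1])) <= d + 1e-12
    assert d <= np.max(np.abs(x - y)) + 1e-12


def test_frechet_time_value_embedding():
    x, y = np.array([0.0, 1.0, 0.0]), np.array([1.0, 0.0, 1.0])
    d1 = d_frechet(x, y, params=MetricParams(frechet_embedding="value_only"))
    d2 = d_frechet(x, y, time_vector=[0, 5, 10], params=MetricParams(frechet_embedding="time_value"))
    assert d2 >= d1  # planar cost dominates the value-only cost on the diagonal


# ---------------------------------------------------------------------------
# brute-force oracle equivalence (exhaustive enumeration, T <= 5)
# ---------------------------------------------------------------------------
@pytest.mark.parametrize("T", [2, 3, 4, 5])
def test_dtw_matches_bruteforce_enumeration(T, rng):
    for _ in range(60):
        x, y = rng.random(T), rng.random(T)
        assert d_dtw(x, y) == pytest.approx(dtw_bruteforce(x, y), abs=1e-12)


@pytest.mark.parametrize("T", [2, 3, 4, 5])
def test_frechet_matches_bruteforce_enumeration(T, rng):
    for _ in range(60):
        x, y = rng.random(T), rng.random(T)
        assert d_frechet(x, y) == pytest.approx(frechet_bruteforce(x, y), abs=1e-12)


def test_frechet_exhaustive_small_integer_pairs():
    # every T=3 pair with entries in {0,1,2}, scaled onto [0,1]
    from itertools import product

    grid = [np.array(p) / 2.0 for p in product(range(3), repeat=3)]
    for x in grid:
        for y in grid:
            assert d_frechet(x, y) == pytest.approx(frechet_bruteforce(x, y), abs=1e-15)


def test_tam_is_optimal_path_value(rng):
    for T in (3, 4, 5):
        for _ in range(40):
            x, y = rng.integers(0, 3, T) / 2.0, rng.integers(0, 3, T) / 2.0
            assert round(d_tam(x, y), 12) in tam_optimal_values(x, y)


# ---------------------------------------------------------------------------
# family-wide properties
# ---------------------------------------------------------------------------
@settings(max_examples=40, deadline=None)
@given(x=series7, y=series7)
def test_metrics_nonnegative_symmetric(x, y):
    for name in METRIC_NAMES:
        dxy = compute_distance(name, x, y, time_vector=TIME7)
        dyx = compute_distance(name, y, x, time_vector=TIME7)
        assert dxy >= 0
        assert dxy == pytest.approx(dyx, abs=1e-9)
        assert np.isfinite(dxy)


@settings(max_examples=40, deadline=None)
@given(x=series7)
def test_metrics_identity(x):
    # CDM excluded: it measures shared information, CDM(x,x) > 0 by design.
    # cor on a constant series is sqrt(2) by the declared rho := 0 convention.
    constant = np.all(x == x[0])
    for name in METRIC_NAMES:
        if name == "cdm" or (name == "cor" and constant):
            continue
        assert compute_distance(name, x, x.copy(), time_vector=TIME7) == pytest.approx(
            0.0, abs=1e-9
        )


@settings(max_examples=30, deadline=None)
@given(x=series7, y=series7)
def test_dtw_bounded_by_manhattan(x, y):
    assert d_dtw(x, y) <= np.sum(np.abs(x - y)) + 1e-12


@settings(max_examples=30, deadline=None)
@given(x=series7, y=series7)
def test_tam_range(x, y):
    assert 0.0 <= d_tam(x, y) <= 2.0


def test_parseval_identity(rng):
    T = 7
    for _ in range(50):
        x, y = rng.random(T), rng.random(T)
        d_full = d_fourier(x, y, params=MetricParams(fourier_n_coef=T))
        assert d_full == pytest.approx(math.sqrt(T) * d_euclidean(x, y), abs=1e-9)


# ---------------------------------------------------------------------------
# table computation
# ---------------------------------------------------------------------------
def test_table_matches_per_pair_functions(rng):
    wt = rng.random((40, 7))
    ko = rng.random((40, 7))
    ps = make_profile_set(wt, ko, time_vector=TIME7, scaled=True)
    table = compute_distance_table(ps)
    funcs = {
        "euclidean": d_euclidean, "sts": d_sts, "dtw": d_dtw, "tam": d_tam,
        "acf": d_acf, "fourier": d_fourier, "cdm": d_cdm, "cid": d_cid,
        "cor": d_cor, "int.per": d_intper, "per": d_per, "frechet": d_frechet,
    }
    for name, func in funcs.items():
        expected = [func(ps.wt[i], ps.ko[i], time_vector=TIME7) for i in range(len(ps))]
        np.testing.assert_allclose(table[name].to_numpy(), expected, atol=1e-12)


def test_table_requires_scaled_profiles(rng):
    ps = make_profile_set(rng.random((3, 7)), rng.random((3, 7)), scaled=False)
    with pytest.raises(DataError):
        compute_distance_table(ps)


def test_unknown_metric_lists_valid_names(rng):
    ps = make_profile_set(rng.random((3, 7)), rng.random((3, 7)), scaled=True)
    with pytest.raises(ConfigError, match="euclidean"):
        compute_distance_table(ps, metrics=["euclidean", "nope"])


def test_non_finite_input_rejected():
    with pytest.raises(DataError):
        d_euclidean([0, np.nan, 1], [0, 0, 0])
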