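"""Gap curves, threshold calibration and the k_est decision rule."""

import numpy as np
import pytest

from modgap import (
    ThresholdTable,
    calibrate_thresholds,
    estimate_modes,
    estimate_modes_batch,
    gap_curve,
    make_mixture_spec,
    sample_modular,
)
from modgap.gap import CalibrationError, _select_k, evidence_batch
from scipy import stats


def test_gap_near_zero_for_uniform_data():
    """Reference matches the generating law, so Gap(k) ~ 0 within MC spread."""
    rng = np.random.default_rng(42)
    curve = gap_curve(rng.random(40), kmax=8, B=200, rng=rng)
    assert np.all(np.abs(curve.gap) < 6.0 * curve.s_k + 0.05)


def test_gap_prefers_two_clusters_for_bimodal_data():
    rng = np.random.default_rng(43)
    v = np.concatenate([rng.normal(0, 0.1, 20), rng.normal(100, 0.1, 20)])
    curve = gap_curve(v, kmax=8, B=100, rng=rng)
    assert curve.gap[1] > curve.gap[0]


def test_gap_curve_validation():
    with pytest.raises(ValueError):
        gap_curve(np.arange(5.0), kmax=6, B=100, rng=0)
    with pytest.raises(ValueError):
        gap_curve(np.arange(20.0), kmax=5, B=5, rng=0)
    with pytest.raises(ValueError):
        gap_curve(np.array([1.0, np.nan, 2.0, 3.0]), kmax=2, B=10, rng=0)


def test_constant_input_degenerate_and_kest_one(table_n40_coarse):
    curve = gap_curve(np.ones(40), kmax=8, B=100, rng=0)
    assert curve.degenerate
    res = estimate_modes(np.ones(40), table_n40_coarse, rng=0)
    assert res.k_est == 1 and not res.clustered


def test_estimate_modes_requires_min_n(table_n40_coarse):
    with pytest.raises(ValueError):
        estimate_modes(np.array([1.0, 2.0, 3.0]), table_n40_coarse)


def test_obvious_two_modes_always_detected(table_n40_coarse):
    """Point masses at 0 and 1000 (sd 1): k_est = 2 in every replicate."""
    rng = np.random.default_rng(7)
    spec = make_mixture_spec(2, separation_sd=1000.0)
    for _ in range(20):
        fs = sample_modular(40, spec, rng=rng)
        assert estimate_modes(fs.values, table_n40_coarse, rng=rng).k_est == 2


def test_affine_invariance_of_kest(table_n40_coarse):
    """x -> a x + b leaves k_est unchanged at fixed seeds."""
    rng = np.random.default_rng(8)
    for _ in range(10):
        v = rng.random(40)
        k1 = estimate_modes(v, table_n40_coarse, rng=99).k_est
        k2 = estimate_modes(13.5 * v - 200.0, table_n40_coarse, rng=99).k_est
        assert k1 == k2
    # batch route: evidence identical under affine maps with a shared seed
    data = rng.random((20, 40))
    e1 = evidence_batch(data, 8, 50, rng=5)
    e2 = evidence_batch(2.0 * data + 7.0, 8, 50, rng=5)
    assert np.allclose(e1, e2, atol=1e-8)


def test_threshold_table_roundtrip(tmp_path, table_n40_coarse):
    path = tmp_path / "table.json"
    table_n40_coarse.to_json(path)
    back = ThresholdTable.from_json(path)
    assert back.n == table_n40_coarse.n
    assert back.seed == table_n40_coarse.seed
    assert np.allclose(back.thresholds, table_n40_coarse.thresholds)


def test_infinite_thresholds_mean_kest_one():
    """The alpha -> 0 limit: no evidence can pass, every dataset is continuous."""
    table = ThresholdTable(n=40, kmax=8, alpha_per_k=0.001, thresholds=np.full(7, np.inf),
                           null_reps=1000, B=100, seed=0)
    rng = np.random.default_rng(9)
    data = rng.random((20, 40))
    assert np.all(estimate_modes_batch(data, table, rng=rng) == 1)


def test_calibration_rejects_bad_arguments():
    with pytest.raises(ValueError):
        calibrate_thresholds(40, kmax=8, alpha_per_k=0.2, null_reps=500, seed=0)
    with pytest.raises(ValueError):
        calibrate_thresholds(40, null_reps=50, seed=0)
    with pytest.raises(CalibrationError):
        calibrate_thresholds(40, alpha_per_k=0.001, null_reps=200, B=20, seed=0)


def test_select_k_tie_goes_to_smaller_k():
    thresholds = np.zeros(3)
    ev = np.array([[0.5, 0.5, 0.2]])
    assert _select_k(ev, thresholds)[0] == 2
    assert _select_k(np.array([[-1.0, -2.0, -0.5]]), thresholds)[0] == 1


@pytest.mark.parametrize("n", [20, 40, 80])
def test_per_k_null_selection_rate_matches_alpha(n):
    """Held-out per-k selection rates sit inside exact binomial bounds.

    Calibration targets a 0.01 selection rate for every k in 2..8; a fresh
    null sample must select each k within exact binomial bounds around
    0.01 (bounds set jointly over the 21 (n, k) checks), at every dataset
    size tested.
    """
    table = calibrate_thresholds(n, kmax=8, alpha_per_k=0.01, null_reps=1500, B=100,
                                 seed=300 + n)
    rng = np.random.default_rng(400 + n)
    nulls = rng.random(size=(800, n))
    k_est = estimate_modes_batch(nulls, table, rng=rng)
    for k in range(2, 9):
        x = int(np.sum(k_est == k))
        lo, hi = stats.binom.ppf([0.0025, 0.9975], 800, 0.01)
        assert lo <= x <= hi, f"n={n}, k={k}: {x} selections outside [{lo}, {hi}]"


def test_overall_null_rate_insensitive_to_n():
    """P(k_est >= 2) under the null is ~alpha*(kmax-1) at every n."""
    rates = []
    for n, seed in [(20, 501), (40, 502), (80, 503)]:
        table = calibrate_thresholds(n, kmax=8, alpha_per_k=0.01, null_reps=1000, B=100,
                                     seed=seed)
        rng = np.random.default_rng(seed + 50)
        k_est = estimate_modes_batch(rng.random(size=(600, n)), table, rng=rng)
        rates.append(np.mean(k_est >= 2))
    # all pairwise differences indistinguishable: two-proportion z at 1% level
    for i in range(3):
        for j in range(i + 1, 3):
            p = (rates[i] + rates[j]) / 2.0
            se = np.sqrt(2.0 * p * (1.0 - p) / 600.0)
            assert abs(rates[i] - rates[j]) < 2.576 * se + 1e-9
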