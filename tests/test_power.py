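"""Detection-power estimation and per-animal panel inference."""

import numpy as np
import pytest

from modgap import (
    FeatureSample,
    animal_panel_summary,
    estimate_detection_rate,
    fit_mixture_separation,
    make_mixture_spec,
    power_sweep,
    sample_modular,
)
from modgap.power import panel_to_frame


def test_power_result_invariants(table_n40_coarse):
    res = estimate_detection_rate("uniform", "modified_gap", reps=100, rng=1,
                                  table=table_n40_coarse)
    assert res.p_detect == res.detections / res.reps
    assert 0.0 <= res.mc_ci[0] <= res.p_detect <= res.mc_ci[1] <= 1.0
    assert res.generator == "uniform" and res.n == 40


def test_detection_rate_monotone_in_separation(table_n40_coarse):
    """p_detect rises with mode separation (2 -> 5 -> 10 SD) within MC error."""
    rates = []
    for i, sep in enumerate([2.0, 5.0, 10.0]):
        spec = make_mixture_spec(2, separation_sd=sep)
        res = estimate_detection_rate(spec, "modified_gap", reps=200, rng=10 + i,
                                      table=table_n40_coarse)
        rates.append(res.p_detect)
    slack = 2.0 * np.sqrt(0.25 / 200)  # two MC standard errors
    assert rates[1] >= rates[0] - slack
    assert rates[2] >= rates[1] - slack
    assert rates[2] > rates[0]


def test_detection_rate_insensitive_to_k(table_n40_coarse):
    """At fixed separation, p_detect varies little across k = 2, 3, 4."""
    rates, widths = [], []
    for i, k in enumerate([2, 3, 4]):
        spec = make_mixture_spec(k, separation_sd=8.0)
        res = estimate_detection_rate(spec, "modified_gap", reps=150, rng=20 + i,
                                      table=table_n40_coarse)
        rates.append(res.p_detect)
        widths.append(res.mc_ci[1] - res.mc_ci[0])
    assert max(rates) - min(rates) < max(widths) + 0.05


def test_matched_detector_arguments(table_n40_coarse):
    with pytest.raises(ValueError):
        estimate_detection_rate("uniform", "modified_gap", reps=10)
    with pytest.raises(ValueError):
        estimate_detection_rate("uniform", "lnds_thresholded", reps=10, n=40)
    with pytest.raises(ValueError):
        estimate_detection_rate("uniform", "nope", reps=10, n=40)
    with pytest.raises(ValueError):
        estimate_detection_rate("uniform", "modified_gap", reps=10,
                                table=table_n40_coarse, n=100)


def test_power_sweep_table(table_n40_coarse):
    df = power_sweep([40], [5.0, 20.0], ks=(2,), reps=60, rng=3,
                     tables={40: table_n40_coarse})
    assert len(df) == 2
    assert set(df.columns) >= {"n", "separation_sd", "k", "p_detect", "ci_lo", "ci_hi"}
    assert df.loc[df.separation_sd == 20.0, "p_detect"].iloc[0] >= \
        df.loc[df.separation_sd == 5.0, "p_detect"].iloc[0] - 0.15


def _make_panel(n_animals, n, spec, rng, feature="feat"):
    out = []
    for i in range(n_animals):
        if spec is None:
            values = rng.random(n)
            fs = FeatureSample(f"a{i:02d}", feature, values)
        else:
            fs = sample_modular(n, spec, rng=rng, animal_id=f"a{i:02d}", feature_name=feature)
        out.append(fs)
    return out


def test_uniform_panel_consistent_with_null(table_n40_coarse):
    """A 15-animal continuous panel should not reject the null rate."""
    rng = np.random.default_rng(30)
    panel = _make_panel(15, 40, None, rng)
    summaries = animal_panel_summary(panel, table_n40_coarse, p0_null=0.07,
                                     p0_modular=0.8, rng=rng, min_n=34)
    s = summaries["feat"]
    assert s.n_animals == 15
    assert s.vs_null.p_value > 0.05
    assert s.k_histogram(8).sum() == 15
    assert s.k_histogram(8)[0] >= 12  # most animals at k_est = 1


def test_modular_panel_rejects_null(table_n40_coarse):
    """A 15-animal panel of 5-SD bimodal features rejects the continuous null."""
    rng = np.random.default_rng(31)
    spec = make_mixture_spec(2, separation_sd=5.0)
    panel = _make_panel(15, 40, spec, rng)
    summaries = animal_panel_summary(panel, table_n40_coarse, p0_null=0.07,
                                     p0_modular=0.8, rng=rng, min_n=34)
    s = summaries["feat"]
    assert s.n_clustered >= 8
    assert s.vs_null.p_value < 1e-6
    assert s.vs_modular.p_value > 0.001


def test_min_n_filter_excludes_small_animals(table_n40_coarse):
    rng = np.random.default_rng(32)
    panel = _make_panel(5, 40, None, rng) + [FeatureSample("tiny", "feat", rng.random(10))]
    summaries = animal_panel_summary(panel, table_n40_coarse, 0.07, 0.8, rng=rng, min_n=34)
    s = summaries["feat"]
    assert s.excluded == ["tiny"]
    assert s.n_animals == 5
    # all excluded -> explicit empty result
    empty = animal_panel_summary([FeatureSample("t", "x", rng.random(5))],
                                 table_n40_coarse, 0.07, 0.8, rng=rng, min_n=34)["x"]
    assert empty.n_animals == 0 and empty.vs_null is None

    df = panel_to_frame(summaries)
    assert set(df.columns) == {"feature", "n_animals", "n_clustered", "p_hat",
                               "ci_lo", "ci_hi", "p_vs_null", "p_vs_modular"}


def test_fit_mixture_separation_recovers_benchmark():
    """EM on a well-separated bimodal sample recovers ~5 SD separation."""
    spec = make_mixture_spec(2, separation_sd=5.0)
    fs = sample_modular(400, spec, rng=33)
    sep = fit_mixture_separation(fs.values, k=2, rng=33)
    assert sep == pytest.approx(5.0, rel=0.2)
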