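"""Binning, quadratic U-shape fitting, and the greedy segment inclusion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cppopt import PRxParams, PRxSeries, Segment, bin_prx, fit_ushape, select_segments


def _series(cpp, prx, t_end=None):
    cpp = np.asarray(cpp, float)
    if t_end is None:
        t_end = 300.0 + 10.0 * np.arange(cpp.size)
    return PRxSeries(t_end=t_end, prx=np.asarray(prx, float), cpp_mean=cpp,
                     abp_mean=cpp + 15.0, icp_mean=np.full(cpp.size, 15.0))


def _wls_oracle(x, y, w):
    """Independent weighted quadratic LS via the normal equations."""
    X = np.vstack([x ** 2, x, np.ones_like(x)]).T
    W = np.diag(w)
    beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
    yhat = X @ beta
    wm = np.average(y, weights=w)
    r2 = 1 - np.sum(w * (y - yhat) ** 2) / np.sum(w * (y - wm) ** 2)
    return beta, r2


def test_bin_edge_convention():
    series = _series([62.0] * 5 + [68.0] * 5, [0.1] * 10)
    bins = bin_prx(series, "cpp")
    np.testing.assert_allclose(bins.centers, [62.5, 67.5])
    assert bins.counts.tolist() == [5, 5]


def test_single_bin_makes_fit_impossible():
    series = _series([72.0] * 20, np.linspace(-0.1, 0.1, 20))
    bins = bin_prx(series, "cpp")
    assert not bins.fit_possible
    assert not fit_ushape(bins).valid


def test_bin_counts_are_conserved():
    rng = np.random.default_rng(0)
    series = _series(rng.uniform(55, 105, 500), rng.uniform(-0.5, 0.5, 500))
    bins = bin_prx(series, "cpp", min_count=1)
    assert bins.counts.sum() == 500


def test_min_count_drops_sparse_bins():
    series = _series([62.0] * 5 + [92.0] * 3, [0.1] * 8)
    bins = bin_prx(series, "cpp", min_count=5)
    np.testing.assert_allclose(bins.centers, [62.5])


def _parabola_series(a=0.002, x0=80.0, c=-0.2, reps=6):
    # samples sit exactly at the bin centers 62.5, 67.5, ..., 102.5
    xs = np.repeat(np.arange(62.5, 103.0, 5.0), reps)
    return _series(xs, a * (xs - x0) ** 2 + c)


def test_exact_parabola_recovered():
    fit = fit_ushape(bin_prx(_parabola_series(), "cpp"))
    assert fit.valid
    assert fit.a == pytest.approx(0.002, abs=1e-9)
    assert fit.opt_value == pytest.approx(80.0, abs=1e-6)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
    assert fit.llca == pytest.approx(64.1886, abs=1e-3)
    assert fit.ulca == pytest.approx(95.8114, abs=1e-3)


def test_minimum_above_threshold_has_no_crossings():
    fit = fit_ushape(bin_prx(_parabola_series(a=0.001, c=0.4), "cpp"))
    assert fit.valid
    assert fit.opt_value == pytest.approx(80.0, abs=1e-6)
    assert fit.llca is None and fit.ulca is None


def test_downward_parabola_invalid():
    fit = fit_ushape(bin_prx(_parabola_series(a=-0.002, c=0.2), "cpp"))
    assert not fit.valid
    assert fit.opt_value is None and fit.llca is None and fit.ulca is None
    assert fit.a == pytest.approx(-0.002, abs=1e-9)  # still recorded


def test_icp_axis_reports_only_ulca():
    xs = np.repeat(np.arange(12.5, 43.0, 5.0), 6)
    series = PRxSeries(
        t_end=300.0 + 10 * np.arange(xs.size),
        prx=0.002 * (xs - 22.0) ** 2 - 0.2,
        cpp_mean=np.full(xs.size, 80.0), abp_mean=np.full(xs.size, 95.0),
        icp_mean=xs)
    fit = fit_ushape(bin_prx(series, "icp"))
    assert fit.valid
    assert fit.opt_value is None and fit.llca is None
    assert fit.ulca == pytest.approx(22.0 + np.sqrt(250), abs=1e-3)


def test_vertex_outside_range_suppressed():
    xs = np.repeat(np.arange(87.5, 108.0, 5.0), 6)
    series = _series(xs, 0.001 * (xs - 80.0) ** 2 - 0.2)
    fit = fit_ushape(bin_prx(series, "cpp"))
    assert fit.valid and fit.opt_value is None  # vertex 80 < lowest center


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.integers(0, 10_000))
def test_weighted_fit_matches_normal_equations(seed):
    rng = np.random.default_rng(seed)
    n_bins = rng.integers(4, 9)
    centers = 62.5 + 5.0 * np.arange(n_bins)
    means = np.clip(rng.normal(0, 0.3, n_bins), -0.95, 0.95)
    counts = rng.integers(5, 40, n_bins)
    xs = np.repeat(centers, counts)
    ys = np.repeat(means, counts)  # exact bin means by construction
    fit = fit_ushape(bin_prx(_series(xs, ys), "cpp", min_count=1))
    (a, b, c0), r2 = _wls_oracle(centers, means, counts.astype(float))
    assert fit.a == pytest.approx(a, abs=1e-10)
    assert fit.b == pytest.approx(b, abs=1e-8)
    assert fit.c0 == pytest.approx(c0, abs=1e-6)
    if np.isfinite(r2):
        assert fit.r_squared == pytest.approx(max(0.0, min(1.0, r2)), abs=1e-9)


def test_limits_bracket_optimum_symmetrically():
    fit = fit_ushape(bin_prx(_parabola_series(), "cpp"))
    assert fit.llca < fit.opt_value < fit.ulca
    assert (fit.opt_value - fit.llca) == pytest.approx(fit.ulca - fit.opt_value,
                                                       abs=1e-6)


# -- segment selection ----------------------------------------------------


def _window_series(seed=0, noise=0.0, n_per_seg=138):
    """A 2-h window's PRx: each 24-min segment sweeps part of the curve."""
    rng = np.random.default_rng(seed)
    t_end = 300.0 + 10.0 * np.arange(5 * n_per_seg)
    cpp = 55 + 50 * (t_end / t_end.max())
    prx = np.clip(0.0015 * (cpp - 80) ** 2 - 0.2 + rng.normal(0, noise, cpp.size),
                  -0.99, 0.99)  # amplitude chosen so the clip never engages
    return PRxSeries(t_end=t_end, prx=prx, cpp_mean=cpp, abp_mean=cpp + 15,
                     icp_mean=np.full(cpp.size, 15.0))


def _segments(labels):
    segs = []
    for k, (art, info) in enumerate(labels):
        segs.append(Segment("w0000", k, k * 1440.0, (k + 1) * 1440.0,
                            artifact_label=art, informative_label=info))
    return segs


def test_all_clean_informative_uses_all_five():
    segs = _segments([("artifact_free", "informative")] * 5)
    chosen, fit = select_segments(segs, _window_series(), "cpp")
    assert sorted(chosen) == [0, 1, 2, 3, 4]
    # bin means of a noiseless parabola are near-quadratic in the bin
    # center; only partially filled edge bins sit slightly off the curve
    assert fit.valid and fit.r_squared > 0.99


def test_no_informative_segment_means_no_fit():
    segs = _segments([("artifact_free", "noninformative")] * 5)
    chosen, fit = select_segments(segs, _window_series(), "cpp")
    assert chosen == [] and fit is None


def test_noise_segment_rejected_and_distorted_never_enters():
    series = _window_series(seed=1, noise=0.02)
    # corrupt segment 2's PRx with pure noise
    in_seg2 = (series.t_end > 2880.0) & (series.t_end <= 4320.0)
    series.prx[in_seg2] = np.random.default_rng(2).uniform(-0.9, 0.9, in_seg2.sum())
    segs = _segments([
        ("artifact_free", "informative"),
        ("artifact_free", "informative"),
        ("artifact_free", "noninformative"),   # the noise segment
        ("artifact_free", "informative"),
        ("artifact_distorted", "informative"),  # must never enter
    ])
    chosen, fit = select_segments(segs, series, "cpp")
    assert 2 not in chosen
    assert 4 not in chosen
    assert fit.valid


def test_greedy_never_below_base_fit():
    for seed in range(30):
        rng = np.random.default_rng(seed)
        series = _window_series(seed=seed, noise=0.15)
        labels = []
        for _ in range(5):
            art = "artifact_free" if rng.random() < 0.9 else "artifact_distorted"
            info = "informative" if rng.random() < 0.6 else "noninformative"
            labels.append((art, info))
        segs = _segments(labels)
        base = [s for s in segs if s.is_artifact_free and s.is_informative]
        if not base:
            continue
        _, base_fit = select_segments(
            [s if s.is_informative or not s.is_artifact_free
             else s.with_labels("artifact_distorted", s.informative_label)
             for s in segs], series, "cpp")
        _, fit = select_segments(segs, series, "cpp")
        if base_fit is not None and base_fit.valid and fit is not None and fit.valid:
            assert fit.r_squared >= base_fit.r_squared - 1e-12
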