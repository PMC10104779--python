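"""Distribution statistics: CCDFs, particle-weighted moments, slope
fits, growth timescale, collapse transform, detection-floor bias."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from condkin import stats


def test_ccdf_counting():
    v, c = stats.ccdf(np.array([1.0, 2.0, 3.0]))
    # at v = 1.5 (i.e. above the first point) two of three exceed
    assert stats.ccdf_at(np.array([1.0, 2.0, 3.0]), np.array([1.5]))[0] == pytest.approx(2 / 3)
    assert c[0] == pytest.approx(2 / 3)
    assert c[-1] == 0.0


def test_ccdf_singleton_below_support():
    assert stats.ccdf_at(np.array([5.0]), np.array([1.0]))[0] == 1.0


def test_ccdf_rejects_empty_and_nonpositive():
    with pytest.raises(ValueError):
        stats.ccdf(np.array([]))
    with pytest.raises(ValueError):
        stats.VolumeSample(np.array([1.0, -2.0]))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.01, 1e4), min_size=1, max_size=200))
def test_ccdf_monotone_nonincreasing(values):
    v, c = stats.ccdf(np.array(values))
    assert np.all(np.diff(c) <= 1e-12)
    assert stats.ccdf_at(np.array(values), np.array([max(values) * 1.01]))[0] == 0.0


def test_exponential_ccdf_semilog_slope():
    rng = np.random.default_rng(0)
    v = rng.exponential(2.5, size=50_000)
    fit = stats.fit_exponential(stats.ccdf(v))
    assert fit.slope == pytest.approx(-1 / 2.5, rel=0.03)
    assert fit.f_pvalue < 1e-10


def test_rescale_average_idempotent_on_identical_cells():
    v = np.array([1.0, 2.0, 4.0, 8.0])
    cells = [stats.VolumeSample(v, cell_id=i) for i in range(5)]
    grid, mean, sem, n = stats.rescale_and_average(cells)
    assert n == 5
    assert np.allclose(sem, 0.0)
    assert np.allclose(mean, stats.ccdf_at(v / v.mean(), grid))


def test_rescale_average_collapses_heterogeneous_exponentials():
    """Cells with different mean volumes collapse onto exp(-v): semi-log
    slope -1."""
    rng = np.random.default_rng(1)
    cells = [
        stats.VolumeSample(rng.exponential(mu, size=400), cell_id=i)
        for i, mu in enumerate(rng.uniform(0.5, 5.0, size=40))
    ]
    grid, mean, _, _ = stats.rescale_and_average(cells)
    fit = stats.fit_exponential((grid, mean))
    assert fit.slope == pytest.approx(-1.0, abs=0.08)


def test_rescale_average_powerlaw_is_loglog_linear():
    rng = np.random.default_rng(2)
    law = ("powerlaw", -1.5, 1.0, 1000.0)
    from condkin.synthetic import sample_volumes

    cells = [stats.VolumeSample(sample_volumes(law, 500, rng), cell_id=i) for i in range(30)]
    grid, mean, _, _ = stats.rescale_and_average(cells)
    good = mean > 0
    pl = stats.fit_powerlaw((grid[good], mean[good]), quantiles=(0.05, 0.9))
    ex = stats.fit_exponential((grid[good], mean[good]), quantiles=(0.05, 0.9))
    assert pl.r_squared > ex.r_squared


def test_particle_moments_constant_sample():
    m, var = stats.particle_moments(np.full(10, 3.0))
    assert m == pytest.approx(3.0)
    assert var == pytest.approx(0.0)


def test_particle_moments_exponential_closed_form():
    """Exponential mean mu: <V>_p = 2mu and sigma_p^2 = 2mu^2 (slope-2 law)."""
    rng = np.random.default_rng(3)
    mu = 1.7
    v = rng.exponential(mu, size=400_000)
    p_mean, p_var = stats.particle_moments(v)
    assert p_mean == pytest.approx(2 * mu, rel=0.02)
    assert p_var == pytest.approx(2 * mu**2, rel=0.05)
    assert p_var / p_mean**2 == pytest.approx(0.5, rel=0.05)


def test_cv_values():
    assert stats.cv(np.full(5, 2.0)) == 0.0
    rng = np.random.default_rng(4)
    assert stats.cv(rng.exponential(1.0, size=100_000)) == pytest.approx(1.0, abs=0.02)
    from condkin.synthetic import sample_volumes

    pl = sample_volumes(("powerlaw", -1.5, 1.0, 1000.0), 100_000, rng)
    assert stats.cv(pl) > 1.0


def test_fit_exponential_exact_curve():
    v = np.linspace(0.1, 8, 100)
    fit = stats.fit_exponential((v, np.exp(-v / 2.0)), quantiles=None)
    assert fit.slope == pytest.approx(-0.5)
    assert fit.r_squared == pytest.approx(1.0)


def test_fit_powerlaw_exact_curve_and_pdf_exponent():
    v = np.geomspace(1, 1000, 60)
    fit = stats.fit_powerlaw((v, v**-0.5), quantiles=None)
    assert fit.slope == pytest.approx(-0.5)
    # printed convention: CCDF exponent -0.41 -> pdf exponent -1.41
    assert stats.pdf_exponent_from_ccdf(-0.41) == pytest.approx(-1.41)


def test_fit_powerlaw_recovers_generator_exponent():
    """Away from the upper cutoff the bounded power law's CCDF slope is
    the analytic k + 1."""
    from condkin.synthetic import sample_volumes

    rng = np.random.default_rng(5)
    v = sample_volumes(("powerlaw", -1.5, 1.0, 1e6), 50_000, rng)
    fit = stats.fit_powerlaw(stats.ccdf(v), quantiles=None, v_hi=1e3)
    assert fit.slope == pytest.approx(-0.5, abs=0.05)


def test_powerlaw_sample_fits_exponential_poorly():
    from condkin.synthetic import sample_volumes

    rng = np.random.default_rng(6)
    v = sample_volumes(("powerlaw", -1.5, 1.0, 1000.0), 20_000, rng)
    grid = np.geomspace(1, 900, 40)
    c = stats.ccdf_at(v, grid)
    good = c > 0
    exp_fit = stats.fit_exponential((grid[good], c[good]), quantiles=None)
    pl_fit = stats.fit_powerlaw((grid[good], c[good]), quantiles=None)
    assert pl_fit.r_squared > exp_fit.r_squared


def test_growth_timescale_recovers_exponential_rate():
    t = np.linspace(0, 1000, 50)
    c = 0.25  # <V> = exp((t/T)/c) with T the duration
    v = np.exp((t / 1000.0) / c)
    xi, ci, fit = stats.growth_timescale(t, v, duration=1000.0)
    assert xi == pytest.approx(c, rel=1e-6)
    assert ci[0] <= c <= ci[1]


def test_growth_timescale_flat_series_is_infinite():
    t = np.linspace(0, 100, 10)
    xi, _, fit = stats.growth_timescale(t, np.full(10, 2.0), duration=100.0)
    assert np.isinf(xi)
    assert fit.slope == pytest.approx(0.0, abs=1e-12)


def test_coarsening_collapse_algebraic_identity():
    """Series following <V>_p = (t/t0)^alpha exactly collapse to slope 1."""
    curves = {
        a: {t: (t / 100.0) ** a for t in np.geomspace(100, 10_000, 12)}
        for a in (0.25, 0.5, 1.0)
    }
    x, y, fit = stats.coarsening_collapse(curves, t0=100.0)
    assert fit.slope == pytest.approx(1.0, abs=1e-9)


def test_coarsening_collapse_detects_wrong_alpha():
    """Normalizing with alpha off by 2x leaves a systematic slope deviation."""
    curves = {0.5: {t: (t / 100.0) ** 0.25 for t in np.geomspace(100, 10_000, 12)}}
    _, _, fit = stats.coarsening_collapse(curves, t0=100.0)
    assert fit.slope == pytest.approx(0.5, abs=1e-9)


def test_detection_bias_exponential_shift():
    assert stats.detection_bias(1.5, 0.0) == (1.5, 0.0)
    mu, shift = stats.detection_bias(1.5, 0.5)
    assert mu == pytest.approx(1.0)
    # sampling oracle: truncated exponential mean = mu + v_min
    rng = np.random.default_rng(7)
    v = rng.exponential(1.0, size=300_000)
    observed = v[v > 0.5].mean()
    assert stats.detection_bias(observed, 0.5)[0] == pytest.approx(1.0, abs=0.02)


def test_summarize_bundles_everything():
    rng = np.random.default_rng(8)
    s = stats.summarize(rng.exponential(2.0, size=5000))
    assert s.n == 5000
    assert s.cv == pytest.approx(1.0, abs=0.06)
    assert s.exp_fit is not None and s.pl_fit is not None
    assert s.pdf_exponent == pytest.approx(s.pl_fit.slope - 1.0)
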