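"""Size-distribution statistics for condensate / sphere volume samples.

The central objects are per-cell (or per-replicate) lists of volumes and
their complementary cumulative distribution function, CCDF(V) = 1 − F(V)
with F(V) = ∫₀^V f(V′) dV′.  An exponential size law is linear on a
semi-log CCDF plot with slope −1/⟨V⟩; a power law f(V) ∝ V^k is linear on
a log–log CCDF plot with slope k̃ = k + 1 (pdf exponent = CCDF exponent
− 1).  To suppress cell-to-cell variation each cell's distribution is
rescaled by its own mean volume before averaging, so exponential
populations collapse onto exp(−v), i.e. semi-log slope −1.

Particle-weighted ("mass-weighted") moments,

    ⟨V⟩_p = ΣV²f / ΣVf,    σ_p² = ⟨V²⟩_p − ⟨V⟩_p²,

are less noisy than cluster-centric moments at fixed density; for an
exponential law σ_p² = ⟨V⟩_p²/2, so variance against mean on log–log axes
has slope 2 ("slope-2 law").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

__all__ = [
    "VolumeSample",
    "FitResult",
    "DistributionSummary",
    "ccdf",
    "ccdf_at",
    "rescale_and_average",
    "particle_moments",
    "cv",
    "fit_exponential",
    "fit_powerlaw",
    "pdf_exponent_from_ccdf",
    "growth_timescale",
    "coarsening_collapse",
    "detection_bias",
    "summarize",
]


@dataclass
class VolumeSample:
    """Volumes measured in one cell (or one simulation replicate)."""

    volumes: np.ndarray
    cell_id: str | int = 0
    time: float | None = None
    min_detectable: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.volumes, dtype=float).ravel()
        if v.size and (not np.all(np.isfinite(v)) or np.any(v <= 0)):
            raise ValueError("volumes must be positive and finite")
        self.volumes = v

    @property
    def n(self) -> int:
        return self.volumes.size

    @property
    def mean(self) -> float:
        return float(self.volumes.mean())


@dataclass
class FitResult:
    slope: float
    intercept: float
    ci: tuple[float, float]  # 95% CI on the slope
    r_squared: float
    f_pvalue: float  # F test against the constant (intercept-only) model
    n_points: int


def ccdf(sample: VolumeSample | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CCDF evaluated at the sorted sample points.

    Returns ``(v, c)`` with c_i = P(V > v_i) = (n − i)/n for the ascending
    order statistics (right-continuous step convention); c at the largest
    sample point is 0 and is dropped from fits but kept here.
    """
    v = sample.volumes if isinstance(sample, VolumeSample) else np.asarray(sample, float)
    if v.size == 0:
        raise ValueError("empty sample")
    v = np.sort(v)
    c = 1.0 - np.arange(1, v.size + 1) / v.size
    return v, c


def ccdf_at(sample: VolumeSample | np.ndarray, grid: np.ndarray) -> np.ndarray:
    """CCDF of the sample evaluated on an arbitrary grid, P(V > grid)."""
    v = sample.volumes if isinstance(sample, VolumeSample) else np.asarray(sample, float)
    v = np.sort(v)
    return 1.0 - np.searchsorted(v, grid, side="right") / v.size


def rescale_and_average(
    samples: list[VolumeSample],
    grid: np.ndarray | None = None,
    min_n: int = 1,
    n_grid: int = 64,
):
    """Mean-rescale each cell's CCDF and average over cells.

    Each cell's volumes are divided by that cell's mean; the rescaled
    CCDFs are evaluated on a common geometric grid over the pooled
    rescaled support and averaged, with s.e.m. over cells.  Returns
    ``(grid, mean_ccdf, sem, n_used)``.
    """
    kept = [s for s in samples if s.n >= min_n]
    n_excluded = len(samples) - len(kept)
    if n_excluded:
        warnings.warn(f"excluded {n_excluded} cells with fewer than {min_n} objects", stacklevel=2)
    if not kept:
        raise ValueError("no cells left after the minimum-size filter")
    rescaled = [s.volumes / s.mean for s in kept]
    if grid is None:
        pooled = np.concatenate(rescaled)
        grid = np.geomspace(pooled.min() * 0.999, pooled.max(), n_grid)
    curves = np.vstack([ccdf_at(r, grid) for r in rescaled])
    mean = curves.mean(axis=0)
    sem = curves.std(axis=0, ddof=1) / np.sqrt(len(kept)) if len(kept) > 1 else np.zeros_like(mean)
    return grid, mean, sem, len(kept)


def particle_moments(sample: VolumeSample | np.ndarray) -> tuple[float, float]:
    """Particle-weighted mean and central variance, (⟨V⟩_p, σ_p²)."""
    v = sample.volumes if isinstance(sample, VolumeSample) else np.asarray(sample, float)
    if v.size == 0:
        raise ValueError("empty sample")
    p_mean = float((v**2).sum() / v.sum())
    p_second = float((v**3).sum() / v.sum())
    return p_mean, p_second - p_mean**2


def cv(sample: VolumeSample | np.ndarray) -> float:
    """Coefficient of variation, sample standard deviation over mean."""
    v = sample.volumes if isinstance(sample, VolumeSample) else np.asarray(sample, float)
    if v.size < 2:
        raise ValueError("CV requires at least two observations")
    return float(v.std(ddof=1) / v.mean())


def _linfit(x: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None) -> FitResult:
    X = sm.add_constant(x)
    model = sm.WLS(y, X, weights=weights) if weights is not None else sm.OLS(y, X)
    res = model.fit()
    lo, hi = res.conf_int()[1]
    return FitResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        ci=(float(lo), float(hi)),
        r_squared=float(res.rsquared),
        f_pvalue=float(res.f_pvalue),
        n_points=len(x),
    )


def _window(v: np.ndarray, c: np.ndarray, v_lo, v_hi, quantiles):
    good = c > 0
    if quantiles is not None:
        # quantiles of the underlying sample == CCDF levels 1-q
        qlo, qhi = quantiles
        good &= (c <= 1.0 - qlo) & (c >= 1.0 - qhi)
    if v_lo is not None:
        good &= v >= v_lo
    if v_hi is not None:
        good &= v <= v_hi
    return v[good], c[good]


def fit_exponential(
    curve: tuple[np.ndarray, np.ndarray],
    *,
    quantiles: tuple[float, float] | None = (0.05, 0.95),
    v_lo: float | None = None,
    v_hi: float | None = None,
) -> FitResult:
    """Linear fit of ln CCDF against V (slope −1/⟨V⟩ for an exponential).

    By default the fit window is the [5%, 95%] quantile range of the
    support; an F test against the constant model is reported.
    """
    v, c = curve
    v, c = _window(np.asarray(v, float), np.asarray(c, float), v_lo, v_hi, quantiles)
    if len(np.unique(v)) < 3:
        raise ValueError("need at least 3 distinct support points to fit")
    return _linfit(v, np.log(c))


def fit_powerlaw(
    curve: tuple[np.ndarray, np.ndarray],
    *,
    quantiles: tuple[float, float] | None = (0.05, 0.95),
    v_lo: float | None = None,
    v_hi: float | None = None,
) -> FitResult:
    """Linear fit of log CCDF against log V; the slope is the CCDF
    exponent k̃ (pdf exponent k = k̃ − 1, see
    :func:`pdf_exponent_from_ccdf`).  Warns when the fitted support spans
    less than one decade."""
    v, c = curve
    v, c = _window(np.asarray(v, float), np.asarray(c, float), v_lo, v_hi, quantiles)
    if len(np.unique(v)) < 3:
        raise ValueError("need at least 3 distinct support points to fit")
    if v.max() / v.min() < 10.0:
        warnings.warn("power-law fit support spans less than one decade", stacklevel=2)
    return _linfit(np.log(v), np.log(c))


def pdf_exponent_from_ccdf(ccdf_exponent: float) -> float:
    """Probability-density exponent from the fitted CCDF exponent.

    Differentiating CCDF ∝ V^k̃ gives f(V) = −dCCDF/dV ∝ V^(k̃−1), so a
    CCDF exponent of −0.41 corresponds to a pdf exponent of −1.41.
    """
    return ccdf_exponent - 1.0


def growth_timescale(
    times: np.ndarray,
    mean_volumes: np.ndarray,
    duration: float,
) -> tuple[float, tuple[float, float], FitResult]:
    """Characteristic growth timescale ξ of the mean volume.

    Fits ln⟨V⟩ against time normalized by the run duration; ξ is the
    inverse slope, i.e. ⟨V⟩ ∝ exp((t/duration)/ξ).  Returns
    ``(xi, (xi_lo, xi_hi), fit)``; a non-growing series yields ξ = inf.
    """
    t = np.asarray(times, float) / duration
    y = np.log(np.asarray(mean_volumes, float))
    if t.size < 3:
        raise ValueError("need at least 3 time points")
    fit = _linfit(t, y)
    with np.errstate(divide="ignore"):
        # slopes at float-noise level mean "no growth": xi is infinite
        xi = 1.0 / fit.slope if fit.slope > 1e-9 else np.inf
        lo, hi = fit.ci
        xi_ci = (1.0 / hi if hi > 0 else np.inf, 1.0 / lo if lo > 0 else np.inf)
    return xi, xi_ci, fit


def coarsening_collapse(
    snapshots: dict[float, dict[float, float]] | list[tuple[float, float, float]],
    t0: float = 100.0,
) -> tuple[np.ndarray, np.ndarray, FitResult]:
    """Collapse particle-weighted mean growth curves across α.

    For each diffusive exponent α the theory predicts
    ⟨V(t)⟩_p ≈ ⟨V(t₀)⟩_p (t/t₀)^α, so plotting
    y = (⟨V(t)⟩_p / ⟨V(t₀)⟩_p)^(1/α) against x = t/t₀ on log–log axes
    collapses every α onto a single line of slope 1.

    ``snapshots`` maps α → {t: ⟨V(t)⟩_p} (or is a flat list of
    ``(alpha, t, p_mean)`` rows).  Returns (x, y, pooled slope fit).
    """
    if isinstance(snapshots, dict):
        rows = [(a, t, v) for a, series in snapshots.items() for t, v in series.items()]
    else:
        rows = list(snapshots)
    xs, ys = [], []
    alphas = sorted({r[0] for r in rows})
    for a in alphas:
        sub = sorted((t, v) for aa, t, v in rows if aa == a and t >= t0)
        if not sub:
            continue
        times = np.array([t for t, _ in sub], float)
        vols = np.array([v for _, v in sub], float)
        v0 = np.interp(t0, times, vols)
        xs.append(times / t0)
        ys.append((vols / v0) ** (1.0 / a))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    good = (x > 0) & (y > 0)
    fit = _linfit(np.log10(x[good]), np.log10(y[good]))
    return x, y, fit


def detection_bias(mean_observed: float, min_detectable: float) -> tuple[float, float]:
    """Correct the observed mean of an exponential population for a
    minimum detection size.

    By memorylessness of the exponential law, truncation at v_min shifts
    the observed mean by exactly v_min: E[V | V > v_min] = μ + v_min.
    Returns ``(mu_corrected, predicted_shift)``.
    """
    if min_detectable < 0:
        raise ValueError("min_detectable must be nonnegative")
    return mean_observed - min_detectable, min_detectable


@dataclass
class DistributionSummary:
    """One-stop summary of a volume sample's distribution shape."""

    n: int
    mean: float
    p_mean: float
    p_var: float
    cv: float
    exp_fit: FitResult | None = None
    pl_fit: FitResult | None = None
    pdf_exponent: float | None = None
    ccdf: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)


def summarize(sample: VolumeSample | np.ndarray, **fit_kwargs) -> DistributionSummary:
    """Compute the CCDF, moments, CV and both slope fits for one sample."""
    v = sample.volumes if isinstance(sample, VolumeSample) else np.asarray(sample, float)
    curve = ccdf(v)
    p_mean, p_var = particle_moments(v)
    exp_fit = pl_fit = None
    pdf_k = None
    try:
        exp_fit = fit_exponential(curve, **fit_kwargs)
    except ValueError:
        pass
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pl_fit = fit_powerlaw(curve, **fit_kwargs)
        pdf_k = pdf_exponent_from_ccdf(pl_fit.slope)
    except ValueError:
        pass
    return DistributionSummary(
        n=v.size,
        mean=float(v.mean()),
        p_mean=p_mean,
        p_var=p_var,
        cv=cv(v) if v.size > 1 else 0.0,
        exp_fit=exp_fit,
        pl_fit=pl_fit,
        pdf_exponent=pdf_k,
        ccdf=curve,
    )
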