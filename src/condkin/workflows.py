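"""End-to-end study procedures shared by the analysis drivers, the test
suite and the acceptance script.

Each function freezes one complete measurement: which simulations to run,
which snapshots to keep, and how the statistic is fitted.  Desk-scale
presets are used throughout (hundreds of spheres, 10⁴–4·10⁴ steps);
docs/methods.md discusses the problem sizes and selection rules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import stats
from .kernel import calibrate_K_alpha, chi_for_config
from .simulate import SimulationResult, injection_preset, quench_preset, run

__all__ = [
    "QUENCH_SNAPSHOTS",
    "quench_study",
    "quench_samples",
    "quench_exponential_fit",
    "quench_collapse_fit",
    "injection_study",
    "late_pooled_volumes",
    "ccdf_grid_fit_loglog",
    "ccdf_grid_fit_semilog",
    "monomer_partner_early_fraction",
    "injection_sweep_summary",
    "cv_chi_grid",
]

QUENCH_SNAPSHOTS = (100, 300, 1000, 3000, 9999)


def quench_study(
    alphas=(0.25, 0.5, 0.75, 1.0),
    seed: int = 0,
    *,
    scaled: bool = True,
    snapshot_times=QUENCH_SNAPSHOTS,
    **overrides,
) -> dict[float, SimulationResult]:
    """Quench-then-coalesce runs over a grid of diffusive exponents."""
    out = {}
    for i, a in enumerate(alphas):
        cfg = quench_preset(
            scaled=scaled, alpha=a, seed=seed + 1000 * i, snapshot_times=tuple(snapshot_times), **overrides
        )
        out[a] = run(cfg)
    return out


def quench_samples(
    result: SimulationResult,
    *,
    growth_min: float = 3.0,
    n_min: int = 15,
) -> list[stats.VolumeSample]:
    """Per-(replicate, time) volume samples from the coarsening regime.

    Snapshots are kept only once the mean volume has grown by at least
    ``growth_min`` over its initial value (so the distribution has
    forgotten the uniform initial condition) and while at least ``n_min``
    spheres remain (mean-rescaling with fewer objects is badly biased).
    """
    samples = []
    for i, rep in enumerate(result.replicates):
        v0 = rep.series.mean_volume.iloc[0]
        for t, vols in sorted(rep.snapshots.items()):
            if len(vols) >= n_min and vols.mean() / v0 >= growth_min:
                samples.append(stats.VolumeSample(vols, cell_id=(i, t), time=t))
    return samples


def quench_exponential_fit(
    results: dict[float, SimulationResult] | SimulationResult,
    **sample_kwargs,
):
    """Mean-rescaled averaged CCDF of the coarsening-regime snapshots and
    its semi-log slope (−1 for an exponential master curve).

    Returns ``(fit, n_curves, (grid, mean_ccdf, sem))``.
    """
    if isinstance(results, SimulationResult):
        results = {0: results}
    samples = []
    for res in results.values():
        samples.extend(quench_samples(res, **sample_kwargs))
    if not samples:
        raise ValueError("no snapshots passed the coarsening-regime selection")
    grid, mean, sem, n_used = stats.rescale_and_average(samples)
    fit = stats.fit_exponential((grid, mean))
    return fit, n_used, (grid, mean, sem)


def quench_collapse_fit(
    results: dict[float, SimulationResult],
    *,
    t0: float = 100.0,
    min_mean_alive: float = 5.0,
):
    """Coarsening-collapse slopes across α.

    The particle-weighted mean ⟨V(t)⟩_p (averaged over replicates) is kept
    from t₀ until the replicate-average alive count drops below
    ``min_mean_alive`` (beyond which growth saturates at the finite system
    size).  Each α's collapse curve (⟨V(t)⟩_p/⟨V(t₀)⟩_p)^(1/α) vs t/t₀ is
    fitted separately and the per-α slopes are averaged with equal weight:
    the 1/α transform stretches low-α curves over many more decades, so a
    single pooled regression would be dominated by the smallest α.

    Returns ``(per_alpha_fits, mean_slope, (x, y))``.
    """
    per_alpha: dict[float, stats.FitResult] = {}
    xs, ys = [], []
    for a, res in results.items():
        tables = [r.series[["step", "n_alive", "p_mean"]] for r in res.replicates]
        merged = pd.concat(tables).groupby("step").mean()
        good = merged[(merged.index >= t0) & (merged.n_alive >= min_mean_alive)]
        if len(good) < 3:
            continue
        curve = {a: dict(zip(good.index.to_numpy(float), good.p_mean.to_numpy(float)))}
        x, y, fit = stats.coarsening_collapse(curve, t0=t0)
        per_alpha[a] = fit
        xs.append(x)
        ys.append(y)
    if not per_alpha:
        raise ValueError("no α had a usable coarsening window")
    mean_slope = float(np.mean([f.slope for f in per_alpha.values()]))
    return per_alpha, mean_slope, (np.concatenate(xs), np.concatenate(ys))


def injection_study(
    injection_rate: float,
    seed: int = 0,
    *,
    scaled: bool = True,
    snapshot_fractions=tuple(np.arange(0.3, 1.0, 0.075)),
    **overrides,
) -> SimulationResult:
    """Steady-injection run with snapshots at fixed fractions of the
    duration (the last ~70% of the run, where the cascade between the
    injection scale and the largest clusters is quasi-steady)."""
    cfg = injection_preset(injection_rate, scaled=scaled, seed=seed, **overrides)
    snaps = tuple(sorted({int(f * cfg.duration) for f in snapshot_fractions}))
    cfg = injection_preset(
        injection_rate, scaled=scaled, seed=seed, snapshot_times=snaps, **overrides
    )
    return run(cfg)


def late_pooled_volumes(result: SimulationResult) -> np.ndarray:
    """Volumes pooled over replicates, late snapshots and the final state."""
    parts = [v for r in result.replicates for v in r.snapshots.values()]
    parts += [r.final_volumes for r in result.replicates]
    return np.concatenate(parts)


def ccdf_grid_fit_loglog(volumes: np.ndarray, n_grid: int = 32) -> stats.FitResult:
    """Log–log CCDF slope over the full support.

    The pooled CCDF is evaluated on a geometric grid (uniform density in
    log V, as on a log–log plot of a binned curve) and fitted by OLS; the
    slope is the CCDF exponent k̃, and k̃ − 1 the pdf exponent.
    """
    grid = np.geomspace(volumes.min(), volumes.max() * 0.999, n_grid)
    c = stats.ccdf_at(volumes, grid)
    good = c > 0
    return stats.fit_powerlaw((grid[good], c[good]), quantiles=None)


def ccdf_grid_fit_semilog(volumes: np.ndarray, n_grid: int = 32) -> stats.FitResult:
    """Semi-log CCDF slope over the full support (linear grid)."""
    grid = np.linspace(volumes.min(), volumes.max() * 0.999, n_grid)
    c = stats.ccdf_at(volumes, grid)
    good = c > 0
    return stats.fit_exponential((grid[good], c[good]), quantiles=None)


def monomer_partner_early_fraction(
    result: SimulationResult,
    early_fraction: float = 0.25,
) -> tuple[float, np.ndarray]:
    """Fraction of monomeric-sphere mergers whose partner's earliest
    ancestor was injected within the first ``early_fraction`` of the run.

    For every merger event, each never-merged partner contributes the
    *other* partner's earliest-ancestor injection time, normalized by the
    run duration.  Returns (replicate-mean fraction, per-replicate array).
    """
    fracs = []
    for r in result.replicates:
        e = r.events
        ages = np.concatenate(
            [
                e.loc[e.monomer1, "ancestor2"].to_numpy(float),
                e.loc[e.monomer2, "ancestor1"].to_numpy(float),
            ]
        )
        if len(ages) == 0:
            continue
        fracs.append(float(np.mean(ages / r.duration <= early_fraction)))
    fracs = np.asarray(fracs)
    return float(fracs.mean()), fracs


def injection_sweep_summary(
    rates=(0.01, 0.1, 1.0, 5.0),
    seed: int = 0,
    **overrides,
) -> pd.DataFrame:
    """CCDF shape statistics across an injection-rate sweep.

    For each J: pooled late-time volumes, log–log and semi-log full-support
    fits, replicate-mean CV and mean rescaled semi-log slope.
    """
    rows = []
    for i, J in enumerate(rates):
        res = injection_study(J, seed=seed + 100 * i, **overrides)
        pooled = late_pooled_volumes(res)
        fl = ccdf_grid_fit_loglog(pooled)
        fe = ccdf_grid_fit_semilog(pooled)
        cvs = [stats.cv(r.final_volumes) for r in res.replicates if len(r.final_volumes) >= 2]
        rows.append(
            dict(
                J=J,
                n_pooled=len(pooled),
                loglog_slope=fl.slope,
                loglog_r2=fl.r_squared,
                semilog_rescaled_slope=fe.slope * pooled.mean(),
                semilog_r2=fe.r_squared,
                cv=float(np.mean(cvs)),
                pdf_exponent=stats.pdf_exponent_from_ccdf(fl.slope),
            )
        )
    return pd.DataFrame(rows)


def cv_chi_grid(
    alphas=(0.5, 1.0),
    rates=(5.0, 0.5, 0.05),
    seed: int = 0,
    *,
    n_spheres: int = 200,
    n_replicates: int = 8,
    base_step: float = 0.5,
    calibration_kwargs: dict | None = None,
) -> pd.DataFrame:
    """CV, growth timescale ξ and χ over an (α, J) grid.

    K(α) is calibrated once per α from vanishing control simulations; each
    grid condition then yields the end-of-injection coefficient of
    variation, the fraction of never-merged spheres (to flag the
    monomer-dominated small-χ branch) and ξ from the growth of the mean.
    """
    calib = dict(
        n_spheres=150,
        n_steps=30_000,
        n_replicates=6,
        base_step=base_step,
        volume_fraction=0.05,
    )
    calib.update(calibration_kwargs or {})
    K = {}
    for a in alphas:
        K[a], _ = calibrate_K_alpha(a, seed=seed + 17, **calib)
    rows = []
    for ia, a in enumerate(alphas):
        for ij, J in enumerate(rates):
            res = injection_study(
                J,
                seed=seed + 31 * ia + 7 * ij,
                alpha=a,
                n_spheres=n_spheres,
                n_replicates=n_replicates,
                base_step=base_step,
            )
            cvs, monofracs, xis = [], [], []
            for r in res.replicates:
                v = r.final_volumes
                if len(v) >= 2:
                    cvs.append(stats.cv(v))
                # spheres that ever merged = monomers consumed across events
                n_ever_merged = int(r.events.monomer1.sum() + r.events.monomer2.sum())
                monofracs.append(1.0 - n_ever_merged / max(r.n_injected, 1))
                s = r.series[(r.series.step > 0) & np.isfinite(r.series.mean_volume)]
                if len(s) >= 3:
                    xi, _, _ = stats.growth_timescale(
                        s.step.to_numpy(), s.mean_volume.to_numpy(), r.duration
                    )
                    xis.append(xi)
            cp = chi_for_config(res.config, K[a])
            rows.append(
                dict(
                    alpha=a,
                    J=J,
                    K_alpha=K[a],
                    chi=cp.chi,
                    cv=float(np.mean(cvs)),
                    monomer_fraction=float(np.mean(monofracs)),
                    xi=float(np.median(xis)),
                )
            )
    return pd.DataFrame(rows)
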