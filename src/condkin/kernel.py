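"""Coagulation kernel and the injection-to-merger timescale ratio χ.

The pairwise collision rate of diffusing spheres is the Smoluchowski
coagulation kernel

    K(V₁, V₂) = 4π (D₁ + D₂)(R₁ + R₂),     V = (4/3)πR³.

For Stokes–Einstein diffusion (D ∝ 1/R) and equal sizes, K is constant —
mergers are "equal opportunity" and the size distribution stays
exponential.  When small spheres meet much larger ones (R₁ ≫ R₂), or when
D decays more slowly with size than 1/R, K grows with the larger radius
and mergers preferentially feed large spheres — the preferential
attachment that drives power-law size distributions.

Steady-injection conditions are organized by the dimensionless number

    χ = τ_inject / τ_merge = ρ² K(α) / j,

with ρ the total injected number density, j = J/V_sys the injection rate
density, τ_merge = 1/(K(α)ρ) and τ_inject = ρ/j.  χ ≫ 1 (slow injection)
gives power-law-like distributions; χ ≪ 1 gives exponential ones.  The
collision rate constant K(α) has no closed form for subdiffusion and is
calibrated from "vanishing" control simulations in which merged spheres
are reset to unit volume, so the pure monomer collision rate appears as
second-order decay of the sphere count, dc/dt = −K c²/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fbm import R_REF
from .simulate import SIZE_BIN_FACTOR, SimulationConfig, radius_of, run
from .stats import _linfit

__all__ = [
    "KernelEstimate",
    "ChiParameters",
    "smoluchowski_kernel",
    "estimate_kernel",
    "calibrate_K_alpha",
    "analytic_K_unit_spheres",
    "chi",
    "chi_for_config",
]


def smoluchowski_kernel(V1, V2, D1, D2):
    """Evaluate K(V₁,V₂) = 4π(D₁+D₂)(R₁+R₂) (vectorized)."""
    V1, V2, D1, D2 = map(np.asarray, (V1, V2, D1, D2))
    if np.any(V1 <= 0) or np.any(V2 <= 0) or np.any(D1 <= 0) or np.any(D2 <= 0):
        raise ValueError("volumes and diffusivities must be positive")
    return 4.0 * np.pi * (D1 + D2) * (radius_of(V1) + radius_of(V2))


@dataclass
class KernelEstimate:
    """Empirical coagulation kernel on logarithmic size bins."""

    bin_edges: np.ndarray  # volume bin edges, length m+1
    kernel_values: np.ndarray  # (m, m) symmetric, volume/time units
    counts: np.ndarray  # (m, m) number of events per bin pair
    n_skipped: int  # events with unrecorded size-class density
    system_volume: float
    duration: float

    @property
    def bin_centers(self) -> np.ndarray:
        return np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])

    def diagonal(self, min_events: int = 1) -> pd.DataFrame:
        """Equal-size kernel values against size (radius and volume)."""
        d = np.diag(self.kernel_values)
        c = np.diag(self.counts)
        keep = c >= min_events
        return pd.DataFrame(
            {
                "volume": self.bin_centers[keep],
                "radius": radius_of(self.bin_centers[keep]),
                "kernel": d[keep],
                "n_events": c[keep],
            }
        )


def estimate_kernel(
    events: pd.DataFrame,
    system_volume: float,
    duration: float,
    bin_edges: np.ndarray | None = None,
    replicate_column: str | None = "replicate",
) -> KernelEstimate:
    """Estimate K(V₁,V₂) from a merger-event log.

    Each event is weighted by 1/(f(V₁)f(V₂)) with f the instantaneous
    number density of the partner's size class (recorded at event time);
    weights are summed per bin pair, averaged over replicates, and
    normalized by system volume and duration.  Same-bin events carry an
    extra factor 2 because the pair rate within one size class is
    K f²/2.  Events whose recorded density is zero are skipped.
    """
    if len(events) == 0:
        raise ValueError("empty event log")
    v1 = events["v1"].to_numpy(float)
    v2 = events["v2"].to_numpy(float)
    f1 = events["f1"].to_numpy(float)
    f2 = events["f2"].to_numpy(float)
    ok = (f1 > 0) & (f2 > 0)
    n_skipped = int((~ok).sum())

    if bin_edges is None:
        vmin = min(v1[ok].min(), v2[ok].min())
        vmax = max(v1[ok].max(), v2[ok].max())
        n_bins = max(1, int(np.ceil(np.log(vmax / vmin) / np.log(SIZE_BIN_FACTOR))) + 1)
        bin_edges = vmin * SIZE_BIN_FACTOR ** np.arange(n_bins + 1)
    m = len(bin_edges) - 1

    if replicate_column is not None and replicate_column in events.columns:
        rep_ids = events[replicate_column].to_numpy()[ok]
        n_reps = len(np.unique(rep_ids))
    else:
        rep_ids = np.zeros(ok.sum(), dtype=int)
        n_reps = 1

    b1 = np.clip(np.digitize(v1[ok], bin_edges) - 1, 0, m - 1)
    b2 = np.clip(np.digitize(v2[ok], bin_edges) - 1, 0, m - 1)
    w = 1.0 / (f1[ok] * f2[ok])
    w = np.where(b1 == b2, 2.0 * w, w)

    total = np.zeros((m, m))
    counts = np.zeros((m, m))
    np.add.at(total, (b1, b2), w)
    np.add.at(total, (b2, b1), w)
    np.add.at(counts, (b1, b2), 1)
    np.add.at(counts, (b2, b1), 1)
    # the two scatters double the diagonal
    np.fill_diagonal(total, np.diag(total) / 2.0)
    np.fill_diagonal(counts, np.diag(counts) / 2.0)

    kernel = total / (n_reps * system_volume * duration)
    return KernelEstimate(
        bin_edges=np.asarray(bin_edges, float),
        kernel_values=kernel,
        counts=counts,
        n_skipped=n_skipped,
        system_volume=system_volume,
        duration=duration,
    )


def analytic_K_unit_spheres(base_step: float) -> float:
    """Smoluchowski rate constant for unit-volume spheres at the
    simulation's diffusivity.

    A per-dimension RMS step of Δr per unit time gives D = Δr²/2, so for
    two unit spheres K = 4π(2D)(2R_REF) = 8πΔr²R_REF.
    """
    D = base_step**2 / 2.0
    return float(4.0 * np.pi * (2 * D) * (2 * R_REF))


def calibrate_K_alpha(
    alpha: float,
    *,
    n_spheres: int = 200,
    volume_fraction: float = 0.05,
    base_step: float = 0.5,
    gamma: float = 1.0,
    n_steps: int = 20_000,
    n_replicates: int = 20,
    seed: int = 0,
    decay_window: tuple[float, float] = (0.2, 0.8),
) -> tuple[float, pd.DataFrame]:
    """Monomer collision rate constant K(α) from vanishing simulations.

    All spheres start (and stay) at volume 1; merged pairs are reset to
    unit volume so one partner effectively vanishes.  The concentration
    then obeys second-order kinetics, dc/dt = −K c²/2, i.e. 1/n(t) is
    linear in t with slope K/(2V_sys).  The fit uses the window where
    n(t) has decayed by ``decay_window`` (default 20–80%); a run with too
    few mergers to populate that window raises with guidance.

    Returns (K, per-replicate table with fitted K values).
    """
    if base_step == 0:
        return 0.0, pd.DataFrame({"replicate": [], "K": []})
    cfg = SimulationConfig(
        n_spheres=n_spheres,
        volume_fraction=volume_fraction,
        alpha=alpha,
        gamma=gamma,
        base_step=base_step,
        n_steps=n_steps,
        n_replicates=n_replicates,
        seed=seed,
        vanishing=True,
        series_stride=max(1, n_steps // 2000),
    )
    result = run(cfg)
    V_sys = cfg.system_volume
    lo_frac, hi_frac = decay_window
    rows = []
    for i, rep in enumerate(result.replicates):
        s = rep.series
        n0 = s.n_alive.iloc[0]
        n = s.n_alive.to_numpy(float)
        t = s.step.to_numpy(float)
        inside = (n <= (1 - lo_frac) * n0) & (n >= (1 - hi_frac) * n0) & (n >= 2)
        if inside.sum() < 3:
            raise RuntimeError(
                "too few mergers to fit the decay window; lengthen the run "
                "(n_steps) or increase base_step/volume_fraction"
            )
        fit = _linfit(t[inside], 1.0 / n[inside])
        rows.append((i, 2.0 * V_sys * fit.slope))
    table = pd.DataFrame(rows, columns=["replicate", "K"])
    return float(table.K.mean()), table


@dataclass(frozen=True)
class ChiParameters:
    """χ and the two timescales it compares."""

    rho: float  # injected spheres per system volume
    j: float  # injection rate per volume, J/V_sys
    K_alpha: float  # calibrated collision rate constant
    chi: float
    tau_inject: float  # ρ/j
    tau_merge: float  # 1/(K(α)ρ)


def chi(rho: float, j: float, K_alpha: float) -> ChiParameters:
    """χ = τ_inject/τ_merge = ρ²K(α)/j (all inputs strictly positive)."""
    if rho <= 0 or j <= 0 or K_alpha <= 0:
        raise ValueError("rho, j and K_alpha must all be positive (χ undefined otherwise)")
    tau_inject = rho / j
    tau_merge = 1.0 / (K_alpha * rho)
    return ChiParameters(
        rho=rho,
        j=j,
        K_alpha=K_alpha,
        chi=tau_inject / tau_merge,
        tau_inject=tau_inject,
        tau_merge=tau_merge,
    )


def chi_for_config(config: SimulationConfig, K_alpha: float) -> ChiParameters:
    """χ of an injection-mode configuration (ρ = total injected count per
    system volume, per the definition of τ_inject)."""
    if config.injection_rate is None:
        raise ValueError("chi is defined for injection-mode configurations")
    V = config.system_volume
    return chi(config.n_spheres / V, config.injection_rate / V, K_alpha)
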