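"""Fractional Brownian motion trajectories for (sub)diffusive spheres.

Sphere motion is modelled as fractional Brownian motion (fBm) with
ensemble mean-squared displacement ⟨r²⟩ = 2 d D τ^α in d = 3 dimensions,
where α is the anomalous exponent (α = 1 is ordinary diffusion, α < 1 is
subdiffusion as is typical for chromatin-embedded condensates).  An fBm
process with MSD ∝ τ^α corresponds to Hurst exponent H = α/2.

Increments (fractional Gaussian noise) are synthesized with the exact
circulant-embedding method of Davies & Harte: the fGn autocovariance is
embedded in a circulant matrix whose eigenvalues are obtained by FFT, and
one FFT of complex Gaussian weights yields a sample path with exactly the
target covariance.  The statistical law is all that matters downstream, so
any exact synthesis route is equivalent.

Trajectories are pre-synthesized for a sphere's whole lifetime so that the
long-range increment correlations of fBm are preserved across time; the
per-step displacement is rescaled on the fly by the sphere's current
radius R through D = D0 / R^γ (see :func:`scaled_step`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["R_REF", "FbmTrajectory", "fgn", "synthesize_trajectory", "scaled_step"]

#: Radius of a sphere of unit volume, V = (4/3)πR³ = 1.  Diffusion-coefficient
#: scaling is referenced to this radius: a sphere of radius R_REF takes
#: unscaled steps.
R_REF: float = (3.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


@dataclass
class FbmTrajectory:
    """Pre-synthesized 3D fBm increment stream for one sphere.

    increments[i] is the unscaled displacement taken between step i and
    step i+1 by a sphere of reference radius ``R_REF``; each spatial
    component has RMS ``base_step``.
    """

    increments: np.ndarray  # (n_steps, 3)
    alpha: float
    base_step: float
    n_steps: int = field(init=False)

    def __post_init__(self) -> None:
        self.increments = np.asarray(self.increments, dtype=float)
        if self.increments.ndim != 2 or self.increments.shape[1] != 3:
            raise ValueError("increments must have shape (n_steps, 3)")
        self.n_steps = self.increments.shape[0]


def _circulant_eigenvalues(n: int, hurst: float) -> np.ndarray:
    """Eigenvalues of the circulant embedding of the fGn covariance."""
    k = np.arange(n + 1, dtype=float)
    # fGn autocovariance for unit-variance increments
    gamma = 0.5 * (
        np.abs(k + 1) ** (2 * hurst)
        - 2 * np.abs(k) ** (2 * hurst)
        + np.abs(k - 1) ** (2 * hurst)
    )
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # length 2n
    lam = np.fft.fft(row).real
    # Negative eigenvalues of magnitude ~1e-15 arise from round-off; the
    # embedding is provably nonnegative-definite for 0 < H <= 1.
    lam = np.clip(lam, 0.0, None)
    return lam


def fgn(
    n_steps: int,
    hurst: float,
    rng: np.random.Generator,
    n_series: int = 1,
) -> np.ndarray:
    """Sample ``n_series`` independent unit-variance fGn series of length
    ``n_steps`` with Hurst exponent ``hurst`` (shape ``(n_series, n_steps)``).

    H = 0.5 short-circuits to i.i.d. standard normals (exact and cheaper).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if not 0.0 < hurst <= 1.0:
        raise ValueError(f"Hurst exponent must be in (0, 1], got {hurst}")
    if hurst == 0.5:
        return rng.standard_normal((n_series, n_steps))
    if n_steps == 1:
        return rng.standard_normal((n_series, 1))

    n = n_steps
    m = 2 * n
    lam = _circulant_eigenvalues(n, hurst)

    # Hermitian complex Gaussian weights -> real stationary series.
    a = rng.standard_normal((n_series, m))
    b = rng.standard_normal((n_series, m))
    w = np.empty((n_series, m), dtype=complex)
    w[:, 0] = np.sqrt(lam[0] / m) * a[:, 0]
    w[:, n] = np.sqrt(lam[n] / m) * a[:, n]
    k = np.arange(1, n)
    scale = np.sqrt(lam[k] / (2 * m))
    w[:, k] = scale * (a[:, k] + 1j * b[:, k])
    w[:, m - k] = np.conj(w[:, k])
    series = np.fft.fft(w, axis=1).real[:, :n]
    return series


def synthesize_trajectory(
    n_steps: int,
    alpha: float,
    base_step: float,
    seed: int | np.random.Generator,
) -> FbmTrajectory:
    """Synthesize one 3D fBm trajectory of ``n_steps`` increments.

    The three spatial components are independent fGn streams with Hurst
    exponent H = α/2 (isotropic motion), each scaled so the RMS single-step
    displacement per dimension equals ``base_step``.  Deterministic given
    ``seed``.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if base_step < 0:
        raise ValueError("base_step must be nonnegative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    incs = fgn(n_steps, alpha / 2.0, rng, n_series=3).T * base_step
    return FbmTrajectory(increments=incs, alpha=alpha, base_step=base_step)


def scaled_step(
    traj: FbmTrajectory,
    step_index: int,
    radius: float,
    gamma: float,
) -> np.ndarray:
    """Displacement at ``step_index`` for a sphere of the given radius.

    The diffusion coefficient scales with size as D = D0 / R^γ (γ = 1 is
    Stokes–Einstein; γ < 0 makes spheres accelerate as they grow).  Since
    displacement RMS goes as sqrt(D), the precomputed increment is
    multiplied by (R_REF / radius)^(γ/2).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    factor = step_scale(radius, gamma)
    return traj.increments[step_index] * factor


def step_scale(radius, gamma: float):
    """Vectorizable step-size factor (R_REF / R)^(γ/2)."""
    return (R_REF / np.asarray(radius)) ** (gamma / 2.0)
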