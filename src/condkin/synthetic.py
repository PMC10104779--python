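"""Ground-truth generators: volume populations, rendered 3D stacks and
well-mixed coagulation event logs.

These stand in for microscopy data, providing every input the analysis
pipeline consumes with the generating law known exactly:

* per-cell volume populations under exponential, bounded power-law or
  uniform laws, with lognormal cell-to-cell variation of the mean and an
  optional detection floor (truncation);
* noisy 3D image stacks of voxelized bright spheres over Gaussian
  background, with the true region table attached;
* merger-event logs from an exact (Gillespie) stochastic simulation of a
  prescribed coagulation kernel on a well-mixed population — the
  independent oracle for the empirical kernel estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segmentation import ImageStack
from .simulate import _LOG_BIN, radius_of
from .stats import VolumeSample

__all__ = [
    "PopulationSpec",
    "RenderSpec",
    "sample_volumes",
    "sample_population",
    "render_stack",
    "synthetic_event_log",
]


@dataclass(frozen=True)
class PopulationSpec:
    """A per-cell volume population with known law.

    law: ``("exponential", mean)`` | ``("powerlaw", k, v_min, v_max)``
    (pdf exponent k < 0, bounded support) | ``("uniform", a, b)``.
    ``cell_mean_cv`` sets a lognormal spread of the per-cell mean scale.
    """

    law: tuple = ("exponential", 1.0)
    n_per_cell: int = 100
    n_cells: int = 1
    cell_mean_cv: float = 0.0
    detection_floor: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        name = self.law[0]
        if name == "exponential":
            if self.law[1] <= 0:
                raise ValueError("exponential mean must be positive")
        elif name == "powerlaw":
            _, k, v_min, v_max = self.law
            if k >= 0:
                raise ValueError("power-law pdf exponent must be negative")
            if not 0 < v_min < v_max:
                raise ValueError("need 0 < v_min < v_max")
        elif name == "uniform":
            _, a, b = self.law
            if not 0 <= a < b:
                raise ValueError("need 0 <= a < b")
        else:
            raise ValueError(f"unknown law {name!r}")
        if self.n_per_cell < 1 or self.n_cells < 1:
            raise ValueError("n_per_cell and n_cells must be >= 1")


def _draw(law: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    name = law[0]
    if name == "exponential":
        return rng.exponential(law[1], size=n)
    if name == "uniform":
        return rng.uniform(law[1], law[2], size=n)
    # bounded power law f(V) ∝ V^k on [v_min, v_max] by inverse transform
    _, k, v_min, v_max = law
    u = rng.uniform(size=n)
    if k == -1.0:
        return v_min * (v_max / v_min) ** u
    a = k + 1.0
    return (v_min**a + u * (v_max**a - v_min**a)) ** (1.0 / a)


def sample_volumes(law: tuple, n: int, rng: np.random.Generator, floor: float = 0.0) -> np.ndarray:
    """Draw n volumes from the law, truncated below ``floor`` (objects
    smaller than the detection floor are never observed)."""
    out = np.empty(0)
    while out.size < n:
        batch = _draw(law, max(n - out.size, 16) * 2, rng)
        out = np.concatenate([out, batch[batch > floor]])
    return out[:n]


def sample_population(spec: PopulationSpec) -> list[VolumeSample]:
    """Generate one VolumeSample per cell under the spec's law."""
    rng = np.random.default_rng(spec.seed)
    samples = []
    for c in range(spec.n_cells):
        scale = 1.0
        if spec.cell_mean_cv > 0:
            sigma = np.sqrt(np.log1p(spec.cell_mean_cv**2))
            scale = rng.lognormal(-0.5 * sigma**2, sigma)
        v = scale * sample_volumes(spec.law, spec.n_per_cell, rng, spec.detection_floor / scale if scale else 0.0)
        samples.append(
            VolumeSample(volumes=v, cell_id=c, min_detectable=spec.detection_floor or None)
        )
    return samples


@dataclass(frozen=True)
class RenderSpec:
    """Geometry and noise model of a rendered single-cell z-stack."""

    shape: tuple[int, int, int] = (32, 128, 128)  # (z, y, x) voxels
    voxel_size: tuple[float, float, float] = (0.3, 0.1, 0.1)  # µm, (z, y, x)
    background_mean: float = 100.0
    background_sd: float = 5.0
    foreground: float = 200.0
    max_placement_tries: int = 200

    @property
    def snr(self) -> float:
        return (self.foreground - self.background_mean) / self.background_sd


def _voxelize(center: np.ndarray, volume: float, spec: RenderSpec) -> tuple[np.ndarray, int]:
    """Voxel indices covered by a sphere, with a volume-conserving
    effective radius: the nominal radius is bisected so that
    (voxel count) × (voxel volume) best matches the requested volume."""
    vz, vy, vx = spec.voxel_size
    voxvol = vz * vy * vx
    r_nom = radius_of(volume)
    zz = np.arange(spec.shape[0]) * vz
    yy = np.arange(spec.shape[1]) * vy
    xx = np.arange(spec.shape[2]) * vx
    # distances from sphere centre on the voxel-centre grid, physical units
    dz = (zz - center[0])[:, None, None]
    dy = (yy - center[1])[None, :, None]
    dx = (xx - center[2])[None, None, :]
    d2 = dz**2 + dy**2 + dx**2
    target = volume / voxvol
    lo, hi = 0.5 * r_nom, 2.0 * r_nom
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        cnt = int((d2 <= mid**2).sum())
        if cnt < target:
            lo = mid
        else:
            hi = mid
    r_eff = 0.5 * (lo + hi)
    mask = d2 <= r_eff**2
    return mask, int(mask.sum())


def render_stack(
    volumes: np.ndarray,
    spec: RenderSpec,
    seed: int | np.random.Generator,
    cell_id: str | int = 0,
) -> tuple[ImageStack, pd.DataFrame]:
    """Render spheres into a noisy stack; returns (stack, ground truth).

    Spheres are placed uniformly at random without mutual overlap, kept
    clear of the stack faces; Gaussian background noise is added
    everywhere.  The ground-truth table lists each sphere's centre,
    requested volume and realized voxel count.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    vz, vy, vx = spec.voxel_size
    extent = np.array([spec.shape[0] * vz, spec.shape[1] * vy, spec.shape[2] * vx])
    img = np.zeros(spec.shape, dtype=float)
    placed: list[tuple[np.ndarray, float]] = []
    rows = []
    for i, vol in enumerate(np.asarray(volumes, float)):
        r = radius_of(vol)
        if np.any(2.2 * r >= extent):
            raise ValueError("sphere too large for the stack; use a larger shape")
        ok = False
        for _ in range(spec.max_placement_tries):
            c = rng.uniform(1.1 * r, extent - 1.1 * r)
            if all(np.linalg.norm(c - pc) > 1.05 * (r + pr) for pc, pr in placed):
                ok = True
                break
        if not ok:
            raise RuntimeError(
                "could not place all spheres without overlap; use a larger stack"
            )
        mask, cnt = _voxelize(c, vol, spec)
        img[mask] = spec.foreground
        placed.append((c, r))
        rows.append((i, c[0], c[1], c[2], vol, cnt, cnt * vz * vy * vx))
    img += rng.normal(spec.background_mean, spec.background_sd, size=spec.shape)
    img = np.clip(img, 0.0, None)
    truth = pd.DataFrame(
        rows, columns=["sphere", "z", "y", "x", "volume_true", "voxels", "volume_voxelized"]
    )
    stack = ImageStack(voxels=img, voxel_size=spec.voxel_size, cell_id=cell_id)
    return stack, truth


def synthetic_event_log(
    kernel,
    volumes: np.ndarray,
    duration: float,
    seed: int | np.random.Generator,
    system_volume: float = 1.0,
) -> pd.DataFrame:
    """Exact (Gillespie) stochastic simulation of well-mixed coagulation.

    ``kernel`` is either a constant or a callable K(V1, V2); the pairwise
    merger propensity is K/V_sys.  Events are recorded in the same layout
    as the Monte Carlo event log (v1, v2, time, and instantaneous
    log-binned size-class number densities f1, f2), so the empirical
    kernel estimator can be validated against the known truth.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    kfun = kernel if callable(kernel) else (lambda a, b, k=float(kernel): k)
    vols = list(np.asarray(volumes, float))
    t = 0.0
    rows = []
    while len(vols) >= 2:
        v = np.asarray(vols)
        K = np.array([[kfun(a, b) for b in v] for a in v])
        iu = np.triu_indices(len(v), k=1)
        props = K[iu] / system_volume
        total = props.sum()
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t > duration:
            break
        pick = rng.choice(len(props), p=props / total)
        i, j = iu[0][pick], iu[1][pick]
        bins = np.floor(np.log(v) / _LOG_BIN)
        f1 = np.count_nonzero(bins == bins[i]) / system_volume
        f2 = np.count_nonzero(bins == bins[j]) / system_volume
        rows.append((t, v[i], v[j], f1, f2, v.mean(), len(v)))
        vols[i] = vols[i] + vols[j]
        del vols[j]
    return pd.DataFrame(
        rows, columns=["step", "v1", "v2", "f1", "f2", "mean_volume", "n_alive"]
    )
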