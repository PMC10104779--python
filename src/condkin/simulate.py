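"""Monte Carlo coalescence simulations of condensates in a periodic box.

Spheres move by fractional Brownian motion in a 3D box with periodic
boundaries and merge on contact, conserving volume (the merged sphere is
placed at the volume-weighted centre of mass of the pair).  Two modes:

* **quench** — all N spheres nucleate at t = 0 with volumes uniform on
  ``v0_range`` and coarsen by coalescence only (models a fast quench, e.g.
  condensate re-formation after mitosis or light-activated nucleation);
* **injection** — the box starts empty and spheres appear at a steady rate
  of J per step until N have been injected (models continuous production
  of aggregating material, e.g. polyQ aggregates).

The box length is set by the target volume fraction, v_f = N·v̄0/L³.
Diffusion is size dependent, D = D0/R^γ (γ = 1 is Stokes–Einstein), and
subdiffusion enters through the fBm exponent α (MSD ∝ τ^α).

Every merger is logged as a :class:`MergerEvent` row carrying the partner
volumes, monomer flags, earliest-injected-ancestor steps, and the
instantaneous number densities of the two size classes — everything the
empirical coagulation-kernel estimator needs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .fbm import R_REF, fgn, step_scale

__all__ = [
    "SimulationConfig",
    "SphereSet",
    "MergerEvent",
    "ReplicateResult",
    "SimulationResult",
    "radius_of",
    "initialize_quench",
    "merge_pair",
    "step",
    "inject",
    "injection_schedule",
    "run",
    "run_replicate",
    "resolve_overlaps",
    "quench_preset",
    "injection_preset",
]

#: Log-bin width factor for instantaneous size-class number densities.
SIZE_BIN_FACTOR = 1.5
_LOG_BIN = np.log(SIZE_BIN_FACTOR)


def radius_of(volume):
    """Sphere radius from volume, V = (4/3)πR³."""
    return (3.0 * np.asarray(volume) / (4.0 * np.pi)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulation condition (all in simulation units:
    one Monte Carlo step = one time unit, initial volumes O(1))."""

    n_spheres: int = 1000
    v0_range: tuple[float, float] = (1.0, 2.0)
    volume_fraction: float = 0.05
    alpha: float = 1.0
    gamma: float = 1.0
    base_step: float = 0.5
    injection_rate: float | None = None  # None -> quench mode
    n_steps: int = 100_000
    n_replicates: int = 20
    seed: int = 0
    box_length: float | None = None  # derived from volume_fraction if None
    vanishing: bool = False  # merged spheres reset to volume 1 (K(α) control)
    inherit: str = "larger"  # trajectory inheritance: "larger" | "random"
    log_initial_mergers: bool = False
    snapshot_times: tuple[int, ...] | None = None
    series_stride: int | None = None  # cadence of the ⟨V⟩(t) series

    def __post_init__(self) -> None:
        if self.n_spheres < 1:
            raise ValueError("n_spheres must be >= 1")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.volume_fraction <= 0:
            raise ValueError("volume_fraction must be positive")
        if not self.v0_range[0] < self.v0_range[1]:
            raise ValueError("v0_range must be an increasing interval")
        if self.base_step < 0:
            raise ValueError("base_step must be nonnegative")
        if self.injection_rate is not None and self.injection_rate <= 0:
            raise ValueError("injection_rate must be positive (or None for quench)")
        if self.inherit not in ("larger", "random"):
            raise ValueError("inherit must be 'larger' or 'random'")

    @property
    def mode(self) -> str:
        return "quench" if self.injection_rate is None else "inject"

    @property
    def mean_v0(self) -> float:
        return 0.5 * (self.v0_range[0] + self.v0_range[1])

    @property
    def L(self) -> float:
        """Box side length: from v_f = N·v̄0/L³ unless given explicitly."""
        if self.box_length is not None:
            return self.box_length
        return (self.n_spheres * self.mean_v0 / self.volume_fraction) ** (1.0 / 3.0)

    @property
    def system_volume(self) -> float:
        return self.L**3

    @property
    def duration(self) -> int:
        """Effective number of steps actually simulated."""
        if self.mode == "quench":
            return self.n_steps
        last = injection_schedule(self.n_spheres, self.injection_rate)[-1]
        return min(self.n_steps, int(last) + 1)


def injection_schedule(n_spheres: int, rate: float) -> np.ndarray:
    """Injection step of each sphere: sphere k enters at floor(k / J).

    Reproduces the stated stride semantics: J = 0.25 injects one sphere at
    every fourth step (0, 4, 8, ...); J = 4 injects four spheres per step.
    """
    return np.floor(np.arange(n_spheres) / rate).astype(np.int64)


@dataclass
class SphereSet:
    """State of all spheres at one time step (dead rows retained)."""

    positions: np.ndarray  # (n, 3) in [0, L)
    volumes: np.ndarray  # (n,)
    alive: np.ndarray  # (n,) bool
    injected_at: np.ndarray  # (n,) int
    ancestor_injection: np.ndarray  # (n,) int, earliest in merger history
    n_mergers: np.ndarray  # (n,) int, 0 -> monomeric
    box_length: float
    trajectories: np.ndarray | None = None  # (n, T, 3) fBm increments, abs time

    @property
    def radii(self) -> np.ndarray:
        return radius_of(self.volumes)

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())

    @property
    def total_volume(self) -> float:
        return float(self.volumes[self.alive].sum())


@dataclass
class MergerEvent:
    """One coalescence record (v1 is the surviving-trajectory parent)."""

    step: int
    v1: float
    v2: float
    monomer1: bool
    monomer2: bool
    ancestor1: int
    ancestor2: int
    f1: float  # number density of v1's size class at the event
    f2: float
    mean_volume: float  # mean alive volume just before the merger
    n_alive: int


def _min_image(delta: np.ndarray, L: float) -> np.ndarray:
    return delta - L * np.round(delta / L)


def _wrap(pos: np.ndarray, L: float) -> np.ndarray:
    pos = np.mod(pos, L)
    # guard the half-open interval against round-off at the boundary
    pos[pos >= L] = 0.0
    return pos


def _size_class_density(volumes_alive: np.ndarray, v1: float, v2: float, system_volume: float):
    """Instantaneous number densities f(V1), f(V2) on logarithmic size bins."""
    bins = np.floor(np.log(volumes_alive) / _LOG_BIN)
    b1 = np.floor(np.log(v1) / _LOG_BIN)
    b2 = np.floor(np.log(v2) / _LOG_BIN)
    f1 = np.count_nonzero(bins == b1) / system_volume
    f2 = np.count_nonzero(bins == b2) / system_volume
    return f1, f2


def merge_pair(
    state: SphereSet,
    i: int,
    j: int,
    t: int,
    rng: np.random.Generator,
    *,
    inherit: str = "larger",
    vanishing: bool = False,
    events: list[MergerEvent] | None = None,
) -> int:
    """Merge spheres ``i`` and ``j`` in place; return the survivor index.

    The merged sphere conserves volume (V = V1 + V2) and sits at the
    volume-weighted centre of mass of the pair under the minimum-image
    convention; it inherits the trajectory of one parent (the larger one by
    default).  In vanishing mode the merged volume is reset to 1 so that
    one sphere effectively disappears (collision-rate control runs).
    """
    if not (state.alive[i] and state.alive[j]):
        raise RuntimeError("attempted to merge a dead sphere")
    L = state.box_length
    va, vb = float(state.volumes[i]), float(state.volumes[j])

    if inherit == "larger":
        keep, drop = (i, j) if va >= vb else (j, i)
    else:
        keep, drop = (i, j) if rng.random() < 0.5 else (j, i)

    if events is not None:
        vols_alive = state.volumes[state.alive]
        f1, f2 = _size_class_density(
            vols_alive, float(state.volumes[keep]), float(state.volumes[drop]), L**3
        )
        events.append(
            MergerEvent(
                step=t,
                v1=float(state.volumes[keep]),
                v2=float(state.volumes[drop]),
                monomer1=bool(state.n_mergers[keep] == 0),
                monomer2=bool(state.n_mergers[drop] == 0),
                ancestor1=int(state.ancestor_injection[keep]),
                ancestor2=int(state.ancestor_injection[drop]),
                f1=f1,
                f2=f2,
                mean_volume=float(vols_alive.mean()),
                n_alive=int(len(vols_alive)),
            )
        )

    delta = _min_image(state.positions[drop] - state.positions[keep], L)
    w = state.volumes[drop] / (state.volumes[keep] + state.volumes[drop])
    com = state.positions[keep] + w * delta
    state.positions[keep] = _wrap(com[None, :], L)[0]
    state.volumes[keep] = 1.0 if vanishing else va + vb
    state.alive[drop] = False
    state.ancestor_injection[keep] = min(
        state.ancestor_injection[i], state.ancestor_injection[j]
    )
    state.n_mergers[keep] = state.n_mergers[i] + state.n_mergers[j] + 1
    return keep


def _overlap_pairs_bruteforce(state: SphereSet) -> list[tuple[int, int]]:
    """All overlapping alive pairs by O(n²) minimum-image audit (oracle)."""
    idx = np.flatnonzero(state.alive)
    if len(idx) < 2:
        return []
    pos = state.positions[idx]
    rad = state.radii[idx]
    L = state.box_length
    delta = _min_image(pos[None, :, :] - pos[:, None, :], L)
    dist = np.sqrt((delta**2).sum(axis=2))
    thresh = rad[None, :] + rad[:, None]
    a, b = np.nonzero(np.triu(dist <= thresh, k=1))
    return sorted((int(idx[x]), int(idx[y])) for x, y in zip(a, b))


def _overlap_pairs_celllist(state: SphereSet) -> list[tuple[int, int]]:
    """Overlapping alive pairs via a periodic k-d tree (cell-list style)."""
    idx = np.flatnonzero(state.alive)
    if len(idx) < 2:
        return []
    pos = state.positions[idx]
    rad = state.radii[idx]
    L = state.box_length
    rmax = float(rad.max())
    cutoff = 2.0 * rmax
    if cutoff >= L / 2.0:
        return _overlap_pairs_bruteforce(state)
    tree = cKDTree(pos, boxsize=L)
    cand = tree.query_pairs(cutoff, output_type="ndarray")
    if len(cand) == 0:
        return []
    delta = _min_image(pos[cand[:, 0]] - pos[cand[:, 1]], L)
    dist = np.sqrt((delta**2).sum(axis=1))
    keep = dist <= rad[cand[:, 0]] + rad[cand[:, 1]]
    pairs = [
        (int(idx[a]), int(idx[b])) if idx[a] < idx[b] else (int(idx[b]), int(idx[a]))
        for a, b in cand[keep]
    ]
    return sorted(pairs)


def _pairs_touching(state: SphereSet, s: int) -> list[tuple[int, int]]:
    """Alive spheres overlapping sphere ``s`` (after a merger)."""
    idx = np.flatnonzero(state.alive)
    idx = idx[idx != s]
    if len(idx) == 0:
        return []
    delta = _min_image(state.positions[idx] - state.positions[s], state.box_length)
    dist = np.sqrt((delta**2).sum(axis=1))
    rs = radius_of(state.volumes[s])
    hit = idx[dist <= rs + radius_of(state.volumes[idx])]
    return sorted((min(int(h), s), max(int(h), s)) for h in hit)


def resolve_overlaps(
    state: SphereSet,
    t: int,
    rng: np.random.Generator,
    *,
    inherit: str = "larger",
    vanishing: bool = False,
    events: list[MergerEvent] | None = None,
    detector: str = "celllist",
) -> int:
    """Iteratively merge overlapping pairs until none remain.

    Pairs are resolved one at a time by uniform random selection among the
    currently overlapping pairs (seeded), including chains created by the
    mergers themselves.  Returns the number of mergers performed.
    """
    finder = _overlap_pairs_celllist if detector == "celllist" else _overlap_pairs_bruteforce
    pairs = finder(state)
    n_merged = 0
    while pairs:
        k = int(rng.integers(len(pairs)))
        i, j = pairs.pop(k)
        s = merge_pair(
            state, i, j, t, rng, inherit=inherit, vanishing=vanishing, events=events
        )
        dead = j if s == i else i
        pairs = [p for p in pairs if i not in p and j not in p]
        pairs = sorted(set(pairs) | set(_pairs_touching(state, s)))
        n_merged += 1
    return n_merged


def _new_state(n: int, L: float) -> SphereSet:
    return SphereSet(
        positions=np.zeros((n, 3)),
        volumes=np.zeros(n),
        alive=np.zeros(n, dtype=bool),
        injected_at=np.zeros(n, dtype=np.int64),
        ancestor_injection=np.zeros(n, dtype=np.int64),
        n_mergers=np.zeros(n, dtype=np.int64),
        box_length=L,
    )


def initialize_quench(
    config: SimulationConfig,
    rng: np.random.Generator,
    *,
    events: list[MergerEvent] | None = None,
) -> SphereSet:
    """Place N spheres uniformly in the box with volumes uniform on
    ``v0_range`` and merge away all initial overlaps before step 0."""
    n = config.n_spheres
    state = _new_state(n, config.L)
    state.positions[:] = rng.uniform(0.0, config.L, size=(n, 3))
    state.volumes[:] = rng.uniform(*config.v0_range, size=n)
    if config.vanishing:
        state.volumes[:] = 1.0
    state.alive[:] = True
    resolve_overlaps(
        state,
        0,
        rng,
        inherit=config.inherit,
        vanishing=config.vanishing,
        events=events if config.log_initial_mergers else None,
    )
    if state.n_alive == 1:
        warnings.warn(
            "initial overlap resolution collapsed the system to a single sphere; "
            "volume fraction is too high for a meaningful quench",
            stacklevel=2,
        )
    return state


def inject(
    state: SphereSet,
    t: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    n_injected_so_far: int,
    *,
    events: list[MergerEvent] | None = None,
) -> int:
    """Inject the spheres scheduled for step ``t``; returns the new total.

    New spheres get uniform random positions, volumes uniform on
    ``v0_range`` and fresh trajectories; overlaps created by injection are
    resolved by merging immediately.
    """
    schedule = injection_schedule(config.n_spheres, config.injection_rate)
    due = np.flatnonzero(schedule == t)
    due = due[due >= n_injected_so_far]
    for k in due:
        state.positions[k] = rng.uniform(0.0, config.L, size=3)
        state.volumes[k] = 1.0 if config.vanishing else rng.uniform(*config.v0_range)
        state.alive[k] = True
        state.injected_at[k] = t
        state.ancestor_injection[k] = t
        state.n_mergers[k] = 0
        if state.trajectories is not None:
            remaining = state.trajectories.shape[1] - t
            incs = fgn(remaining, config.alpha / 2.0, rng, n_series=3).T * config.base_step
            state.trajectories[k, t:] = incs
    if len(due):
        resolve_overlaps(
            state, t, rng, inherit=config.inherit, vanishing=config.vanishing, events=events
        )
    return n_injected_so_far + len(due)


def step(
    state: SphereSet,
    t: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    *,
    events: list[MergerEvent] | None = None,
    detector: str = "celllist",
) -> SphereSet:
    """Advance every alive sphere one fBm step (scaled by its size) with
    periodic wrapping, then merge all resulting contacts (in place)."""
    idx = np.flatnonzero(state.alive)
    if len(idx) == 0:
        return state
    factor = step_scale(radius_of(state.volumes[idx]), config.gamma)
    if state.trajectories is not None:
        incs = state.trajectories[idx, t]
    else:
        # α = 1: fBm increments are i.i.d. Gaussian; draw on the fly
        incs = rng.standard_normal((len(idx), 3)) * config.base_step
    state.positions[idx] = _wrap(state.positions[idx] + incs * factor[:, None], state.box_length)
    resolve_overlaps(
        state,
        t,
        rng,
        inherit=config.inherit,
        vanishing=config.vanishing,
        events=events,
        detector=detector,
    )
    return state


@dataclass
class ReplicateResult:
    """Output of one seeded replicate."""

    snapshots: dict[int, np.ndarray]  # step -> alive volumes
    events: pd.DataFrame
    series: pd.DataFrame  # columns: step, n_alive, mean_volume, total_volume
    final_volumes: np.ndarray
    n_injected: int
    duration: int


@dataclass
class SimulationResult:
    config: SimulationConfig
    replicates: list[ReplicateResult]

    @property
    def pooled_final_volumes(self) -> np.ndarray:
        return np.concatenate([r.final_volumes for r in self.replicates])

    @property
    def events(self) -> pd.DataFrame:
        frames = []
        for i, r in enumerate(self.replicates):
            df = r.events.copy()
            df["replicate"] = i
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


_EVENT_COLUMNS = [
    "step",
    "v1",
    "v2",
    "monomer1",
    "monomer2",
    "ancestor1",
    "ancestor2",
    "f1",
    "f2",
    "mean_volume",
    "n_alive",
]


def _events_frame(events: list[MergerEvent]) -> pd.DataFrame:
    if not events:
        return pd.DataFrame(columns=_EVENT_COLUMNS)
    return pd.DataFrame([vars(e) for e in events], columns=_EVENT_COLUMNS)


def run_replicate(
    config: SimulationConfig,
    rng: np.random.Generator,
    *,
    detector: str = "celllist",
) -> ReplicateResult:
    """Run one replicate of the configured simulation."""
    T = config.duration
    events: list[MergerEvent] = []
    snap_times = set(config.snapshot_times or ())
    stride = config.series_stride or max(1, T // 500)

    prestore = config.alpha < 1.0 and config.base_step > 0
    if config.mode == "quench":
        state = initialize_quench(config, rng, events=events)
        if prestore:
            # synthesize in chunks to bound the FFT workspace
            state.trajectories = np.empty((config.n_spheres, T, 3))
            chunk = 128
            for lo in range(0, config.n_spheres, chunk):
                hi = min(lo + chunk, config.n_spheres)
                incs = fgn(T, config.alpha / 2.0, rng, n_series=3 * (hi - lo))
                state.trajectories[lo:hi] = (
                    incs.reshape(hi - lo, 3, T).transpose(0, 2, 1) * config.base_step
                )
        n_injected = config.n_spheres
    else:
        state = _new_state(config.n_spheres, config.L)
        if prestore:
            state.trajectories = np.zeros((config.n_spheres, T, 3))
        n_injected = 0

    snapshots: dict[int, np.ndarray] = {}
    series_rows = []
    for t in range(T):
        if config.mode == "inject":
            n_injected = inject(state, t, config, rng, n_injected, events=events)
        if config.base_step > 0:
            step(state, t, config, rng, events=events, detector=detector)
        if t % stride == 0 or t == T - 1:
            vols = state.volumes[state.alive]
            if len(vols):
                pmean = float((vols**2).sum() / vols.sum())
                row = (t, len(vols), float(vols.mean()), pmean, float(vols.sum()))
            else:
                row = (t, 0, np.nan, np.nan, 0.0)
            series_rows.append(row)
        if t in snap_times:
            snapshots[t] = state.volumes[state.alive].copy()

    series = pd.DataFrame(
        series_rows, columns=["step", "n_alive", "mean_volume", "p_mean", "total_volume"]
    )
    return ReplicateResult(
        snapshots=snapshots,
        events=_events_frame(events),
        series=series,
        final_volumes=state.volumes[state.alive].copy(),
        n_injected=n_injected,
        duration=T,
    )


def run(config: SimulationConfig, *, detector: str = "celllist") -> SimulationResult:
    """Run all replicates (deterministic given ``config.seed``)."""
    ss = np.random.SeedSequence(config.seed)
    replicates = []
    for child in ss.spawn(config.n_replicates):
        rng = np.random.default_rng(child)
        replicates.append(run_replicate(config, rng, detector=detector))
    return SimulationResult(config=config, replicates=replicates)


# ---------------------------------------------------------------------------
# Figure-matching presets (full-scale) and desk-scale variants.


def quench_preset(*, scaled: bool = False, alpha: float = 1.0, seed: int = 0, **overrides):
    """Fast-quench coarsening condition (1,000 spheres, 5% volume
    fraction, 10⁵ steps; scaled: 300 spheres, 10⁴ steps, 10 replicates)."""
    base = dict(
        n_spheres=1000,
        volume_fraction=0.05,
        alpha=alpha,
        gamma=1.0,
        base_step=0.5,
        n_steps=100_000,
        n_replicates=20,
        seed=seed,
    )
    if scaled:
        base.update(n_spheres=300, n_steps=10_000, n_replicates=10)
    base.update(overrides)
    return SimulationConfig(**base)


def injection_preset(
    injection_rate: float,
    *,
    scaled: bool = False,
    alpha: float = 1.0,
    seed: int = 0,
    **overrides,
):
    """Steady-injection condition (1,200 spheres to a final volume
    fraction of 4%).

    The scaled variant injects 400 spheres into a box whose volume is
    shrunk by (400/1200)² relative to the full condition, which preserves
    the dimensionless ratio χ = N²K/(V_sys·J) exactly at the cost of a
    higher final volume fraction.
    """
    n_full, vf = 1200, 0.04
    base = dict(
        n_spheres=n_full,
        volume_fraction=vf,
        alpha=alpha,
        gamma=1.0,
        base_step=0.5,
        injection_rate=injection_rate,
        n_steps=10**9,  # duration is set by the injection schedule
        n_replicates=20,
        seed=seed,
    )
    if scaled:
        n_scaled = 400
        v_full = n_full * 1.5 / vf
        v_scaled = v_full * (n_scaled / n_full) ** 2
        base.update(
            n_spheres=n_scaled,
            box_length=v_scaled ** (1.0 / 3.0),
            n_replicates=10,
        )
    base.update(overrides)
    return SimulationConfig(**base)
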