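"""Monte Carlo generators for 2-D Brownian trajectories and QD-like datasets.

Two layers:

* :func:`simulate_brownian` — the validation simulator: free Brownian motion
  on an infinite plane, each step composed of a uniform direction
  θ ∈ [0, 2π) and a Rayleigh-distributed step length r with scale
  σ = √(2·D·t_lag), sampled by inverse CDF as r = √(−4·D·t_lag·ln u).
  The mean squared step length is then 4·D·t_lag.

* :func:`simulate_multispecies` — realistic multi-channel quantum-dot data:
  per-species mixtures of diffusion coefficients, isotropic Gaussian
  localization noise, and a two-state Markov blinking process that
  fragments each particle's track into separately emitted trajectories,
  with a ground-truth table linking fragments back to particles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MICROMETERS, AcquisitionMeta, Trajectory, TrackSet

#: Study conditions of the validation simulations.
DEFAULT_D_SIMULATION = 0.5      # µm²/s
DEFAULT_T_LAG = 0.040           # s (25 Hz)

#: Validation grid: (n_traj, steps_per_traj) at a constant total of
#: 10,000 displacements.
VALIDATION_GRID = ((1000, 10), (200, 50), (100, 100), (50, 200), (20, 500))


@dataclass(frozen=True)
class SimulationConfig:
    """One Brownian-validation condition.

    ``n_traj × steps_per_traj`` is the total displacement budget (10,000 in
    the reference grid).
    """

    D_simulation: float = DEFAULT_D_SIMULATION   # µm²/s
    t_lag: float = DEFAULT_T_LAG                 # s
    n_traj: int = 200
    steps_per_traj: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.D_simulation < 0:
            raise ValueError("D_simulation must be >= 0")
        if self.t_lag <= 0:
            raise ValueError("t_lag must be > 0")
        if self.n_traj < 1 or self.steps_per_traj < 1:
            raise ValueError("n_traj and steps_per_traj must be >= 1")

    @property
    def total_displacements(self) -> int:
        return self.n_traj * self.steps_per_traj


@dataclass(frozen=True)
class SpeciesSpec:
    """One labeled membrane species in a synthetic multi-channel dataset.

    ``D_components`` is a mixture of (D [µm²/s], weight) pairs; each
    simulated particle draws one component.  ``localization_sigma`` is the
    per-axis Gaussian noise in µm.  Blinking is a two-state Markov chain:
    an ON particle turns OFF with probability ``blink_off_rate`` per frame
    and an OFF particle returns with ``blink_on_rate``; the defaults give a
    mean on-time of 300 frames and mean off-time of 20 frames, which
    reproduces the trajectory-length scale of β-ME-stabilised QD data.
    """

    name: str
    D_components: tuple = ((0.05, 1.0),)
    localization_sigma: float = 0.020     # µm; δr = σ·√2 ≈ 28 nm < 30 nm
    blink_off_rate: float = 1.0 / 300.0   # per frame
    blink_on_rate: float = 1.0 / 20.0     # per frame
    n_particles: int = 100

    def __post_init__(self) -> None:
        weights = [w for _, w in self.D_components]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if any(d < 0 for d, _ in self.D_components):
            raise ValueError("diffusion coefficients must be >= 0")
        for r in (self.blink_off_rate, self.blink_on_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("blink rates must lie in [0, 1]")
        if self.localization_sigma < 0:
            raise ValueError("localization_sigma must be >= 0")


def rayleigh_steps(
    n: int, D: float, t_lag: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw n 2-D Brownian displacement vectors (µm).

    θ ~ Uniform[0, 2π); r = √(−4·D·t_lag·ln u), u ~ Uniform(0, 1] — the
    inverse-CDF sample of a Rayleigh law with scale √(2·D·t_lag), so that
    E[r²] = 4·D·t_lag.
    """
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    u = 1.0 - rng.random(n)          # in (0, 1]; avoids log(0)
    r = np.sqrt(-4.0 * D * t_lag * np.log(u))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def brownian_steps_batch(
    n_traj: int, n_steps: int, D: float, t_lag: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Displacement array of shape (n_traj, n_steps, 2) in µm."""
    steps = rayleigh_steps(n_traj * n_steps, D, t_lag, rng)
    return steps.reshape(n_traj, n_steps, 2)


def simulate_brownian(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    meta: AcquisitionMeta | None = None,
) -> tuple[TrackSet, pd.DataFrame]:
    """Simulate one validation condition.

    Returns the TrackSet (coordinates in µm, contiguous frames from 0) and
    a ground-truth table with one row per trajectory (id, true D, steps).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if meta is None:
        meta = AcquisitionMeta(frame_interval=config.t_lag, pixel_size=0.107)
    steps = brownian_steps_batch(
        config.n_traj, config.steps_per_traj, config.D_simulation,
        config.t_lag, rng,
    )
    frames = np.arange(config.steps_per_traj + 1, dtype=np.int64)
    trajectories = []
    for i in range(config.n_traj):
        xy = np.vstack([np.zeros((1, 2)), np.cumsum(steps[i], axis=0)])
        trajectories.append(
            Trajectory(id=f"sim{i:05d}", frames=frames.copy(), xy=xy,
                       channel="sim", unit=MICROMETERS)
        )
    truth = pd.DataFrame({
        "trajectory_id": [t.id for t in trajectories],
        "D_true": config.D_simulation,
        "n_steps": config.steps_per_traj,
    })
    return TrackSet(trajectories, meta), truth


def _blink_segments(
    n_frames: int, off_rate: float, on_rate: float,
    rng: np.random.Generator,
    max_gap: int | None = None,
) -> list[np.ndarray]:
    """Visible frame-index runs of a two-state Markov emitter.

    The chain starts ON.  If ``max_gap`` is given, dark intervals are
    truncated to that many frames (used to generate relink-friendly data).
    """
    if off_rate <= 0.0:
        return [np.arange(n_frames, dtype=np.int64)]
    visible = np.empty(n_frames, dtype=bool)
    on = True
    gap_len = 0
    for f in range(n_frames):
        if on:
            visible[f] = True
            if rng.random() < off_rate:
                on = False
                gap_len = 0
        else:
            gap_len += 1
            if rng.random() < on_rate or (max_gap is not None
                                          and gap_len >= max_gap):
                on = True
                visible[f] = True
            else:
                visible[f] = False
    idx = np.flatnonzero(visible)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1) + 1
    return np.split(idx, breaks)


def simulate_multispecies(
    specs: list[SpeciesSpec],
    meta: AcquisitionMeta,
    n_frames: int = 1200,
    seed: int = 0,
    rng: np.random.Generator | None = None,
    max_blink_gap: int | None = None,
    spacing_um: float = 0.0,
) -> tuple[dict[str, TrackSet], pd.DataFrame]:
    """Generate a multi-channel QD-like dataset with ground truth.

    Each particle draws a D component by weight, diffuses on an infinite
    plane, gets per-axis Gaussian localization noise, and is fragmented by
    blinking; fragments are emitted as separate trajectories named
    ``<species>_p<particle>_f<fragment>``.  With ``spacing_um > 0``
    particles start on a square grid with that pitch (useful for
    relink/dedupe tests that need spatial separation).

    Returns per-channel TrackSets (µm) and a ground-truth table with one
    row per fragment: particle id, species, component D, fragment id,
    fragment start/end frames.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    channels: dict[str, list[Trajectory]] = {s.name: [] for s in specs}
    rows = []
    total = sum(s.n_particles for s in specs)
    side = int(np.ceil(np.sqrt(total))) if spacing_um > 0 else 0
    particle_counter = 0
    for spec in specs:
        comp_d = np.array([d for d, _ in spec.D_components])
        comp_w = np.array([w for _, w in spec.D_components])
        for p in range(spec.n_particles):
            D = float(rng.choice(comp_d, p=comp_w))
            if spacing_um > 0:
                origin = np.array([
                    (particle_counter % side) * spacing_um,
                    (particle_counter // side) * spacing_um,
                ])
            else:
                origin = rng.uniform(0.0, 30.0, size=2)
            steps = rayleigh_steps(n_frames - 1, D, meta.frame_interval, rng)
            xy = origin + np.vstack([np.zeros((1, 2)),
                                     np.cumsum(steps, axis=0)])
            if spec.localization_sigma > 0:
                xy = xy + rng.normal(0.0, spec.localization_sigma,
                                     size=xy.shape)
            segments = _blink_segments(
                n_frames, spec.blink_off_rate, spec.blink_on_rate, rng,
                max_gap=max_blink_gap,
            )
            pid = f"{spec.name}_p{particle_counter:04d}"
            for j, seg in enumerate(segments):
                if seg.size < 2:
                    continue
                fid = f"{pid}_f{j}"
                channels[spec.name].append(
                    Trajectory(id=fid, frames=seg, xy=xy[seg],
                               channel=spec.name, unit=MICROMETERS)
                )
                rows.append({
                    "particle_id": pid, "species": spec.name, "D_true": D,
                    "fragment_id": fid, "start_frame": int(seg[0]),
                    "end_frame": int(seg[-1]),
                })
            particle_counter += 1
    tracksets = {
        name: TrackSet(trajs, meta, condition="synthetic")
        for name, trajs in channels.items()
    }
    truth = pd.DataFrame(
        rows, columns=["particle_id", "species", "D_true", "fragment_id",
                       "start_frame", "end_frame"])
    return tracksets, truth
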