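"""Rigid-body Langevin dynamics of adhesin-patterned cells in a periodic box.

Each cell is one rigid body (template from :mod:`piliagg.geometry`): a body
sphere plus adhesin spheres at fixed body-frame offsets.  The state advances
by a BAOAB Langevin splitting at temperature ``kBT`` with drag chosen so the
unit of time ``tau`` is the time a free adhesin-sized sphere takes to diffuse
one unit length (``D_P = sigma_P^2 / (6 tau)``, hence a per-atom Stokes-like
drag ``zeta_P = 6 kBT tau / sigma_P^2`` scaled by atom radius).  A cell's
translational drag is the sum over its constituent atoms; rotational drag and
inertia are isotropic, from the constituent atoms' arms about the center.

Three phases make up the assay protocol: free equilibration, a recording
window with evenly spaced snapshots, and uniaxial compression between two
repulsive z-plates closing at constant speed to a final gap (mimicking cells
settling under an agar pad before imaging).

The ``desk`` preset runs 64 cells in a 200^3 box (number density within 2x of
the full-scale 512 cells in 500^3) on schedules short enough for a laptop;
the ``full`` preset pins the full-scale reference schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from . import _kernels
from .geometry import CellTemplate, PairPotentialParams

__all__ = [
    "SimulationConfig",
    "SystemState",
    "Trajectory",
    "InfeasibleDensityError",
    "IntegrationBlowupError",
    "desk_config",
    "full_config",
    "rigid_body_coefficients",
    "minimum_image",
    "initialize_system",
    "compute_forces",
    "advance",
    "step",
    "run_phase",
]

KBT_REFERENCE = 1.0  # drag is a property of the medium; derived at kBT = 1


class InfeasibleDensityError(RuntimeError):
    """Rejection-sampling placement failed: the box is too crowded."""


class IntegrationBlowupError(RuntimeError):
    """Non-finite coordinates appeared during integration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Schedule and thermodynamic parameters (simulation units).

    Times are in units of ``tau``; lengths in units of the adhesin radius.
    ``record_interval`` must divide ``t_record_window``.
    """

    n_cells: int = 64
    box_lengths: tuple[float, float, float] = (200.0, 200.0, 200.0)
    kBT: float = 1.0
    tau: float = 1.0
    dt: float = 0.05
    t_equilibrate: float = 2.0e5
    t_record_window: float = 1.5e4
    record_interval: float = 5.0e3
    t_compress: float = 1.0e4
    plate_final_gap: float = 50.0
    n_replicates: int = 5
    seed: int = 0
    particle_mass: float = 1.0
    force_cap: float = 1.0e3
    neighbor_skin: float = 4.0
    thermostat: bool = True  # False: gamma = 0, no noise (microcanonical checks)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if any(L <= 0 for L in self.box_lengths):
            raise ValueError("box lengths must be positive")
        n = self.t_record_window / self.record_interval
        if abs(n - round(n)) > 1e-9:
            raise ValueError("record_interval must divide t_record_window")

    @property
    def n_snapshots(self) -> int:
        return int(round(self.t_record_window / self.record_interval))

    @property
    def box(self) -> np.ndarray:
        return np.asarray(self.box_lengths, dtype=float)


def desk_config(**overrides) -> SimulationConfig:
    """Scaled-down preset: 64 cells, 200^3 box, short schedule."""
    return replace(SimulationConfig(), **overrides) if overrides else SimulationConfig()


def full_config(**overrides) -> SimulationConfig:
    """Full-scale preset: 512 cells in 500^3, reference schedule."""
    cfg = SimulationConfig(
        n_cells=512,
        box_lengths=(500.0, 500.0, 500.0),
        t_equilibrate=8.0e8,
        t_record_window=1.5e8,
        record_interval=0.5e6,
        t_compress=2.0e7,
        plate_final_gap=50.0,
        n_replicates=5,
    )
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class SystemState:
    """Positions/orientations/velocities of every cell, plus box geometry.

    Adhesin world coordinates are always derived from ``quaternions`` and the
    template — rigid geometry is exact by construction.
    """

    positions: np.ndarray  # (N, 3), wrapped into [0, L)
    quaternions: np.ndarray  # (N, 4), unit norm, (w, x, y, z)
    velocities: np.ndarray  # (N, 3)
    ang_velocities: np.ndarray  # (N, 3), world frame
    box: np.ndarray  # (3,)
    time: float = 0.0
    plates: tuple[float, float] | None = None  # (z_lo, z_hi) when walls active

    @property
    def n_cells(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "SystemState":
        return SystemState(
            self.positions.copy(),
            self.quaternions.copy(),
            self.velocities.copy(),
            self.ang_velocities.copy(),
            self.box.copy(),
            self.time,
            self.plates,
        )

    def adhesin_world_coords(self, template: CellTemplate) -> np.ndarray:
        """(N, n_adhesins, 3) world positions of every adhesin (unwrapped arms)."""
        W = np.empty((self.n_cells, template.n_adhesins, 3))
        _kernels._world_offsets(self.quaternions, template.local_coords, W)
        return self.positions[:, None, :] + W


@dataclass
class Trajectory:
    """Ordered snapshots with provenance (config, seed)."""

    states: list[SystemState]
    provenance: dict = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.states])

    def __len__(self) -> int:
        return len(self.states)


def rigid_body_coefficients(
    template: CellTemplate,
    params: PairPotentialParams,
    mass_per_atom: float = 1.0,
) -> tuple[float, float, float, float]:
    """(mass, inertia, gamma_t, gamma_r) of one rigid cell.

    Per-atom drag scales with atom radius (Stokes), normalized so a free
    adhesin sphere has ``D = sigma_P^2/(6 tau)``.  Inertia is the isotropic
    (orientation-averaged) point-mass moment ``(2/3) m sum r_k^2``; the body
    atom sits at the center and contributes neither inertia nor rotational
    drag.
    """
    zeta_P = 6.0 * KBT_REFERENCE / params.sigma_P**2
    zeta_B = zeta_P * params.sigma_B / params.sigma_P
    arms_sq = float(np.sum(template.local_coords**2))
    mass = (template.n_adhesins + 1) * mass_per_atom
    inertia = (2.0 / 3.0) * mass_per_atom * arms_sq
    zeta_t = zeta_B + template.n_adhesins * zeta_P
    zeta_r = zeta_P * arms_sq
    return mass, inertia, zeta_t / mass, zeta_r / inertia


def minimum_image(displacement, box_lengths) -> np.ndarray:
    """Map each displacement component into ``(-L/2, L/2]``."""
    d = np.asarray(displacement, dtype=float)
    L = np.asarray(box_lengths, dtype=float)
    return d - L * np.ceil(d / L - 0.5)


def initialize_system(
    config: SimulationConfig,
    template: CellTemplate,
    params: PairPotentialParams | None = None,
    seed: int | None = None,
    max_attempts_per_cell: int = 10_000,
) -> SystemState:
    """Random non-overlapping placement with thermal velocities.

    Cell centers are rejection-sampled with minimum pairwise center distance
    ``2 sigma_B`` (bodies non-overlapping); orientations are uniform random
    quaternions; linear and angular velocities are Maxwell-Boltzmann at
    ``kBT``.  Deterministic given the seed.
    """
    params = params or PairPotentialParams()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    box = config.box
    d_min = 2.0 * params.sigma_B
    d_min2 = d_min * d_min
    pos = np.empty((config.n_cells, 3))
    for i in range(config.n_cells):
        for attempt in range(max_attempts_per_cell):
            cand = rng.random(3) * box
            if i == 0:
                pos[i] = cand
                break
            d = minimum_image(pos[:i] - cand, box)
            if np.min(np.sum(d * d, axis=1)) >= d_min2:
                pos[i] = cand
                break
        else:
            raise InfeasibleDensityError(
                f"could not place cell {i} of {config.n_cells} in box {box}"
            )
    quat = rng.normal(size=(config.n_cells, 4))
    quat /= np.linalg.norm(quat, axis=1, keepdims=True)
    mass, inertia, _, _ = rigid_body_coefficients(template, params, config.particle_mass)
    vel = rng.normal(scale=np.sqrt(config.kBT / mass), size=(config.n_cells, 3))
    angvel = rng.normal(scale=np.sqrt(config.kBT / inertia), size=(config.n_cells, 3))
    return SystemState(pos, quat, vel, angvel, box.copy(), time=0.0)


def _forces_all_pairs(
    state: SystemState, template: CellTemplate, params: PairPotentialParams
) -> tuple[np.ndarray, np.ndarray, float]:
    """Reference all-pairs force evaluation in plain numpy (no neighbor list).

    Enumerates every inter-cell atom pair directly; used as the independent
    check of the compiled neighbor-list path.
    """
    N = state.n_cells
    na = template.n_adhesins
    box = state.box
    W = state.adhesin_world_coords(template) - state.positions[:, None, :]
    # atom tables: index 0 is the body, 1..na the adhesins
    offsets = np.concatenate([np.zeros((N, 1, 3)), W], axis=1)  # (N, na+1, 3)
    sig = np.concatenate([[params.sigma_B], np.full(na, params.sigma_P)])
    F = np.zeros((N, 3))
    T = np.zeros((N, 3))
    U = 0.0
    root6 = 2.0 ** (1.0 / 6.0)
    for i in range(N - 1):
        for j in range(i + 1, N):
            dc = minimum_image(state.positions[j] - state.positions[i], box)
            # r_vec from every atom of i to every atom of j
            rv = dc[None, None, :] + offsets[j][None, :, :] - offsets[i][:, None, :]
            r = np.linalg.norm(rv, axis=-1)
            for a in range(na + 1):
                for b in range(na + 1):
                    rab = r[a, b]
                    if a == 0 or b == 0:  # at least one body atom: WCA
                        s = sig[a] + sig[b]
                        if rab >= root6 * s:
                            continue
                        sr6 = (s / rab) ** 6
                        U += params.epsilon + 4 * params.epsilon * (sr6**2 - sr6)
                        mag = 24 * params.epsilon * (2 * sr6**2 - sr6) / rab
                        mag = min(mag, 1e300)
                    else:  # adhesin-adhesin cosine well
                        if params.A == 0.0 or rab >= params.r_c:
                            continue
                        U += params.A * (1 + np.cos(np.pi * rab / params.r_c))
                        if rab < 1e-12:
                            continue
                        mag = params.A * np.pi / params.r_c * np.sin(np.pi * rab / params.r_c)
                    f = -mag * rv[a, b] / rab
                    F[i] += f
                    F[j] -= f
                    T[i] += np.cross(offsets[i, a], f)
                    T[j] += np.cross(offsets[j, b], -f)
    return F, T, U


def compute_forces(
    state: SystemState,
    template: CellTemplate,
    params: PairPotentialParams | None = None,
    method: Literal["neighbor", "all_pairs"] = "neighbor",
    force_cap: float = 1.0e3,
    neighbor_skin: float = 4.0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-cell forces, torques about cell centers, and total potential energy.

    ``method="neighbor"`` is the production compiled path (Verlet list over
    cell centers); ``method="all_pairs"`` is a direct O(N^2 na^2) numpy
    enumeration kept as an independent oracle.
    """
    params = params or PairPotentialParams()
    if method == "all_pairs":
        return _forces_all_pairs(state, template, params)
    plate_on = state.plates is not None
    zlo, zhi = state.plates if plate_on else (0.0, 0.0)
    F, T, U = _kernels.forces_neighbor_list(
        state.positions, state.quaternions, template.local_coords, state.box,
        params.sigma_B, params.sigma_P, params.epsilon, params.A, params.r_c,
        force_cap, plate_on, zlo, zhi, neighbor_skin,
    )
    return F, T, U


def advance(
    state: SystemState,
    config: SimulationConfig,
    template: CellTemplate,
    params: PairPotentialParams,
    n_steps: int,
    rng_state: np.ndarray,
    snapshot_every: int = 0,
    plates: tuple[float, float, float, float] | None = None,
) -> tuple[SystemState, list[SystemState]]:
    """Advance ``n_steps`` in place-copy semantics; returns (final, snapshots).

    ``plates``, when given, is ``(z_lo, z_hi, closing_speed, final_gap)``;
    each wall moves inward at ``closing_speed`` until the gap reaches
    ``final_gap``.  ``rng_state`` is the persistent uint64 noise stream.
    """
    s = state.copy()
    mass, inertia, gamma_t, gamma_r = rigid_body_coefficients(
        template, params, config.particle_mass
    )
    if not config.thermostat:
        gamma_t = gamma_r = 0.0
    if plates is not None:
        plate_on, zlo, zhi, speed, gap = True, plates[0], plates[1], plates[2], plates[3]
    elif s.plates is not None:
        plate_on, (zlo, zhi), speed, gap = True, s.plates, 0.0, 0.0
    else:
        plate_on, zlo, zhi, speed, gap = False, 0.0, 0.0, 0.0, 0.0
    n_snap_max = n_steps // snapshot_every if snapshot_every > 0 else 0
    N = s.n_cells
    snap_pos = np.empty((max(n_snap_max, 1), N, 3))
    snap_quat = np.empty((max(n_snap_max, 1), N, 4))
    snap_vel = np.empty((max(n_snap_max, 1), N, 3))
    snap_angvel = np.empty((max(n_snap_max, 1), N, 3))
    status, zlo_f, zhi_f, nsnap = _kernels.run_steps(
        s.positions, s.quaternions, s.velocities, s.ang_velocities,
        template.local_coords, s.box,
        n_steps, config.dt,
        mass, inertia, gamma_t, gamma_r, config.kBT,
        params.sigma_B, params.sigma_P, params.epsilon, params.A, params.r_c,
        config.force_cap,
        plate_on, zlo, zhi, speed, gap,
        config.neighbor_skin, rng_state,
        snapshot_every, snap_pos, snap_quat, snap_vel, snap_angvel,
    )
    if status != 0:
        raise IntegrationBlowupError(
            f"non-finite coordinates within {n_steps} steps from t={state.time}"
        )
    s.time = state.time + n_steps * config.dt
    s.plates = (zlo_f, zhi_f) if plate_on else None
    snapshots = []
    for k in range(nsnap):
        t_k = state.time + (k + 1) * snapshot_every * config.dt
        snapshots.append(
            SystemState(
                snap_pos[k].copy(), snap_quat[k].copy(), snap_vel[k].copy(),
                snap_angvel[k].copy(), s.box.copy(), t_k, s.plates,
            )
        )
    return s, snapshots


def step(
    state: SystemState,
    config: SimulationConfig,
    template: CellTemplate,
    params: PairPotentialParams,
    rng_state: np.ndarray,
) -> SystemState:
    """Single BAOAB step (thin wrapper around :func:`advance`)."""
    final, _ = advance(state, config, template, params, 1, rng_state)
    return final


def run_phase(
    state: SystemState,
    config: SimulationConfig,
    template: CellTemplate,
    params: PairPotentialParams,
    phase: Literal["equilibrate", "record", "compress"],
    rng_state: np.ndarray,
) -> Trajectory:
    """Run one protocol phase; returns the trajectory of that phase.

    ``equilibrate`` advances ``t_equilibrate`` and keeps only the final state;
    ``record`` snapshots every ``record_interval`` over ``t_record_window``;
    ``compress`` closes two z-walls from the full box height to
    ``plate_final_gap`` at constant speed over ``t_compress`` and keeps the
    final (compressed) state, with plates still registered on it.
    """
    prov = {"phase": phase, "t_start": state.time, "n_cells": state.n_cells}
    if phase == "equilibrate":
        n_steps = int(round(config.t_equilibrate / config.dt))
        final, _ = advance(state, config, template, params, n_steps, rng_state)
        return Trajectory([final], prov)
    if phase == "record":
        snap_every = int(round(config.record_interval / config.dt))
        n_steps = int(round(config.t_record_window / config.dt))
        _, snaps = advance(
            state, config, template, params, n_steps, rng_state,
            snapshot_every=snap_every,
        )
        return Trajectory(snaps, prov)
    if phase == "compress":
        n_steps = int(round(config.t_compress / config.dt))
        Lz = state.box[2]
        speed = (Lz - config.plate_final_gap) / (2.0 * config.t_compress)
        final, _ = advance(
            state, config, template, params, n_steps, rng_state,
            plates=(0.0, Lz, speed, config.plate_final_gap),
        )
        return Trajectory([final], prov)
    raise ValueError(f"unknown phase {phase!r}")
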