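"""Thermal noise and time integration of the overdamped Langevin equation.

The equation of motion per node is c dr/dt = -dW/dr + F_rand with Stokes
friction c and a white-noise random force of magnitude sigma = sqrt(2 c kb T).
The discrete update is an operator split: forward Euler for bending, torsion,
aggregation and repulsion, a Box-Muller thermal kick, and classical RK4 for
the stiff stretch term (switchable to pure Euler for ablation).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels as _k
from .init_conditions import InitialConditionSpec, random_straight_fibres
from .network import FibreNetwork
from .params import ModelParameters
from .potentials import active_pairs, find_pairs


#: xorshift128+ state of the integrator stream (seed via seed_kernel_rng)
_RNG_STATE = np.zeros(2, dtype=np.uint64)
_k.seed_state(0, _RNG_STATE)


def seed_kernel_rng(seed: int) -> None:
    """Seed the compiled integrator's random stream (deterministic per seed)."""
    _k.seed_state(int(seed), _RNG_STATE)


def gaussian_stream(n: int, seed: Optional[int] = None) -> np.ndarray:
    """n standard normals from the kernel's Box-Muller stream."""
    if seed is not None:
        seed_kernel_rng(seed)
    out = np.empty(int(n))
    _k.fill_standard_normal(out, _RNG_STATE)
    return out


@dataclass
class NoiseModel:
    """Random-force model: sigma^2 = 2 c kb T, i.i.d. Gaussian directions."""

    params: ModelParameters
    seed: Optional[int] = None

    def __post_init__(self):
        if self.seed is not None:
            seed_kernel_rng(self.seed)

    @property
    def sigma(self) -> float:
        return self.params.noise_sigma

    def draw(self, n_nodes: int) -> np.ndarray:
        """(n_nodes, 3) standard-normal directions j-hat."""
        return gaussian_stream(3 * n_nodes).reshape(n_nodes, 3)


def draw_noise(n_nodes: int, rng: np.random.Generator) -> np.ndarray:
    """(n_nodes, 3) standard normals via Box-Muller from ``rng`` uniforms.

    Reference implementation used for statistical validation; the integrator
    uses the identical transform on the compiled kernel's uniform stream.
    """
    m = 3 * n_nodes
    half = (m + 1) // 2
    u1 = rng.random(half)
    u1 = np.where(u1 <= 1e-300, 1e-300, u1)
    u2 = rng.random(half)
    r = np.sqrt(-2.0 * np.log(u1))
    z = np.concatenate([r * np.cos(2 * np.pi * u2), r * np.sin(2 * np.pi * u2)])
    return z[:m].reshape(n_nodes, 3)


@dataclass
class SimulationLog:
    """Sampled observables of an aggregation run."""

    energy_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    energies: np.ndarray = field(default_factory=lambda: np.empty((0, 5)))  # WS WB WT WA WR
    obs_times: list = field(default_factory=list)
    mean_orientation: list = field(default_factory=list)
    median_tortuosity: list = field(default_factory=list)
    n_pairs: list = field(default_factory=list)
    steady_time: Optional[float] = None
    plateau_time: Optional[float] = None

    @property
    def total_energy(self) -> np.ndarray:
        return self.energies.sum(axis=1)

    def as_frame(self):
        import pandas as pd
        return pd.DataFrame(self.energies,
                            columns=["W_S", "W_B", "W_T", "W_A", "W_R"],
                            index=pd.Index(self.energy_times, name="time_s"))


def _integrate(network: FibreNetwork, params: ModelParameters, nsteps: int,
               noise: bool = True, energy_every: int = 0,
               skin: float = 9e-9, use_rk4: bool = True):
    """Low-level driver around the compiled integrator (advances in place)."""
    n_samp = nsteps // energy_every + 1 if energy_every > 0 else 0
    E = np.empty((max(n_samp, 1), 5))
    noise_std = math.sqrt(2.0 * params.kbT * params.dt / params.c) if noise else 0.0
    nearest = params.aggregation_mode == "nearest"
    if nearest and network.bond_partner is None:
        network.bond_partner = np.full(
            (network.n_nodes, params.max_bonds_per_node), -1, dtype=np.int64)
    partner = (network.bond_partner if nearest
               else np.empty((0, 1), dtype=np.int64))
    status, ns = _k.integrate(
        network.flat_positions, network.nodes_per_fibre, network.box_lengths,
        nsteps, params.dt, params.c, params.k_S, params.r0_S, use_rk4,
        params.k_B, params.theta0, params.k_T, params.k_A, params.r0_A,
        params.a_th, params.k_R, params.r0_R, noise_std, skin,
        energy_every, E, _RNG_STATE, nearest, partner)
    if status != 0 or not np.all(np.isfinite(network.flat_positions)):
        raise FloatingPointError(
            f"integration diverged at t~{network.time:.3e}s "
            f"(dt={params.dt:.2e}); state dump: max|r|="
            f"{np.nanmax(np.abs(network.flat_positions)):.3e}")
    network.time += nsteps * params.dt
    return E[:ns]


def step(network: FibreNetwork, params: ModelParameters,
         noise: bool = True, use_rk4: bool = True) -> FibreNetwork:
    """Advance one time step dt in place (seed via seed_kernel_rng)."""
    _integrate(network, params, 1, noise=noise, use_rk4=use_rk4)
    return network


def plateau_time(times: np.ndarray, W: np.ndarray, window: float,
                 rtol: float = 0.01) -> Optional[float]:
    """First time at which the windowed mean of W changes by < rtol.

    Compares the mean over [t - w, t] against the mean over [t - 2w, t - w];
    returns the earliest qualifying t, or None if never reached.
    """
    times = np.asarray(times)
    W = np.asarray(W)
    if times.size < 4:
        return None
    dt = np.median(np.diff(times))
    k = max(int(round(window / dt)), 2)
    for end in range(2 * k, times.size + 1):
        m1 = W[end - k:end].mean()
        m0 = W[end - 2 * k:end - k].mean()
        if abs(m1 - m0) <= rtol * abs(m1):
            return float(times[end - 1])
    return None


def run_aggregation(params: ModelParameters,
                    network: Optional[FibreNetwork] = None,
                    t_end: float = 0.2,
                    steady_time: float | str = 0.05,
                    sample_every: float = 1e-4,
                    energy_every: float = 2e-5,
                    plateau_window: float = 0.01,
                    noise: bool = True,
                    skin: float = 9e-9,
                    use_rk4: bool = True,
                    extend_until_gelled: bool = False,
                    t_cap: Optional[float] = None):
    """Integrate the aggregation phase and log observables.

    The initial condition defaults to seeded random straight rods at the
    parameter concentration.  ``steady_time`` controls when the per-fibre
    reference contour lengths l0 and the reference aggregation pair set
    n_agg^0 are frozen on the network: a time in seconds, "auto" (the plateau
    detector: windowed-mean change of W_total below 1% over
    ``plateau_window``), or "end" (freeze at the final configuration, i.e.
    at the start of a subsequent tensile test).

    With ``extend_until_gelled`` the run continues past ``t_end`` in
    ``sample_every`` blocks (up to ``t_cap``) until the bonded network
    percolates along z — the steady state a tensile test presumes; in the
    full-scale system gelation completes within the 50 ms equilibration, but
    its completion time fluctuates strongly at desk scale.

    Returns ``(network, SimulationLog)``.
    """
    from .analysis import percolation_axes, segment_orientation, tortuosity

    if network is None:
        spec = InitialConditionSpec(box=tuple(params.box),
                                    concentration=params.concentration,
                                    n_fibres=params.n_fibres, seed=params.seed)
        network = random_straight_fibres(spec, params)
    seed_kernel_rng(params.seed)

    log = SimulationLog()
    e_every_steps = max(int(round(energy_every / params.dt)), 1)
    chunk_steps = max(int(round(sample_every / params.dt)), 1)
    auto = steady_time == "auto"
    at_end = steady_time == "end"
    if not (auto or at_end):
        freeze_at = float(steady_time)
    target = t_end

    E_rows, E_times = [], []
    while network.time < target - 0.5 * params.dt:
        t0 = network.time
        E = _integrate(network, params, chunk_steps, noise=noise,
                       energy_every=e_every_steps, skin=skin, use_rk4=use_rk4)
        E_rows.append(E)
        E_times.append(t0 + np.arange(E.shape[0]) * e_every_steps * params.dt)
        pairs = active_pairs(network, params)
        stats = segment_orientation(network)
        log.obs_times.append(network.time)
        log.mean_orientation.append(stats.ensemble_mean)
        log.median_tortuosity.append(float(np.nanmedian(tortuosity(network))))
        log.n_pairs.append(len(pairs))

        if network.reference_lengths is None and not at_end:
            tt = np.concatenate(E_times)
            WW = np.concatenate(E_rows).sum(axis=1) if E_rows else np.empty(0)
            if auto:
                pt = plateau_time(tt, WW, plateau_window)
                if pt is not None:
                    log.plateau_time = pt
                    log.steady_time = network.time
                    network.freeze_reference(pairs)
            elif network.time >= freeze_at - 0.5 * params.dt:
                log.steady_time = network.time
                network.freeze_reference(pairs)

        if (extend_until_gelled and t_cap is not None
                and network.time >= target - 0.5 * params.dt
                and target < t_cap - 0.5 * params.dt
                and not percolation_axes(network, pairs)[2]):
            target = min(target + sample_every, t_cap)

    log.energy_times = np.concatenate(E_times)
    log.energies = np.concatenate(E_rows)
    if log.plateau_time is None:
        log.plateau_time = plateau_time(log.energy_times, log.total_energy,
                                        plateau_window)
    if network.reference_lengths is None:
        if not at_end:
            warnings.warn("steady state not declared within t_end; freezing "
                          "the reference state at the final configuration")
        log.steady_time = network.time
        network.freeze_reference(active_pairs(network, params))
    return network, log


def equilibrium_statistics(trajectory: np.ndarray, params: ModelParameters) -> dict:
    """Equipartition report for a single-fibre trajectory (T, npf, 3).

    Bond lengths fluctuate with variance kb*T/k^S.  The joint angle theta has
    two transverse modes: with the sin(theta) area Jacobian the polar deviation
    x = pi - theta is Rayleigh-distributed and <x^2> = 2 kb T / k^B (kb T / k^B
    per transverse direction, which is what ``angle_variance_per_mode``
    reports).
    """
    traj = np.asarray(trajectory)
    if traj.ndim != 3 or traj.shape[0] < 100:
        raise ValueError("need a (T, nodes, 3) trajectory with T >= 100 samples")
    bonds = np.linalg.norm(np.diff(traj, axis=1), axis=-1)
    u = traj[:, :-2] - traj[:, 1:-1]
    v = traj[:, 2:] - traj[:, 1:-1]
    ct = (u * v).sum(-1) / (np.linalg.norm(u, axis=-1) * np.linalg.norm(v, axis=-1))
    theta = np.arccos(np.clip(ct, -1.0, 1.0))
    kbT = params.kbT
    x2 = ((theta - math.pi) ** 2).mean()
    return {
        "n_samples": traj.shape[0],
        "bond_variance": float(((bonds - bonds.mean()) ** 2).mean()),
        "bond_variance_expected": kbT / params.k_S,
        "angle_msd": float(x2),
        "angle_msd_expected": 2.0 * kbT / params.k_B,
        "angle_variance_per_mode": float(x2 / 2.0),
        "angle_variance_per_mode_expected": kbT / params.k_B,
    }
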