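"""Virtual tensile test: affine z-scaling with Brownian relaxation, the
engineering stress from the energy gradient, and the elastic-modulus fit.

The extension protocol scales every z coordinate and the box length L_z by
xi = 1 + c_s * dtau / L_z each increment (stretch speed c_s = 2.5 mm/s,
relaxation period dtau = 2 us), so each increment adds the same length
c_s * dtau and the engineering-strain grid eps_z = L_z/L_z0 - 1 is uniform.
The lateral box dimensions are never scaled; the cross-section A = Lx * Ly
stays fixed and sigma_z = (dW/dL_z)/A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .analysis import bond_survival, segment_orientation, stretched_fraction
from .dynamics import _integrate, seed_kernel_rng
from .network import FibreNetwork
from .params import ModelParameters
from .potentials import find_pairs, total_field


@dataclass
class StretchRecord:
    """Per-strain observables of one virtual tensile test."""

    strain: np.ndarray            # eps_z grid
    box_z: np.ndarray             # L_z per record, metres
    energies: np.ndarray          # (n, 5): W_S W_B W_T W_A W_R
    stretched_fraction: np.ndarray  # n_(eps>=0.05)/N
    bond_survival: np.ndarray       # n_agg/n_agg0
    frac_theta_le_45: np.ndarray    # fraction of fibres with <theta_i> <= 45 deg
    mean_orientation: np.ndarray    # ensemble <theta>, rad
    box_z0: float = 0.0
    cross_section: float = 0.0      # A = Lx * Ly, fixed
    c_s: float = 2.5e-3
    dtau: float = 2e-6

    @property
    def total_energy(self) -> np.ndarray:
        return self.energies.sum(axis=1)

    def at_strain(self, eps: float) -> int:
        """Index of the record closest to the requested strain."""
        return int(np.argmin(np.abs(self.strain - eps)))

    def as_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "eps_z": self.strain, "L_z": self.box_z,
            "W_S": self.energies[:, 0], "W_B": self.energies[:, 1],
            "W_T": self.energies[:, 2], "W_A": self.energies[:, 3],
            "W_R": self.energies[:, 4], "W_total": self.total_energy,
            "frac_stretched": self.stretched_fraction,
            "bond_survival": self.bond_survival,
            "frac_theta_le_45": self.frac_theta_le_45,
            "mean_theta_rad": self.mean_orientation,
        })


def stretch_increment(network: FibreNetwork, params: ModelParameters,
                      c_s: float = 2.5e-3, dtau: float = 2e-6,
                      relax: bool = True, skin: float = 9e-9,
                      use_rk4: bool = True) -> float:
    """One extension increment: scale z by xi = 1 + c_s*dtau/L_z, then relax
    for dtau of Brownian dynamics.  Returns xi.  x and y are untouched."""
    Lz = network.box_lengths[2]
    xi = 1.0 + c_s * dtau / Lz
    if xi <= 1.0:
        raise ValueError("stretch factor xi must exceed 1 (need c_s, dtau > 0)")
    network.positions[:, :, 2] *= xi
    network.box_lengths[2] = Lz * xi
    if relax:
        nsteps = max(int(round(dtau / params.dt)), 1)
        _integrate(network, params, nsteps, noise=True, skin=skin,
                   use_rk4=use_rk4)
    return xi


def run_stretch(network: FibreNetwork, params: ModelParameters,
                eps_max: float = 1.5, c_s: float = 2.5e-3, dtau: float = 2e-6,
                seed: Optional[int] = None, threshold: float = 0.05,
                skin: float = 9e-9, use_rk4: bool = True) -> StretchRecord:
    """Alternate stretch increments and relaxation until eps_z = eps_max.

    Requires a steady-state network with frozen reference lengths and
    reference pair set.  Observables are recorded after each increment's
    relaxation; the strain grid spacing is c_s*dtau/L_z0.
    """
    if network.reference_lengths is None or network.reference_pairs is None:
        raise ValueError("network has no frozen steady state (l0, n_agg^0); "
                         "run the aggregation phase first")
    if seed is not None:
        seed_kernel_rng(seed)
    Lz0 = float(network.box_lengths[2])
    A = float(network.box_lengths[0] * network.box_lengths[1])
    rows = {k: [] for k in ("eps", "Lz", "E", "fs", "bs", "f45", "mo")}

    def record():
        ff = total_field(network, params)
        e = ff.energy
        stats = segment_orientation(network)
        rows["eps"].append(network.box_lengths[2] / Lz0 - 1.0)
        rows["Lz"].append(float(network.box_lengths[2]))
        rows["E"].append([e.W_S, e.W_B, e.W_T, e.W_A, e.W_R])
        rows["fs"].append(stretched_fraction(network, threshold))
        rows["bs"].append(bond_survival(network, network.reference_pairs,
                                        params.a_th))
        rows["f45"].append(float(np.mean(stats.fibre_means <= math.pi / 4)))
        rows["mo"].append(stats.ensemble_mean)

    record()
    while network.box_lengths[2] / Lz0 - 1.0 < eps_max - 1e-12:
        stretch_increment(network, params, c_s=c_s, dtau=dtau, skin=skin,
                          use_rk4=use_rk4)
        record()
    return StretchRecord(
        strain=np.array(rows["eps"]), box_z=np.array(rows["Lz"]),
        energies=np.array(rows["E"]),
        stretched_fraction=np.array(rows["fs"]),
        bond_survival=np.array(rows["bs"]),
        frac_theta_le_45=np.array(rows["f45"]),
        mean_orientation=np.array(rows["mo"]),
        box_z0=Lz0, cross_section=A, c_s=c_s, dtau=dtau)


def moving_average(y: np.ndarray, half_width: int) -> np.ndarray:
    """Centred boxcar with edge truncation (window shrinks near the ends)."""
    n = y.size
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half_width)
        hi = min(n, i + half_width + 1)
        out[i] = y[lo:hi].mean()
    return out


def stress_curve(record: StretchRecord, window: float = 0.08):
    """Engineering stress sigma_z(eps_z) = (1/A) dW/dL_z.

    W_total is moving-averaged over the strain ``window`` first, then
    differentiated along L_z by central differences (one-sided at the ends).
    Returns ``(strain, sigma_z)``.
    """
    eps = record.strain
    if eps.size < 3:
        raise ValueError("need at least 3 strain samples")
    d_eps = float(np.median(np.diff(eps)))
    if window < d_eps:
        raise ValueError(f"window {window} smaller than the strain grid "
                         f"spacing {d_eps:.4g}")
    half = max(int(round(0.5 * window / d_eps)), 1)
    W = moving_average(record.total_energy, half)
    sigma = np.gradient(W, record.box_z) / record.cross_section
    return eps, sigma


def fit_modulus(sigma: np.ndarray, eps: np.ndarray,
                fit_range=(0.05, 0.15)):
    """Least-squares line sigma_z = E*eps_z + sigma_0 over ``fit_range``.

    Returns ``(E, sigma_0)`` in pascals.
    """
    eps = np.asarray(eps)
    sigma = np.asarray(sigma)
    m = (eps >= fit_range[0]) & (eps <= fit_range[1])
    if m.sum() < 3:
        raise ValueError("need at least 3 points inside the fit range")
    if np.ptp(eps[m]) <= 0:
        raise ValueError("degenerate strain values in the fit range")
    E, s0 = np.polyfit(eps[m], sigma[m], 1)
    return float(E), float(s0)
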