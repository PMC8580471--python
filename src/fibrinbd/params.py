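"""Model parameters, unit handling and periodic-box geometry helpers.

Internally everything is SI (metres, seconds, joules, newtons).  The config
loader accepts the bench units the fibrin literature uses (nm, mPa s, ns) and
converts once at load time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

KB_BOLTZMANN = 1.38e-23  # J/K


def friction_coefficient(mu: float, a: float) -> float:
    """Stokes drag c = 6 pi mu a for a sphere of radius ``a`` in a solvent of
    viscosity ``mu``."""
    if mu <= 0 or a <= 0:
        raise ValueError("viscosity and radius must be positive")
    return 6.0 * math.pi * mu * a


def minimum_image(displacement, box_lengths):
    """Map each displacement component into [-L/2, L/2) (nearest periodic
    image).  Works on single 3-vectors or (..., 3) arrays."""
    d = np.asarray(displacement, dtype=float)
    L = np.asarray(box_lengths, dtype=float)
    if np.any(L <= 0):
        raise ValueError("box lengths must be positive")
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite displacement")
    out = d - L * np.floor(d / L + 0.5)
    # rounding at the boundary can land on +L/2 or just below -L/2; fold so
    # the result is always in [-L/2, L/2) and the map is idempotent
    out = np.where(out >= 0.5 * L, out - L, out)
    return np.where(out < -0.5 * L, out + L, out)


@dataclass(frozen=True)
class EnergyBreakdown:
    """Potential energy split into the five model terms (joules)."""

    W_S: float = 0.0
    W_B: float = 0.0
    W_T: float = 0.0
    W_A: float = 0.0
    W_R: float = 0.0

    @property
    def W_total(self) -> float:
        return self.W_S + self.W_B + self.W_T + self.W_A + self.W_R

    def as_dict(self) -> dict:
        return {"W_S": self.W_S, "W_B": self.W_B, "W_T": self.W_T,
                "W_A": self.W_A, "W_R": self.W_R, "W_total": self.W_total}


@dataclass
class ModelParameters:
    """All model constants plus numerical settings.

    Defaults are the baseline fibrin protofibril values: 8 nm fibrinogen
    radius, 22.5 nm segment rest length (half the fibrinogen length), harmonic
    constants k^S = 0.01 N/m, k^B = 1e-18 J/rad^2, k^T = 1e-23 J/rad^2,
    k^A = 2e-3 N/m, k^R = 1e-3 N/m, plasma viscosity 1.2 mPa s at 300 K.
    Derived quantities: aggregation threshold a_th = 2 r0_S (one fibrinogen
    length), aggregation/repulsion rest lengths r0_A = r0_R = 2 a (fibrinogen
    diameter) and Stokes friction c = 6 pi mu a.
    """

    a: float = 8e-9
    r0_S: float = 22.5e-9
    theta0: float = math.pi
    phi0: float = 0.0
    k_S: float = 0.01
    k_B: float = 1e-18
    k_T: float = 1e-23
    k_A: float = 2e-3
    k_R: float = 1e-3
    mu: float = 1.2e-3
    temperature: float = 300.0
    kb: float = KB_BOLTZMANN
    dt: float = 2e-9
    seed: int = 0
    nodes_per_fibre: int = 22
    n_fibres: int = 1215
    box: tuple = (3e-6, 3e-6, 3e-6)
    concentration: float = 0.5  # mg/ml == kg/m^3
    #: "nearest": persistent bonds, each node binding up to
    #: ``max_bonds_per_node`` mutual-nearest foreign nodes inside a_th and
    #: dissociating only when a pair leaves the a_th shell (production
    #: default; bounded bond multiplicity); "all": every inter-fibre pair
    #: inside a_th carries the harmonic attraction, recomputed statelessly.
    aggregation_mode: str = "nearest"
    #: aggregation bonds per node under the "nearest" rule (a node region
    #: carries two aC binding arms)
    max_bonds_per_node: int = 2

    def __post_init__(self):
        for name in ("a", "r0_S", "k_S", "k_B", "k_T", "k_A", "k_R", "mu",
                     "temperature", "kb", "dt", "concentration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.nodes_per_fibre < 4:
            raise ValueError("nodes_per_fibre must be >= 4 (torsion needs 4 nodes)")
        if self.n_fibres < 1:
            raise ValueError("n_fibres must be >= 1")
        if len(self.box) != 3 or any(L <= 0 for L in self.box):
            raise ValueError("box must be three positive edge lengths")
        if self.aggregation_mode not in ("nearest", "all"):
            raise ValueError("aggregation_mode must be 'nearest' or 'all'")
        if self.max_bonds_per_node < 1:
            raise ValueError("max_bonds_per_node must be >= 1")
        check_timestep(self)

    # -- derived, cached ----------------------------------------------------
    @property
    def a_th(self) -> float:
        return 2.0 * self.r0_S

    @property
    def r0_A(self) -> float:
        return 2.0 * self.a

    @property
    def r0_R(self) -> float:
        return 2.0 * self.a

    @property
    def c(self) -> float:
        return friction_coefficient(self.mu, self.a)

    @property
    def kbT(self) -> float:
        return self.kb * self.temperature

    @property
    def noise_sigma(self) -> float:
        """Random-force magnitude, sigma^2 = 2 c k_b T."""
        return math.sqrt(2.0 * self.c * self.kbT)

    @property
    def fibre_length(self) -> float:
        return (self.nodes_per_fibre - 1) * self.r0_S

    def with_(self, **kw) -> "ModelParameters":
        return replace(self, **kw)

    @classmethod
    def from_config(cls, cfg: dict) -> "ModelParameters":
        """Build parameters from a key-value config in bench units.

        Recognized keys (all optional): a_nm, r0S_nm, kS, kB, kT, kA, kR
        (SI: N/m or J/rad^2), mu_mPa_s, T, dt_ns, seed, n_fibres,
        nodes_per_fibre, box_nm (scalar or 3-list), concentration_mg_ml.
        """
        kw = {}
        if "a_nm" in cfg:
            kw["a"] = cfg["a_nm"] * 1e-9
        if "r0S_nm" in cfg:
            kw["r0_S"] = cfg["r0S_nm"] * 1e-9
        for src, dst in (("kS", "k_S"), ("kB", "k_B"), ("kT", "k_T"),
                         ("kA", "k_A"), ("kR", "k_R")):
            if src in cfg:
                kw[dst] = float(cfg[src])
        if "mu_mPa_s" in cfg:
            kw["mu"] = cfg["mu_mPa_s"] * 1e-3
        if "T" in cfg:
            kw["temperature"] = float(cfg["T"])
        if "dt_ns" in cfg:
            kw["dt"] = cfg["dt_ns"] * 1e-9
        if "seed" in cfg:
            kw["seed"] = int(cfg["seed"])
        if "n_fibres" in cfg:
            kw["n_fibres"] = int(cfg["n_fibres"])
        if "nodes_per_fibre" in cfg:
            kw["nodes_per_fibre"] = int(cfg["nodes_per_fibre"])
        if "box_nm" in cfg:
            b = cfg["box_nm"]
            if np.isscalar(b):
                b = (b, b, b)
            kw["box"] = tuple(x * 1e-9 for x in b)
        if "concentration_mg_ml" in cfg:
            kw["concentration"] = float(cfg["concentration_mg_ml"])
        if "aggregation_mode" in cfg:
            kw["aggregation_mode"] = str(cfg["aggregation_mode"])
        return cls(**kw)


def check_timestep(params: "ModelParameters") -> None:
    """Validate the integration step against the stiffest relaxation rates.

    The stretch term is advanced by RK4 (stable to lambda*dt ~ 2.8 on the real
    axis); the remaining terms are advanced by forward Euler (stable to
    lambda*dt < 2).  The stiffest Euler rate comes from the discrete bending
    operator, lambda <= 16 k_B / (r0_S^2 c), and from the pair springs
    2 max(k_A, k_R)/c.  Errors above lambda*dt of 1.0 (Euler) / 2.5 (RK4);
    warns above 75% of those bounds.
    """
    c = friction_coefficient(params.mu, params.a)
    lam_euler = max(16.0 * params.k_B / params.r0_S**2,
                    2.0 * params.k_A, 2.0 * params.k_R) / c
    lam_stretch = 4.0 * params.k_S / c
    ze, zs = lam_euler * params.dt, lam_stretch * params.dt
    if ze > 1.0 or zs > 2.5:
        raise ValueError(
            f"dt={params.dt:.3g}s unstable: euler lambda*dt={ze:.2f} (limit 1.0), "
            f"stretch RK4 lambda*dt={zs:.2f} (limit 2.5)")
    if ze > 0.75 or zs > 1.875:
        warnings.warn(
            f"dt={params.dt:.3g}s is close to the stability limit "
            f"(euler lambda*dt={ze:.2f}, RK4 lambda*dt={zs:.2f})",
            stacklevel=3)


def stable_timestep(params: "ModelParameters", safety: float = 0.7) -> float:
    """Largest dt satisfying the stability margins times ``safety``, capped at
    the parameter default 2 ns."""
    c = friction_coefficient(params.mu, params.a)
    lam_euler = max(16.0 * params.k_B / params.r0_S**2,
                    2.0 * params.k_A, 2.0 * params.k_R) / c
    lam_stretch = 4.0 * params.k_S / c
    return min(2e-9, safety * 1.0 / lam_euler, safety * 2.5 / lam_stretch)
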