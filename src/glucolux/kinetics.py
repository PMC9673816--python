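"""Glucose-oxidase reaction network and Stern-Volmer phosphorescence lifetime.

The sensing chemistry is the classical two-substrate ping-pong cycle of
glucose oxidase (GOx):

    E + G <-> X1 -> E' + gluconate        (k1, k-1; k2)
    E' + O2 <-> X2 -> E + H2O2            (k3, k-3; k4)

where ``E`` is oxidized GOx, ``E'`` reduced GOx and ``X1``/``X2`` the two
enzyme-substrate complexes.  One O2 is consumed per glucose turned over, so
glucose concentration is transduced into local O2 depletion, which in turn
lengthens the lifetime ``tau`` of an O2-quenched phosphor via the
Stern-Volmer relation ``tau0/tau = 1 + ksv*[O2]``.

Enzyme species are immobile; only G and O2 diffuse.  The functions here are
pointwise (NumPy-broadcasting) operators used by :mod:`glucolux.rd_solver`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KineticParams",
    "SternVolmerParams",
    "SpeciesState",
    "reaction_rates",
    "reaction_jacobian",
    "quasi_steady_consumption",
    "lifetime",
    "aggregate_lifetime",
    "o2_in_unit",
]

#: Henry-law solubility of O2 in water at 37 C, mol m^-3 mmHg^-1 (used only
#: when the Stern-Volmer unit convention is mmHg).
O2_SOLUBILITY_PER_MMHG = 1.3e-3


@dataclass(frozen=True)
class KineticParams:
    """GOx rate constants and total enzyme loading.

    Defaults are the sensing-hydrogel values used throughout the package.
    Units: k1, k3 in m^3 mol^-1 s^-1; k-1, k2, k-3, k4 in s^-1; Et in mol/m^3.
    """

    k1: float = 100.0
    km1: float = 0.003
    k2: float = 300.0
    k3: float = 1000.0
    km3: float = 150.0
    k4: float = 50.0
    Et: float = 0.1463

    def __post_init__(self) -> None:
        for name in ("k1", "km1", "k2", "k3", "km3", "k4", "Et"):
            if getattr(self, name) < 0:
                raise ValueError(f"kinetic parameter {name} must be >= 0")


@dataclass(frozen=True)
class SternVolmerParams:
    """Phosphorescence-lifetime calibration of the O2-quenched dye.

    ``ksv`` is expressed per unit of O2 concentration in ``o2_unit``; the
    default convention is uM (so 0.009 mol/m^3 = 9 uM gives tau ~ 166.5 us).
    """

    tau0: float = 201.0  # us
    ksv: float = 0.023
    o2_unit: str = "uM"

    def __post_init__(self) -> None:
        if self.tau0 <= 0:
            raise ValueError("tau0 must be > 0")
        if self.ksv < 0:
            raise ValueError("ksv must be >= 0")
        if self.o2_unit not in ("uM", "mol/m3", "mmHg"):
            raise ValueError(f"unknown o2_unit {self.o2_unit!r}")


@dataclass
class SpeciesState:
    """Concentrations (mol/m^3) of the six species; scalars or ndarrays."""

    G: np.ndarray
    O2: np.ndarray
    E: np.ndarray
    Eprime: np.ndarray
    X1: np.ndarray
    X2: np.ndarray

    @classmethod
    def initial(cls, G, O2, Et, shape=None) -> "SpeciesState":
        """All enzyme oxidized (E = Et), no complexes."""
        if shape is None:
            shape = np.shape(G)
        z = np.zeros(shape)
        return cls(
            G=np.broadcast_to(G, shape).copy(),
            O2=np.broadcast_to(O2, shape).copy(),
            E=np.broadcast_to(Et, shape).copy(),
            Eprime=z.copy(),
            X1=z.copy(),
            X2=z.copy(),
        )

    def enzyme_total(self) -> np.ndarray:
        return self.E + self.Eprime + self.X1 + self.X2


def reaction_rates(state: SpeciesState, params: KineticParams) -> SpeciesState:
    """Reaction-only time derivatives of all six species (diffusion excluded).

    Returns a :class:`SpeciesState` whose fields hold d/dt of each species.
    Raises ``ValueError`` on negative concentrations.
    """
    for name in ("G", "O2", "E", "Eprime", "X1", "X2"):
        if np.any(np.asarray(getattr(state, name)) < 0):
            raise ValueError(f"negative concentration in species {name}")
    p = params
    v1 = p.k1 * state.G * state.E          # E + G -> X1
    vm1 = p.km1 * state.X1                 # X1 -> E + G
    v2 = p.k2 * state.X1                   # X1 -> E' + gluconate
    v3 = p.k3 * state.O2 * state.Eprime    # E' + O2 -> X2
    vm3 = p.km3 * state.X2                 # X2 -> E' + O2
    v4 = p.k4 * state.X2                   # X2 -> E + H2O2
    return SpeciesState(
        G=-v1 + vm1,
        O2=-v3 + vm3,
        E=-v1 + vm1 + v4,
        Eprime=v2 - v3 + vm3,
        X1=v1 - (p.km1 + p.k2) * state.X1,
        X2=v3 - (p.km3 + p.k4) * state.X2,
    )


def reaction_jacobian(state: SpeciesState, params: KineticParams) -> np.ndarray:
    """Jacobian of :func:`reaction_rates` w.r.t. (G, O2, E, E', X1, X2).

    Shape ``state.G.shape + (6, 6)``; used by the implicit reaction update.
    """
    p = params
    G = np.asarray(state.G, dtype=float)
    shape = G.shape
    J = np.zeros(shape + (6, 6))
    O2, E, Ep = state.O2, state.E, state.Eprime
    # rows: dG, dO2, dE, dE', dX1, dX2; cols: G, O2, E, E', X1, X2
    J[..., 0, 0] = -p.k1 * E
    J[..., 0, 2] = -p.k1 * G
    J[..., 0, 4] = p.km1
    J[..., 1, 1] = -p.k3 * Ep
    J[..., 1, 3] = -p.k3 * O2
    J[..., 1, 5] = p.km3
    J[..., 2, 0] = -p.k1 * E
    J[..., 2, 2] = -p.k1 * G
    J[..., 2, 4] = p.km1
    J[..., 2, 5] = p.k4
    J[..., 3, 1] = -p.k3 * Ep
    J[..., 3, 3] = -p.k3 * O2
    J[..., 3, 4] = p.k2
    J[..., 3, 5] = p.km3
    J[..., 4, 0] = p.k1 * E
    J[..., 4, 2] = p.k1 * G
    J[..., 4, 4] = -(p.km1 + p.k2)
    J[..., 5, 1] = p.k3 * Ep
    J[..., 5, 3] = p.k3 * O2
    J[..., 5, 5] = -(p.km3 + p.k4)
    return J


def quasi_steady_consumption(G, O2, params: KineticParams):
    """Quasi-steady-state consumption rates of glucose and O2 (mol m^-3 s^-1).

    Solves dE = dE' = dX1 = dX2 = 0 under E + E' + X1 + X2 = Et.  With
    ``alpha = k1 G/(k-1+k2)`` and ``beta = k3 O2/(k-3+k4)`` the cycle flux is

        R = k2 alpha Et / (1 + alpha + (k2 alpha / k4) (1 + 1/beta))

    and the glucose and O2 rates are both equal to R (one O2 per glucose).
    Both rates are returned (positive = consumption); they are identical.
    """
    G = np.asarray(G, dtype=float)
    O2 = np.asarray(O2, dtype=float)
    if np.any(G < 0) or np.any(O2 < 0):
        raise ValueError("concentrations must be >= 0")
    p = params
    alpha = p.k1 * G / (p.km1 + p.k2)
    beta = p.k3 * O2 / (p.km3 + p.k4)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_beta = np.where(beta > 0, 1.0 / np.where(beta > 0, beta, 1.0), np.inf)
        denom = 1.0 + alpha + (p.k2 * alpha / p.k4) * (1.0 + inv_beta)
        rate = np.where(
            (alpha > 0) & (beta > 0), p.k2 * alpha * p.Et / denom, 0.0
        )
    rate = rate[()] if rate.ndim == 0 else rate
    return rate, rate


def o2_in_unit(o2_mol_per_m3, unit: str):
    """Convert an O2 concentration from mol/m^3 to the given unit."""
    c = np.asarray(o2_mol_per_m3, dtype=float)
    if unit == "mol/m3":
        out = c
    elif unit == "uM":
        out = c * 1e3  # 1 mol/m^3 = 1 mM = 1000 uM
    elif unit == "mmHg":
        out = c / O2_SOLUBILITY_PER_MMHG
    else:
        raise ValueError(f"unknown o2_unit {unit!r}")
    return out[()] if out.ndim == 0 else out


def lifetime(O2, sv: SternVolmerParams):
    """Phosphorescence lifetime tau (us) at quencher concentration ``O2``.

    ``O2`` must already be expressed in ``sv.o2_unit``:
    ``tau = tau0 / (1 + ksv * O2)``.
    """
    O2 = np.asarray(O2, dtype=float)
    if np.any(O2 < 0):
        raise ValueError("O2 must be >= 0")
    tau = sv.tau0 / (1.0 + sv.ksv * O2)
    return tau[()] if tau.ndim == 0 else tau


def aggregate_lifetime(tau, weights=None) -> float:
    """Volume-weighted mean lifetime over the sensing domain.

    ``weights`` defaults to uniform (equal cell volumes); pass emission
    intensities for intensity weighting.
    """
    tau = np.asarray(tau, dtype=float).ravel()
    if tau.size == 0:
        raise ValueError("empty sensor domain")
    if weights is None:
        return float(tau.mean())
    w = np.asarray(weights, dtype=float).ravel()
    if w.shape != tau.shape:
        raise ValueError("weights shape mismatch")
    s = w.sum()
    if s <= 0:
        raise ValueError("weights must have positive sum")
    return float((tau * w).sum() / s)
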