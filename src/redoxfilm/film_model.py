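"""1D reaction-diffusion model of a hydrogenase / viologen redox film.

The film occupies the normalized coordinate xi in [0, 1], with xi = 0 at the
electrode and xi = 1 at the film/solution interface.  Five species are
followed: oxidized and reduced mediator (V_ox, V_red, transported by
electron hopping modelled as apparent diffusion with coefficient ``d_e``),
dissolved H2 and O2 (molecular diffusion), and the enzyme, which is immobile
and partitioned between active, reversibly inactive and irreversibly dead
pools.

Chemistry
---------
Enzyme (net rate r > 0 means H2 oxidation)::

    H2 + 2 V_ox  <->  2 H+ + 2 V_red

Mediator/O2 scavenging (rate q)::

    O2 + s_o2 V_red  ->  products + s_o2 V_ox

The enzyme rate law is a reversible two-substrate form

    r = e_active * k_cat_ox * (a_ox - C * a_red) / (1 + a_ox + a_red)
    a_ox = (v_ox/K_vox)^2 * (h2/K_h2),   a_red = (v_red/K_vred)^2

with the constant C fixed by detailed balance so that r = 0 exactly when
the local mediator Nernst potential E_V equals the H+/H2 equilibrium
potential at the local H2 activity.

The enzyme senses the *local* mediator Nernst potential: the reversible
(anaerobic) inactivation rates are

    k_i = k_x exp(+alpha (E_V - E_inact)/2)
    k_a = k_x exp(-alpha (E_V - E_inact)/2)

so that the two are equal at E_inact, and O2 adds a parallel
active -> inactive channel at rate k_inact_o2*[O2], a fraction ``phi_irr``
of which is diverted to the dead pool.

Boundary conditions: the mediator is confined to the film (zero flux at
xi = 1) and equilibrated with the electrode at xi = 0 (Nernstian boundary,
no interfacial resistance); the substrates are zero-flux at the electrode
and fixed at partition-scaled bulk values at xi = 1.

The current density is the electron flux at the electrode,
j = F * d_e * d[V_red]/dx at x = 0, positive for H2 oxidation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import solve_banded
from scipy import sparse

from .potentials import F, R, PotentialValue, RedoxCouple, h2_equilibrium_potential

__all__ = [
    "EnzymeKinetics",
    "InactivationModel",
    "FilmParameters",
    "BoundaryConditions",
    "SpeciesProfile",
    "TransientResult",
    "SolverError",
    "enzyme_net_rate",
    "inactivation_rate_pair",
    "inactive_fraction",
    "electrode_boundary_ratio",
    "solve_steady_state",
    "equilibrated_profile",
    "solve_transient",
    "nernst_profile",
    "current_from_profile",
    "estimate_front_speed",
    "front_position",
    "reaction_layer",
    "layer_potential",
    "rate_density",
    "write_profile",
    "read_profile",
    "load_config",
    "dump_config",
]


class SolverError(RuntimeError):
    """Raised when a solver fails to converge; carries the last residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnzymeKinetics:
    """Kinetic constants of the bidirectional H+/H2 conversion.

    k_cat_ox : maximal H2-oxidation turnover, s^-1
    K_h2     : H2 affinity, mol m^-3
    K_vox    : oxidized-mediator affinity, mol m^-3
    K_vred   : reduced-mediator affinity, mol m^-3
    """

    k_cat_ox: float = 1000.0
    K_h2: float = 0.1
    K_vox: float = 1.0
    K_vred: float = 100.0

    def __post_init__(self) -> None:
        for name in ("k_cat_ox", "K_h2", "K_vox", "K_vred"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class InactivationModel:
    """Potential- and O2-driven interconversion of the enzyme pools.

    e_inact    : potential (V vs SHE) where inactivation and reactivation
                 rate constants are equal
    k_x        : shared rate magnitude at e_inact, s^-1
    alpha      : exponential potential sensitivity, V^-1
    k_inact_o2 : O2-driven inactivation rate constant, m^3 mol^-1 s^-1
    phi_irr    : fraction of O2-driven inactivation events that are
                 irreversible (dead pool), in [0, 1]
    k_cap      : ceiling on the conformational transition rate, s^-1: where
                 max(k_i, k_a) exceeds this, both are scaled down together,
                 preserving their ratio (and hence every steady state).  The
                 cysteine-gate motion is a slow conformational change, so the
                 exponential laws saturate at this shared ceiling; it also
                 bounds the fastest relaxation rate the integrator follows.
    """

    e_inact: float = -0.25
    k_x: float = 0.1
    alpha: float = 79.0
    k_inact_o2: float = 100.0
    phi_irr: float = 0.0
    k_cap: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.phi_irr <= 1.0):
            raise ValueError("phi_irr must lie in [0, 1]")
        if self.k_x <= 0 or self.k_cap <= 0:
            raise ValueError("k_x and k_cap must be positive")
        if self.k_inact_o2 < 0:
            raise ValueError("k_inact_o2 must be non-negative")


@dataclass(frozen=True)
class FilmParameters:
    """Full physical/kinetic description of one enzyme-film electrode.

    Lengths in m, concentrations in mol m^-3, diffusivities in m^2 s^-1,
    temperature in K.  ``s_o2`` is the number of reduced-mediator
    equivalents consumed per O2 scavenged (1, 2 or 4).  ``h2_solubility``
    is the dissolved H2 concentration in equilibrium with 1 bar, used as
    the activity reference of the H+/H2 couple inside the film.
    """

    thickness: float = 1.0e-6
    v_total: float = 100.0
    d_e: float = 1.0e-12
    d_h2: float = 1.0e-9
    d_o2: float = 1.0e-9
    part_h2: float = 1.0
    part_o2: float = 1.0
    e_total: float = 10.0
    mediator: RedoxCouple = field(default_factory=lambda: RedoxCouple(-0.40, 1, "DV2"))
    kinetics: EnzymeKinetics = field(default_factory=EnzymeKinetics)
    inactivation: InactivationModel = field(default_factory=InactivationModel)
    k_o2_v: float = 1000.0
    s_o2: int = 1
    temperature: float = 293.15
    pH: float = 7.0
    h2_solubility: float = 0.78

    def __post_init__(self) -> None:
        for name in ("thickness", "v_total", "d_e", "d_h2", "d_o2", "part_h2",
                     "part_o2", "e_total", "h2_solubility"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.s_o2 not in (1, 2, 4):
            raise ValueError("s_o2 must be one of {1, 2, 4}")
        if self.k_o2_v < 0:
            raise ValueError("k_o2_v must be non-negative")

    @property
    def f(self) -> float:
        """F/RT in V^-1."""
        return F / (R * self.temperature)

    def e_eq(self, p_h2: float = 1.0) -> float:
        """H+/H2 equilibrium potential (V vs SHE) at the film pH."""
        return h2_equilibrium_potential(self.pH, p_h2=p_h2).value

    def k_thermo(self) -> float:
        """Equilibrium value of (v_ox/v_red)^2 * (h2/h2_solubility)."""
        return math.exp(2.0 * self.f * (self.e_eq() - self.mediator.e0))


@dataclass(frozen=True)
class BoundaryConditions:
    """Electrode potential and bulk gas concentrations.

    The mediator is confined (zero flux at xi = 1); the substrates are
    zero-flux at the electrode and take partition-scaled bulk values at
    the film/solution interface.
    """

    electrode_potential: PotentialValue
    bulk_h2: float = 0.78
    bulk_o2: float = 0.0

    def __post_init__(self) -> None:
        if self.bulk_h2 < 0 or self.bulk_o2 < 0:
            raise ValueError("bulk concentrations must be non-negative")
        if self.electrode_potential.scale != "SHE":
            raise ValueError("electrode potential must be given vs SHE")


@dataclass
class SpeciesProfile:
    """Concentrations on the normalized grid plus the Nernst potential.

    ``e_v`` is in volts vs SHE; nodes where the mediator is numerically
    fully oxidized or reduced are flagged NaN rather than raising.
    """

    xi: np.ndarray
    v_ox: np.ndarray
    v_red: np.ndarray
    h2: np.ndarray
    o2: np.ndarray
    e_active: np.ndarray
    e_inactive: np.ndarray
    e_dead: np.ndarray
    e_v: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.xi.size


@dataclass
class TransientResult:
    """Snapshots and the current transient from ``solve_transient``."""

    times: np.ndarray
    profiles: list[SpeciesProfile]
    current: np.ndarray
    potential: np.ndarray


# ---------------------------------------------------------------------------
# Local kinetics
# ---------------------------------------------------------------------------

_EV_CLIP = 1.0e-14  # mediator fraction below which E_V is flagged undefined
_EXP_MAX = 600.0


def _detailed_balance_constant(params: FilmParameters) -> float:
    """C such that a_ox = C * a_red at H+/H2 equilibrium."""
    k = params.kinetics
    return (
        params.k_thermo()
        * params.h2_solubility
        * k.K_vred**2
        / (k.K_vox**2 * k.K_h2)
    )


def enzyme_net_rate(
    v_ox,
    v_red,
    h2,
    params: FilmParameters,
    e_active=None,
):
    """Net enzymatic H2-oxidation rate, mol m^-3 s^-1 (positive = oxidation).

    Reversible two-substrate rate law, linear in the active-enzyme
    concentration, vanishing exactly at the local mediator/H2 equilibrium
    (detailed balance).
    """
    v_ox = np.asarray(v_ox, dtype=float)
    v_red = np.asarray(v_red, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    if np.any(v_ox < 0) or np.any(v_red < 0) or np.any(h2 < 0):
        raise ValueError("concentrations must be non-negative")
    if e_active is None:
        e_active = params.e_total
    k = params.kinetics
    a_ox = (v_ox / k.K_vox) ** 2 * (h2 / k.K_h2)
    a_red = (v_red / k.K_vred) ** 2
    c_eq = _detailed_balance_constant(params)
    rate = e_active * k.k_cat_ox * (a_ox - c_eq * a_red) / (1.0 + a_ox + a_red)
    return rate if rate.shape else float(rate)


def inactivation_rate_pair(e_v, model: InactivationModel):
    """(k_i, k_a) in s^-1 at local Nernst potential ``e_v`` (V vs SHE).

    Both equal ``k_x`` at ``e_inact``; the stiffness cap scales the pair
    together where either would exceed ``k_cap``, preserving the ratio.
    """
    x = np.clip(model.alpha * (np.asarray(e_v, dtype=float) - model.e_inact) / 2.0,
                -_EXP_MAX, _EXP_MAX)
    k_i = model.k_x * np.exp(x)
    k_a = model.k_x * np.exp(-x)
    top = np.maximum(k_i, k_a)
    scale = np.where(top > model.k_cap, model.k_cap / top, 1.0)
    k_i = k_i * scale
    k_a = k_a * scale
    if np.ndim(e_v) == 0:
        return float(k_i), float(k_a)
    return k_i, k_a


def inactive_fraction(e_v, model: InactivationModel, o2=0.0):
    """Steady-state reversibly-inactive fraction at local E_V and [O2].

    e_i/(e_a + e_i) with e_a*(k_i + k_inact_o2*[O2]) = k_a*e_i, using the
    same (ceiling-limited) rate pair as the transient solver.
    """
    k_i, k_a = inactivation_rate_pair(e_v, model)
    k_i = np.asarray(k_i, dtype=float)
    k_a = np.asarray(k_a, dtype=float)
    num = k_i + model.k_inact_o2 * np.asarray(o2, dtype=float)
    frac = num / (num + k_a)
    return float(frac) if np.ndim(frac) == 0 else frac


def electrode_boundary_ratio(
    E: PotentialValue, mediator: RedoxCouple, temperature: float = 293.15
) -> float:
    """V_ox/V_red at xi = 0 for a Nernstian (fast) electrode reaction."""
    if E.scale != "SHE":
        raise ValueError("electrode potential must be on the SHE scale")
    x = mediator.n_electrons * F * (E.value - mediator.e0) / (R * temperature)
    return math.exp(min(max(x, -_EXP_MAX), _EXP_MAX))


def _e_v_from_fraction(u: np.ndarray, params: FilmParameters) -> np.ndarray:
    """Nernst potential (V vs SHE) from the oxidized-mediator fraction."""
    uu = np.clip(u, _EV_CLIP, 1.0 - _EV_CLIP)
    return params.mediator.e0 + (1.0 / params.f) * (np.log(uu) - np.log1p(-uu))


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------


def _reaction_terms(u, h, w, a_frac, params: FilmParameters):
    """Volumetric rates given full node arrays (u = v_ox/v_total etc.).

    Returns (r, q, p_o2) = enzyme rate, mediator/O2 scavenging rate and
    O2 uptake by the enzyme-inactivation channel, all mol m^-3 s^-1.
    """
    v_ox = params.v_total * u
    v_red = params.v_total * (1.0 - u)
    k = params.kinetics
    a_ox = (v_ox / k.K_vox) ** 2 * (h / k.K_h2)
    a_red = (v_red / k.K_vred) ** 2
    c_eq = _detailed_balance_constant(params)
    e_act = params.e_total * a_frac
    r = e_act * k.k_cat_ox * (a_ox - c_eq * a_red) / (1.0 + a_ox + a_red)
    q = params.k_o2_v * w * v_red
    p_o2 = params.inactivation.k_inact_o2 * w * e_act
    return r, q, p_o2


def _laplacian(c: np.ndarray, dxi: float, left: float | None, right: float | None):
    """Second derivative on the xi grid with ghost-node Neumann closures.

    ``left``/``right`` give Dirichlet values; ``None`` means zero flux.
    Dirichlet end nodes get a placeholder (their residual is replaced).
    """
    lap = np.empty_like(c)
    lap[1:-1] = c[2:] - 2.0 * c[1:-1] + c[:-2]
    if left is None:
        lap[0] = 2.0 * (c[1] - c[0])
    else:
        lap[0] = 0.0
    if right is None:
        lap[-1] = 2.0 * (c[-2] - c[-1])
    else:
        lap[-1] = 0.0
    return lap / dxi**2


def _boundary_u(E_she: float, params: FilmParameters) -> float:
    ratio = electrode_boundary_ratio(
        PotentialValue(E_she, "SHE"), params.mediator, params.temperature
    )
    return ratio / (1.0 + ratio)


def _refs(params: FilmParameters, bc: BoundaryConditions):
    """Normalization references for H2 and O2 concentrations."""
    href = params.part_h2 * bc.bulk_h2 if bc.bulk_h2 > 0 else params.h2_solubility
    oref = params.part_o2 * bc.bulk_o2 if bc.bulk_o2 > 0 else 1.0
    return href, oref


# ---------------------------------------------------------------------------
# Steady-state solver (damped Newton, banded FD Jacobian)
# ---------------------------------------------------------------------------


def _steady_residual(z, n, dxi, params, bc, href, oref, u_bc, e_avail):
    u = z[0::3]
    h = z[1::3] * href
    w = z[2::3] * oref
    e_v = _e_v_from_fraction(u, params)
    a_frac = e_avail * (1.0 - inactive_fraction(e_v, params.inactivation, o2=w))
    r, q, p_o2 = _reaction_terms(u, h, w, a_frac, params)
    L2 = params.thickness**2

    res_u = (params.d_e / L2) * _laplacian(u, dxi, left=0.0, right=None) + (
        -2.0 * r + params.s_o2 * q
    ) / params.v_total
    res_u[0] = u[0] - u_bc

    res_h = (params.d_h2 / L2) * _laplacian(h, dxi, left=None, right=0.0) / href - r / href
    res_h[-1] = z[1::3][-1] - (params.part_h2 * bc.bulk_h2) / href

    if bc.bulk_o2 > 0:
        res_w = (params.d_o2 / L2) * _laplacian(w, dxi, left=None, right=0.0) / oref - (
            q + p_o2
        ) / oref
        res_w[-1] = z[2::3][-1] - (params.part_o2 * bc.bulk_o2) / oref
    else:
        res_w = z[2::3]

    out = np.empty_like(z)
    out[0::3] = res_u
    out[1::3] = res_h
    out[2::3] = res_w
    return out


def _newton_banded(fun, z0, bw=3, tol=1.0e-9, max_iter=80):
    """Damped Newton with a banded finite-difference Jacobian.

    ``tol`` is an absolute bound on the residual inf-norm, relaxed by a
    1e-10 relative factor against the initial residual scale.
    """
    z = z0.copy()
    f = fun(z)
    n = z.size
    stride = 2 * bw + 1
    eps = math.sqrt(np.finfo(float).eps)
    tol = max(tol, 1.0e-10 * float(np.max(np.abs(f))))
    for _ in range(max_iter):
        norm = float(np.max(np.abs(f)))
        if norm < tol:
            return z, norm, True
        # banded Jacobian by coloring: columns j with j % stride equal can
        # be perturbed together since their row supports do not overlap
        ab = np.zeros((stride, n))
        for color in range(stride):
            idx = np.arange(color, n, stride)
            dz = eps * np.maximum(1.0, np.abs(z[idx]))
            zp = z.copy()
            zp[idx] += dz
            df = (fun(zp) - f)
            for j, d in zip(idx, dz):
                lo = max(0, j - bw)
                hi = min(n, j + bw + 1)
                rows = np.arange(lo, hi)
                ab[bw + rows - j, j] = df[rows] / d
        try:
            step = solve_banded((bw, bw), ab, -f)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise SolverError(f"Jacobian solve failed: {exc}", residual=norm)
        lam = 1.0
        while lam > 1.0e-6:
            z_new = z + lam * step
            z_new[0::3] = np.clip(z_new[0::3], 0.0, 1.0)
            z_new[1::3] = np.maximum(z_new[1::3], 0.0)
            z_new[2::3] = np.maximum(z_new[2::3], 0.0)
            f_new = fun(z_new)
            if np.max(np.abs(f_new)) < norm * (1.0 - 1.0e-4 * lam) or np.max(
                np.abs(f_new)
            ) < tol:
                break
            lam *= 0.5
        else:
            norm = float(np.max(np.abs(f)))
            return z, norm, norm < tol  # stalled; caller decides on fallback
        z, f = z_new, f_new
    norm = float(np.max(np.abs(f)))
    return z, norm, norm < tol


def _assemble_profile(u, h, w, params, bc, e_avail=1.0, a_frac=None, i_frac=None):
    n = u.size
    xi = np.linspace(0.0, 1.0, n)
    e_v = _e_v_from_fraction(u, params)
    undef = (u <= _EV_CLIP) | (u >= 1.0 - _EV_CLIP)
    e_v = np.where(undef, np.nan, e_v)
    if a_frac is None:
        ifr = inactive_fraction(
            _e_v_from_fraction(u, params), params.inactivation, o2=w
        )
        a_frac = e_avail * (1.0 - ifr)
        i_frac = e_avail * ifr
    dead = np.maximum(1.0 - a_frac - i_frac, 0.0)
    return SpeciesProfile(
        xi=xi,
        v_ox=params.v_total * u,
        v_red=params.v_total * (1.0 - u),
        h2=h.copy(),
        o2=w.copy(),
        e_active=params.e_total * np.asarray(a_frac, dtype=float),
        e_inactive=params.e_total * np.asarray(i_frac, dtype=float),
        e_dead=params.e_total * dead,
        e_v=e_v,
    )


def solve_steady_state(
    params: FilmParameters,
    bc: BoundaryConditions,
    n_nodes: int = 200,
    tol: float = 1.0e-8,
    e_dead_frac: float = 0.0,
) -> tuple[SpeciesProfile, float]:
    """Steady state of the film and the catalytic current density (A m^-2).

    The enzyme pools are at local equilibrium with the Nernst potential (and
    [O2], with the dead pool frozen at ``e_dead_frac``), which is exact at
    steady state.  Damped Newton on the discretized balance equations with a
    pseudo-transient fallback; raises :class:`SolverError` on failure.
    """
    if n_nodes < 50:
        raise ValueError("grid size must be at least 50 nodes")
    href, oref = _refs(params, bc)
    dxi = 1.0 / (n_nodes - 1)
    E = bc.electrode_potential.value
    u_bc = _boundary_u(E, params)
    e_avail = 1.0 - e_dead_frac

    # initial guess: electrode value relaxing to the H+/H2-equilibrated film
    h_hat = max(bc.bulk_h2 * params.part_h2 / href, 1.0e-6) if bc.bulk_h2 > 0 else 1e-6
    rho_eq = math.sqrt(
        params.k_thermo() / max(bc.bulk_h2 * params.part_h2 / params.h2_solubility, 1e-12)
    ) if bc.bulk_h2 > 0 else math.exp(params.f * (E - params.mediator.e0))
    u_eq = rho_eq / (1.0 + rho_eq)
    xi = np.linspace(0.0, 1.0, n_nodes)
    u0 = u_eq + (u_bc - u_eq) * np.exp(-xi / 0.05)
    z0 = np.empty(3 * n_nodes)
    z0[0::3] = u0
    z0[1::3] = 1.0 if bc.bulk_h2 > 0 else 0.0
    z0[2::3] = xi**2 if bc.bulk_o2 > 0 else 0.0

    fun = lambda z: _steady_residual(z, n_nodes, dxi, params, bc, href, oref, u_bc, e_avail)
    z, resid, converged = _newton_banded(fun, z0, tol=tol)
    if not converged:
        # pseudo-transient fallback: march the full transient for a few
        # mediator-diffusion times from the crude guess, then polish
        t_relax = 30.0 * params.thickness**2 / params.d_e
        guess = _assemble_profile(
            z0[0::3], z0[1::3] * href, z0[2::3] * oref, params, bc, e_avail=e_avail
        )
        res = solve_transient(
            params, bc, t_end=t_relax, snapshots=[t_relax], n_nodes=n_nodes,
            initial=guess,
        )
        prof = res.profiles[-1]
        z1 = np.empty(3 * n_nodes)
        z1[0::3] = prof.v_ox / params.v_total
        z1[1::3] = prof.h2 / href
        z1[2::3] = prof.o2 / oref
        z, resid, converged = _newton_banded(fun, z1, tol=tol)
        if not converged:
            raise SolverError(
                f"steady-state solver did not converge (residual {resid:.3e})",
                residual=resid,
            )
    u = z[0::3]
    h = z[1::3] * href
    w = z[2::3] * oref
    profile = _assemble_profile(u, h, w, params, bc, e_avail=e_avail)
    return profile, current_from_profile(profile, params)




def equilibrated_profile(
    params: FilmParameters,
    bc: BoundaryConditions,
    n_nodes: int = 200,
    fully_active: bool = True,
) -> SpeciesProfile:
    """Uniform film at H+/H2 equilibrium with the bulk, as an initial state.

    Useful as a neutral, non-steady starting point for transient runs (the
    true steady state under bias differs from it near the electrode).
    """
    h_hat = params.part_h2 * bc.bulk_h2 / params.h2_solubility
    if h_hat > 0:
        rho = math.sqrt(params.k_thermo() / h_hat)
    else:
        rho = 1.0
    u = np.full(n_nodes, rho / (1.0 + rho))
    h = np.full(n_nodes, params.part_h2 * bc.bulk_h2)
    w = np.zeros(n_nodes)
    if fully_active:
        a = np.ones(n_nodes)
        ei = np.zeros(n_nodes)
        return _assemble_profile(u, h, w, params, bc, a_frac=a, i_frac=ei)
    return _assemble_profile(u, h, w, params, bc)


# ---------------------------------------------------------------------------
# Transient solver (method of lines, BDF)
# ---------------------------------------------------------------------------


def _pack(u, h, w, a, ei):
    return np.concatenate([u[1:], h[:-1], w[:-1], a, ei])


def _unpack(y, n, u_bc, h_bc_hat, w_bc_hat):
    u = np.empty(n)
    u[0] = u_bc
    u[1:] = y[: n - 1]
    h = np.empty(n)
    h[:-1] = y[n - 1 : 2 * n - 2]
    h[-1] = h_bc_hat
    w = np.empty(n)
    w[:-1] = y[2 * n - 2 : 3 * n - 3]
    w[-1] = w_bc_hat
    a = y[3 * n - 3 : 4 * n - 3]
    ei = y[4 * n - 3 : 5 * n - 3]
    return u, h, w, a, ei


def _transient_sparsity(n: int) -> sparse.csr_matrix:
    m = 5 * n - 3
    pat = sparse.lil_matrix((m, m), dtype=np.int8)

    def iu(k):  # node k >= 1
        return k - 1

    def ih(k):  # node k <= n-2
        return (n - 1) + k

    def iw(k):
        return 2 * (n - 1) + k

    def ia(k):
        return 3 * (n - 1) + k

    def ie(k):
        return 3 * (n - 1) + n + k

    for k in range(n):
        local = []
        if 1 <= k <= n - 1:
            local.append(iu(k))
        if k <= n - 2:
            local.append(ih(k))
            local.append(iw(k))
        local.append(ia(k))
        local.append(ie(k))
        neighbors = []
        for kk in (k - 1, k + 1):
            if 1 <= kk <= n - 1:
                neighbors.append(("u", kk))
            if 0 <= kk <= n - 2:
                neighbors.append(("h", kk))
                neighbors.append(("w", kk))
        for row in local:
            for col in local:
                pat[row, col] = 1
        # diffusion coupling, species-wise
        if 1 <= k <= n - 1:
            for kk in (k - 1, k + 1):
                if 1 <= kk <= n - 1:
                    pat[iu(k), iu(kk)] = 1
        if k <= n - 2:
            for kk in (k - 1, k + 1):
                if 0 <= kk <= n - 2:
                    pat[ih(k), ih(kk)] = 1
                    pat[iw(k), iw(kk)] = 1
    return pat.tocsr()


def solve_transient(
    params: FilmParameters,
    bc: BoundaryConditions,
    t_end: float,
    snapshots: Sequence[float] | None = None,
    initial: SpeciesProfile | None = None,
    potential_program: Callable[[float], float] | None = None,
    n_nodes: int = 200,
    rtol: float = 1.0e-8,
    atol: float = 1.0e-12,
    method: str = "BDF",
) -> TransientResult:
    """Method-of-lines integration of the full model.

    ``potential_program(t)`` (V vs SHE) overrides the constant electrode
    potential in ``bc``; the initial condition defaults to the anaerobic
    steady state at the initial potential.  ``snapshots`` are honored
    exactly via ``t_eval``.
    """
    href, oref = _refs(params, bc)
    n = n_nodes
    dxi = 1.0 / (n - 1)
    L2 = params.thickness**2
    model = params.inactivation

    if potential_program is None:
        E0 = bc.electrode_potential.value
        program = lambda t: E0
    else:
        program = potential_program

    if initial is None:
        bc0 = replace(
            bc,
            electrode_potential=PotentialValue(program(0.0), "SHE"),
            bulk_o2=0.0,
        )
        initial, _ = solve_steady_state(params, bc0, n_nodes=n)
    elif initial.n_nodes != n:
        raise ValueError("initial profile grid does not match n_nodes")

    u0 = initial.v_ox / params.v_total
    h0 = initial.h2 / href
    w0 = initial.o2 / oref
    a0 = initial.e_active / params.e_total
    ei0 = initial.e_inactive / params.e_total
    y0 = _pack(u0, h0, w0, a0, ei0)

    h_bc_hat = params.part_h2 * bc.bulk_h2 / href
    w_bc_hat = params.part_o2 * bc.bulk_o2 / oref

    def rhs(t, y):
        u, h_hat, w_hat, a, ei = _unpack(y, n, _boundary_u(program(t), params),
                                         h_bc_hat, w_bc_hat)
        h = h_hat * href
        w = w_hat * oref
        e_v = _e_v_from_fraction(u, params)
        r, q, p_o2 = _reaction_terms(u, h, w, a, params)
        k_i, k_a = inactivation_rate_pair(e_v, model)
        k_o2 = model.k_inact_o2 * w

        du = (params.d_e / L2) * _laplacian(u, dxi, left=0.0, right=None) + (
            -2.0 * r + params.s_o2 * q
        ) / params.v_total
        dh = (params.d_h2 / L2) * _laplacian(h_hat, dxi, left=None, right=0.0) - r / href
        dw = (params.d_o2 / L2) * _laplacian(w_hat, dxi, left=None, right=0.0) - (
            q + p_o2
        ) / oref
        da = -(k_i + k_o2) * a + k_a * ei
        dei = k_i * a + (1.0 - model.phi_irr) * k_o2 * a - k_a * ei
        return np.concatenate([du[1:], dh[:-1], dw[:-1], da, dei])

    if snapshots is None:
        t_eval = np.linspace(0.0, t_end, 201)
    else:
        t_eval = np.unique(np.concatenate([[0.0], np.asarray(snapshots, dtype=float)]))
        if t_eval[-1] > t_end + 1e-12:
            raise ValueError("snapshot times must not exceed t_end")

    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        y0,
        method=method,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        jac_sparsity=_transient_sparsity(n),
    )
    if not sol.success:
        raise SolverError(f"transient integrator failed: {sol.message}")

    profiles: list[SpeciesProfile] = []
    current = np.empty(sol.t.size)
    potential = np.empty(sol.t.size)
    for j, t in enumerate(sol.t):
        u, h_hat, w_hat, a, ei = _unpack(
            sol.y[:, j], n, _boundary_u(program(t), params), h_bc_hat, w_bc_hat
        )
        prof = _assemble_profile(
            u, h_hat * href, w_hat * oref, params, bc, a_frac=a, i_frac=ei
        )
        profiles.append(prof)
        current[j] = current_from_profile(prof, params)
        potential[j] = program(t)
    return TransientResult(times=sol.t, profiles=profiles, current=current,
                           potential=potential)


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------


def nernst_profile(
    profile: SpeciesProfile, mediator: RedoxCouple, temperature: float = 293.15
) -> np.ndarray:
    """Nernst potential per node (V vs SHE); undefined nodes are NaN."""
    with np.errstate(divide="ignore", invalid="ignore"):
        e_v = mediator.e0 + (R * temperature / (mediator.n_electrons * F)) * np.log(
            profile.v_ox / profile.v_red
        )
    bad = (profile.v_ox <= 0) | (profile.v_red <= 0)
    return np.where(bad, np.nan, e_v)


def current_from_profile(profile: SpeciesProfile, params: FilmParameters) -> float:
    """Electrode current density j = F * d_e * d[V_red]/dx at x=0, A m^-2.

    Second-order one-sided finite difference; positive for H2 oxidation.
    """
    n = profile.n_nodes
    if n < 3:
        raise ValueError("grid too coarse for a one-sided gradient (need >= 3 nodes)")
    dxi = profile.xi[1] - profile.xi[0]
    v = profile.v_red
    dv_dxi = (-3.0 * v[0] + 4.0 * v[1] - v[2]) / (2.0 * dxi)
    return F * params.d_e * dv_dxi / params.thickness


def rate_density(profile: SpeciesProfile, params: FilmParameters) -> np.ndarray:
    """Local enzymatic H2-oxidation rate (mol m^-3 s^-1) along the film."""
    return enzyme_net_rate(
        profile.v_ox, profile.v_red, profile.h2, params, e_active=profile.e_active
    )


def reaction_layer(profile: SpeciesProfile, params: FilmParameters,
                   threshold: float = 0.1, u_max: float = 0.9) -> np.ndarray:
    """Boolean mask of the catalytically active, mediator-buffered region.

    Nodes where the enzymatic rate is at least ``threshold`` of its spatial
    maximum *and* the mediator retains reducing capacity (oxidized fraction
    at most ``u_max``).  The second condition excludes the thin
    electrode-equilibration zone where the film is essentially fully
    oxidized and the Nernst potential simply tracks the applied potential.
    """
    r = np.abs(rate_density(profile, params))
    top = float(np.max(r))
    if top <= 0:
        return np.zeros(profile.n_nodes, dtype=bool)
    u = profile.v_ox / (profile.v_ox + profile.v_red)
    return (r >= threshold * top) & (u <= u_max)


def layer_potential(profile: SpeciesProfile, params: FilmParameters) -> float:
    """Rate-weighted mean Nernst potential over the reaction layer, V vs SHE.

    This is the potential the working enzyme population actually
    experiences; for a protective mediator it sits close to the mediator
    E0 (redox buffering).
    """
    mask = reaction_layer(profile, params)
    if not np.any(mask):
        raise ValueError("no catalytic activity in the profile")
    r = np.abs(rate_density(profile, params))[mask]
    return float(np.sum(profile.e_v[mask] * r) / np.sum(r))


def front_position(profile: SpeciesProfile, params: FilmParameters) -> float | None:
    """Position of the inactive-enzyme front.

    Scans from the film/solution interface inward for the first node where
    e_inactive + e_dead exceeds e_total/2 and linearly interpolates the
    crossing; ``None`` if the enzyme is active everywhere.
    """
    half = params.e_total / 2.0
    inact = profile.e_inactive + profile.e_dead
    idx = None
    for k in range(profile.n_nodes - 1, -1, -1):
        if inact[k] > half:
            idx = k
        else:
            break
    if idx is None:
        return None
    if idx == 0:
        return 0.0
    x0, x1 = profile.xi[idx - 1], profile.xi[idx]
    y0, y1 = inact[idx - 1], inact[idx]
    if y1 == y0:
        return float(x1)
    return float(x0 + (half - y0) / (y1 - y0) * (x1 - x0))


def estimate_front_speed(params: FilmParameters, bc: BoundaryConditions) -> float:
    """Closed-form estimate of the O2-inactivation front speed, m s^-1.

    The incoming O2 flux must (i) consume the standing reduced-mediator
    pool that the film holds at H+/H2 equilibrium and (ii) fight the
    electron-hopping resupply that the catalytic interior pushes out across
    the inactivated zone, so the front advances at roughly

        speed = s_o2 * J_O2 / (v_red_eq * (1 + J_e / (s_o2 * J_O2)))

    with J_O2 = d_o2 * [O2]_surface / L the O2 flux scale and
    J_e = d_e * v_red_eq / L the hopping-resupply flux scale.  Lower
    mediator E0 means a smaller equilibrium V_red pool and hence a faster
    front.  Returns 0 for anaerobic conditions and ``inf`` when the film
    holds no reduced mediator.
    """
    if bc.bulk_o2 <= 0:
        return 0.0
    h_hat = params.part_h2 * bc.bulk_h2 / params.h2_solubility
    if h_hat <= 0:
        return math.inf
    rho_eq = math.sqrt(params.k_thermo() / h_hat)
    v_red_eq = params.v_total / (1.0 + rho_eq)
    if v_red_eq <= 0:
        return math.inf
    c_surf = params.part_o2 * bc.bulk_o2
    j_o2 = params.d_o2 * c_surf / params.thickness
    j_e = params.d_e * v_red_eq / params.thickness
    return (
        params.s_o2 * j_o2
        / (v_red_eq * (1.0 + j_e / (params.s_o2 * j_o2)))
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_PROFILE_COLUMNS = [
    "xi", "v_ox", "v_red", "h2", "o2",
    "e_active", "e_inactive", "e_dead", "e_v_she", "e_v_rhe",
]


def write_profile(profile: SpeciesProfile, path, params: FilmParameters,
                  metadata: dict | None = None) -> None:
    """Write a profile as CSV with '#'-prefixed metadata header lines."""
    import pandas as pd

    e_eq = params.e_eq()
    df = pd.DataFrame(
        {
            "xi": profile.xi,
            "v_ox": profile.v_ox,
            "v_red": profile.v_red,
            "h2": profile.h2,
            "o2": profile.o2,
            "e_active": profile.e_active,
            "e_inactive": profile.e_inactive,
            "e_dead": profile.e_dead,
            "e_v_she": profile.e_v,
            "e_v_rhe": profile.e_v - e_eq,
        }
    )
    meta = {"pH": params.pH, "temperature_K": params.temperature,
            "mediator_e0_V_SHE": params.mediator.e0}
    if metadata:
        meta.update(metadata)
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=False)


def read_profile(path) -> "tuple[dict, 'pd.DataFrame']":
    """Read a profile CSV written by :func:`write_profile`."""
    import pandas as pd

    meta: dict = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    return meta, df


def dump_config(params: FilmParameters, bc: BoundaryConditions, path) -> None:
    """Write a YAML config mirroring FilmParameters/BoundaryConditions."""
    import yaml

    doc = {
        "film": {
            "thickness_m": params.thickness,
            "v_total_mol_m3": params.v_total,
            "d_e_m2_s": params.d_e,
            "d_h2_m2_s": params.d_h2,
            "d_o2_m2_s": params.d_o2,
            "part_h2": params.part_h2,
            "part_o2": params.part_o2,
            "e_total_mol_m3": params.e_total,
            "k_o2_v_m3_mol_s": params.k_o2_v,
            "s_o2": params.s_o2,
            "temperature_K": params.temperature,
            "pH": params.pH,
            "h2_solubility_mol_m3_bar": params.h2_solubility,
        },
        "mediator": {
            "e0_V_SHE": params.mediator.e0,
            "n_electrons": params.mediator.n_electrons,
            "label": params.mediator.label,
        },
        "kinetics": {
            "k_cat_ox_s": params.kinetics.k_cat_ox,
            "K_h2_mol_m3": params.kinetics.K_h2,
            "K_vox_mol_m3": params.kinetics.K_vox,
            "K_vred_mol_m3": params.kinetics.K_vred,
        },
        "inactivation": {
            "e_inact_V_SHE": params.inactivation.e_inact,
            "k_x_s": params.inactivation.k_x,
            "alpha_per_V": params.inactivation.alpha,
            "k_inact_o2_m3_mol_s": params.inactivation.k_inact_o2,
            "phi_irr": params.inactivation.phi_irr,
        },
        "boundary": {
            "electrode_potential_V_SHE": bc.electrode_potential.value,
            "bulk_h2_mol_m3": bc.bulk_h2,
            "bulk_o2_mol_m3": bc.bulk_o2,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path) -> tuple[FilmParameters, BoundaryConditions]:
    """Read a YAML config written by :func:`dump_config`."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    film = doc["film"]
    med = doc["mediator"]
    kin = doc["kinetics"]
    ina = doc["inactivation"]
    bnd = doc["boundary"]
    params = FilmParameters(
        thickness=film["thickness_m"],
        v_total=film["v_total_mol_m3"],
        d_e=film["d_e_m2_s"],
        d_h2=film["d_h2_m2_s"],
        d_o2=film["d_o2_m2_s"],
        part_h2=film["part_h2"],
        part_o2=film["part_o2"],
        e_total=film["e_total_mol_m3"],
        mediator=RedoxCouple(med["e0_V_SHE"], med["n_electrons"], med.get("label", "")),
        kinetics=EnzymeKinetics(
            k_cat_ox=kin["k_cat_ox_s"],
            K_h2=kin["K_h2_mol_m3"],
            K_vox=kin["K_vox_mol_m3"],
            K_vred=kin["K_vred_mol_m3"],
        ),
        inactivation=InactivationModel(
            e_inact=ina["e_inact_V_SHE"],
            k_x=ina["k_x_s"],
            alpha=ina["alpha_per_V"],
            k_inact_o2=ina["k_inact_o2_m3_mol_s"],
            phi_irr=ina["phi_irr"],
        ),
        k_o2_v=film["k_o2_v_m3_mol_s"],
        s_o2=film["s_o2"],
        temperature=film["temperature_K"],
        pH=film["pH"],
        h2_solubility=film["h2_solubility_mol_m3_bar"],
    )
    bc = BoundaryConditions(
        electrode_potential=PotentialValue(bnd["electrode_potential_V_SHE"], "SHE"),
        bulk_h2=bnd["bulk_h2_mol_m3"],
        bulk_o2=bnd["bulk_o2_mol_m3"],
    )
    return params, bc
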