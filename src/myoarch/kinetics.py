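"""Integrin binding/unbinding kinetics and the fast-diffusion reduction.

Three density fields live on the lattice: free integrin ``rho_f``, bound
integrin connected to premyofibrils ``rho_p`` and bound integrin connected
to nascent myofibrils ``rho_n``.  The total integrin content Phi0 * A is
conserved exactly: each explicit Euler step moves mass between the bound
pools and a ledgered free pool, and the free pool is then redistributed
instantaneously (membrane diffusion is much faster than any binding
process, so the free field is always at its quasi-steady profile).

The quasi-steady profile under the mutual-alignment biasing potential chi
is the drift-diffusion equilibrium rho_f proportional to exp(-sigma * chi),
where sigma is the ratio of the biased to the plain diffusion coefficient.
With the alignment feature off (tau = False) or sigma = 0 the profile is
uniform over the island.

The fraction of bound integrins actually connected to fibers of each class
follows a Langmuir adsorption isotherm f = rho / (rho + epsilon): linear at
low density, saturating at 1, with half-saturation at the density epsilon.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict
from typing import Optional

import numpy as np

__all__ = [
    "ModelParams",
    "IntegrinState",
    "langmuir_fraction",
    "step_bound_integrins",
    "redistribute_free_integrin",
    "total_integrin",
]


@dataclass(frozen=True)
class ModelParams:
    """Model parameters (defaults are the fitted stair-shape set).

    Rates are per unit simulation time (au).  The time-scale ordering
    follows focal-adhesion formation (fast) < premyofibril assembly
    (intermediate) < nascent-myofibril realignment (slow), compressed into
    simulation units; see docs/methods.md for the calibration.

    Attributes
    ----------
    phi0:
        Total average integrin density; total content is phi0 * A.
    binding_rate:
        Basal free -> premyofibril-bound conversion rate (seeds adhesions
        even at zero force).
    force_binding_rate:
        Force-promoted stabilization: extra binding rate per unit |F|.
    unbinding_rate:
        Premyofibril-bound -> free conversion rate (dominates at low force,
        so unloaded adhesions disassemble).
    maturation_rate:
        Premyofibril -> nascent conversion rate per unit |F|.
    reversion_rate:
        Nascent -> premyofibril back-conversion rate.
    nascent_force_ratio:
        G, ratio of nascent to premyofibril force contribution (> 1: mature
        fibers pull harder).
    epsilon:
        Langmuir half-saturation density of the integrin-fiber connection.
    sigma:
        Biased-to-plain diffusion coefficient ratio (strength of the
        mutual-alignment redistribution).
    zeta:
        Inverse area of the biasing-potential attraction well.
    length_dependent:
        L flag: pair force scales with fiber length when True.
    alignment:
        tau flag: mutual-alignment biasing potential active when True.
    dt, t_total:
        Euler step and default run length in au.  ``t_total_circle`` is the
        extended run length used for the circular island, which needs much
        longer to self-organize.
    """

    phi0: float = 1.0
    binding_rate: float = 0.5
    force_binding_rate: float = 6.0
    unbinding_rate: float = 2.0
    maturation_rate: float = 3.0
    reversion_rate: float = 0.05
    nascent_force_ratio: float = 3.0
    epsilon: float = 0.3
    sigma: float = 15.0
    zeta: float = 100.0
    length_dependent: bool = True
    alignment: bool = True
    dt: float = 0.1
    t_total: float = 600.0
    t_total_circle: float = 1800.0
    angular_bins: int = 36

    def __post_init__(self) -> None:
        for name in (
            "phi0",
            "binding_rate",
            "force_binding_rate",
            "unbinding_rate",
            "maturation_rate",
            "reversion_rate",
            "nascent_force_ratio",
            "sigma",
            "zeta",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.t_total < self.dt:
            raise ValueError("t_total must be >= dt")
        if self.angular_bins < 2:
            raise ValueError("angular_bins must be >= 2")

    def with_(self, **kw) -> "ModelParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class IntegrinState:
    """The three integrin density fields at one instant (flat, one value per
    lattice point)."""

    rho_f: np.ndarray
    rho_p: np.ndarray
    rho_n: np.ndarray
    time: float = 0.0

    @property
    def rho_b(self) -> np.ndarray:
        """Total bound integrin density."""
        return self.rho_p + self.rho_n

    def copy(self) -> "IntegrinState":
        return IntegrinState(
            self.rho_f.copy(), self.rho_p.copy(), self.rho_n.copy(), self.time
        )


def langmuir_fraction(bound_density: np.ndarray, epsilon: float) -> np.ndarray:
    """Fraction of bound integrins connected to a fiber class.

    ``f = rho / (rho + epsilon)``: zero at zero density, 0.5 at
    ``rho = epsilon``, monotone, approaching 1 as the density grows.
    """
    rho = np.asarray(bound_density, dtype=float)
    if np.any(rho < 0):
        raise ValueError("bound density must be nonnegative")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    return rho / (rho + epsilon)


def step_bound_integrins(
    state: IntegrinState,
    force_magnitude: np.ndarray,
    params: ModelParams,
    dt: Optional[float] = None,
) -> IntegrinState:
    """One explicit Euler step of the bound-integrin pools.

    Premyofibril-bound integrin gains from basal plus force-promoted
    recruitment of free integrin, loses by density-proportional unbinding
    and by force-promoted maturation into the nascent pool, and regains
    mass from nascent back-conversion.  The net mass drawn from (or
    returned to) the free pool is ledgered into ``rho_f`` so a subsequent
    redistribution conserves the total exactly.

    Raises if ``dt`` violates the positivity bound (per-step outflow
    fraction must stay below 1 for every pool).
    """
    if dt is None:
        dt = params.dt
    fmag = np.asarray(force_magnitude, dtype=float)
    if fmag.shape != state.rho_p.shape:
        raise ValueError("force field shape does not match state")

    out_f = params.binding_rate + params.force_binding_rate * fmag
    out_p = params.unbinding_rate + params.maturation_rate * fmag
    out_n = params.reversion_rate
    worst = max(out_f.max(initial=0.0), out_p.max(initial=0.0), out_n)
    if dt * worst >= 1.0:
        raise ValueError(
            f"dt={dt} violates the positivity bound (dt * max outflow rate = "
            f"{dt * worst:.3f} >= 1); use a smaller time step"
        )

    bind = out_f * state.rho_f
    unbind = params.unbinding_rate * state.rho_p
    mature = params.maturation_rate * fmag * state.rho_p
    revert = params.reversion_rate * state.rho_n

    rho_p = state.rho_p + dt * (bind - unbind - mature + revert)
    rho_n = state.rho_n + dt * (mature - revert)
    rho_f = state.rho_f + dt * (unbind - bind)
    # positivity is guaranteed analytically by the bound above; clip only
    # floating-point dust
    rho_f = np.maximum(rho_f, 0.0)
    return IntegrinState(rho_f, rho_p, rho_n, state.time + dt)


def redistribute_free_integrin(
    state: IntegrinState,
    chi: np.ndarray,
    params: ModelParams,
    delta_area: float,
) -> IntegrinState:
    """Replace ``rho_f`` by its instantaneous-diffusion profile.

    The free pool (total integrin minus bound integrin) is distributed as
    ``exp(-sigma * chi)`` over the island, the drift-diffusion equilibrium
    in the biasing potential; uniform when the alignment feature is off,
    ``sigma = 0`` or ``chi`` is constant.  Total integrin is unchanged to
    machine precision by construction.
    """
    chi = np.asarray(chi, dtype=float)
    if not np.all(np.isfinite(chi)):
        raise ValueError("chi must be finite on the island")
    n = state.rho_p.size
    area = n * delta_area
    free_total = params.phi0 * area - delta_area * float((state.rho_p + state.rho_n).sum())
    if free_total < -1e-9 * params.phi0 * area:
        raise RuntimeError(
            "bound integrin exceeds the total pool; the step size is too "
            "large for the current binding rates"
        )
    free_total = max(free_total, 0.0)
    if params.alignment and params.sigma > 0:
        w = np.exp(-params.sigma * (chi - chi.min()))
    else:
        w = np.ones(n)
    rho_f = free_total * w / (delta_area * w.sum())
    return IntegrinState(rho_f, state.rho_p, state.rho_n, state.time)


def total_integrin(state: IntegrinState, delta_area: float) -> float:
    """delta-A-weighted total of all three integrin fields."""
    return float(delta_area * (state.rho_f + state.rho_p + state.rho_n).sum())
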