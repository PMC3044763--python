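"""Force field on bound integrins, mutual-alignment potential, traction.

The contractile network connects every pair of visible lattice points.  The
tension carried between r and r' is the product of the Langmuir-attenuated
fiber connections at the two endpoints — premyofibril product plus G times
the nascent product — optionally scaled by the pair distance (the fiber
length-force hypothesis, toggle L).  The net force on the bound integrins
at r is the vector sum of all pair tensions, pointing toward each partner;
pairwise action-reaction makes the island-wide force balance exact.

The mutual-alignment biasing potential chi is an attraction well carved
along every nascent fiber: each visible pair contributes a Gaussian trench
of depth proportional to its nascent connection weight, line-integrated
along the segment, with support area inversely proportional to zeta.  Free
integrin redistributed in this potential accumulates alongside existing
nascent bundles, which is how adjacent myofibrils recruit each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .domains import DomainLattice, SegmentRaster, segment_raster
from .kinetics import IntegrinState, ModelParams, langmuir_fraction

__all__ = ["ForceField", "PotentialField", "TractionField", "net_force", "biasing_potential", "traction"]


@dataclass
class ForceField:
    """Net force vector on the bound integrins at each lattice point (au)."""

    F: np.ndarray  # (N, 2)

    @property
    def magnitude(self) -> np.ndarray:
        return np.sqrt((self.F**2).sum(-1))


@dataclass
class PotentialField:
    """Mutual-alignment biasing potential; <= 0, zero far from nascent fibers."""

    chi: np.ndarray


@dataclass
class TractionField:
    """Nominal stress exerted on the substrate (reaction to the fiber pull)."""

    T: np.ndarray  # (N, 2)

    @property
    def magnitude(self) -> np.ndarray:
        return np.sqrt((self.T**2).sum(-1))


def _force_kernels(domain: DomainLattice, length_dependent: bool) -> tuple[np.ndarray, np.ndarray]:
    """(N, N) matrices K_x, K_y with K[i, j] = vis * |r-r'|^L * n_hat(i->j)."""
    cache = getattr(domain, "_force_kernels", None)
    key = bool(length_dependent)
    if cache is not None and key in cache:
        return cache[key]
    unit = domain.pair_direction()
    vis = domain.visible().astype(float)
    if length_dependent:
        vis = vis * domain.pair_distance()
    kx = vis * unit[:, :, 0]
    ky = vis * unit[:, :, 1]
    if cache is None:
        cache = {}
        domain._force_kernels = cache  # type: ignore[attr-defined]
    cache[key] = (kx, ky)
    return kx, ky


def _chi_kernel(domain: DomainLattice, zeta: float) -> np.ndarray:
    """Normalized Gaussian well (zeta/pi) exp(-zeta d^2) between point pairs."""
    cache = getattr(domain, "_chi_kernels", None)
    if cache is not None and zeta in cache:
        return cache[zeta]
    k = (zeta / np.pi) * np.exp(-zeta * domain.pair_distance() ** 2)
    if cache is None:
        cache = {}
        domain._chi_kernels = cache  # type: ignore[attr-defined]
    cache[zeta] = k
    return k


def net_force(
    state: IntegrinState, domain: DomainLattice, params: ModelParams
) -> ForceField:
    """Vector sum of all pair tensions acting on each point.

    F(r) = dA * sum_{r' in Lambda(r)} [f_p(r) f_p(r') + G f_n(r) f_n(r')]
           * |r - r'|^L * n_hat(r -> r')
    """
    if state.rho_p.shape[0] != domain.n_points:
        raise ValueError("state and domain have mismatched sizes")
    fp = langmuir_fraction(state.rho_p, params.epsilon)
    fn = langmuir_fraction(state.rho_n, params.epsilon)
    kx, ky = _force_kernels(domain, params.length_dependent)
    g = params.nascent_force_ratio
    da = domain.delta_area
    fx = da * (fp * (kx @ fp) + g * fn * (kx @ fn))
    fy = da * (fp * (ky @ fp) + g * fn * (ky @ fn))
    return ForceField(np.stack([fx, fy], axis=1))


def biasing_potential(
    state: IntegrinState,
    domain: DomainLattice,
    params: ModelParams,
    raster: SegmentRaster | None = None,
) -> PotentialField:
    """Attraction wells along nascent fibers.

    Implemented by rasterizing the nascent fiber-length mass onto the
    lattice (step dl = spacing/2 along each fiber) and convolving with the
    normalized Gaussian kernel of inverse area zeta.  Identically zero when
    the alignment toggle is off or no nascent myofibrils exist.
    """
    n = domain.n_points
    if not params.alignment:
        return PotentialField(np.zeros(n))
    if raster is None:
        raster = segment_raster(domain)
    fn = langmuir_fraction(state.rho_n, params.epsilon)
    w = fn[raster.pair_i] * fn[raster.pair_j] * domain.delta_area**2
    if not np.any(w > 0):
        return PotentialField(np.zeros(n))
    mass = raster.cell_lengths(w, n)
    chi = -(_chi_kernel(domain, params.zeta) @ mass)
    return PotentialField(chi)


def traction(state: IntegrinState, force: ForceField) -> TractionField:
    """Substrate traction: equal and opposite to the net pull on the
    adhesions, hence zero wherever no integrin is bound."""
    if force.F.shape[0] != state.rho_p.shape[0]:
        raise ValueError("force and state have mismatched sizes")
    return TractionField(-force.F)
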