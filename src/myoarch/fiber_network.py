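"""Directional fiber fields, density, director, order parameter, coupling.

Every visible pair of lattice points carries a notional fiber whose weight
is the product of the Langmuir-attenuated bound-integrin connections at its
endpoints.  Rasterizing those segments gives, per lattice cell and per
angular bin on [0, pi), the total fiber length passing through the cell in
that direction (fibers are unoriented rods, so directions are folded modulo
pi).  From that field come the architecture read-outs:

* fiber density p(r): share of the cell-wide fiber length near r;
* director theta(r): dominant local rod orientation;
* orientational order parameter s(r) in [0, 1]: 0 isotropic, 1 aligned,
  computed from the first nontrivial Fourier mode of the local direction
  distribution on the rod period pi;
* parallel coupling psi(r): normalized nascent density times nascent order
  — the lateral-bundling metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .domains import DomainLattice, SegmentRaster, segment_raster
from .kinetics import IntegrinState, langmuir_fraction

__all__ = [
    "FiberField",
    "OrientationSummary",
    "fiber_length_field",
    "fiber_density",
    "orientation_summary",
    "global_orientation",
    "parallel_coupling",
]


@dataclass
class FiberField:
    """Directional fiber-length fields per class, ``(n_cells, K)`` each."""

    L_p: np.ndarray
    L_n: np.ndarray
    bin_angles: np.ndarray  # bin-center angles in [0, pi)

    @property
    def L_tot(self) -> np.ndarray:
        return self.L_p + self.L_n

    def s_cell(self, which: str = "tot") -> float:
        """Total fiber length in the cell for one class."""
        return float(self._class(which).sum())

    def _class(self, which: str) -> np.ndarray:
        try:
            return {"p": self.L_p, "n": self.L_n, "tot": self.L_tot}[which]
        except KeyError:
            raise ValueError(f"unknown fiber class {which!r}") from None


@dataclass
class OrientationSummary:
    """Per-point orientation read-outs for one fiber class.

    ``director`` is in [0, pi) and NaN where no fiber length exists
    (``defined`` False there, ``oop`` 0 by convention).
    """

    density: np.ndarray
    director: np.ndarray
    oop: np.ndarray
    defined: np.ndarray
    empty: bool = False  # whole-cell zero-fiber flag


def fiber_length_field(
    state: IntegrinState,
    domain: DomainLattice,
    k: int = 36,
    epsilon: float | None = None,
    raster: SegmentRaster | None = None,
) -> FiberField:
    """Directional fiber-length field from the current integrin state.

    Each visible pair contributes its rasterized length, weighted by the
    product of Langmuir-attenuated bound densities at its endpoints, to the
    angular bin of its direction.
    """
    if k < 2:
        raise ValueError("need at least 2 angular bins")
    if epsilon is None:
        epsilon = 0.3
    if raster is None:
        raster = segment_raster(domain)
    n = domain.n_points
    da2 = domain.delta_area**2
    out = []
    for rho in (state.rho_p, state.rho_n):
        f = langmuir_fraction(rho, epsilon)
        w = f[raster.pair_i] * f[raster.pair_j] * da2
        out.append(raster.binned_lengths(w, n, k))
    angles = (np.arange(k) + 0.5) * np.pi / k
    return FiberField(L_p=out[0], L_n=out[1], bin_angles=angles)


def fiber_density(field: FiberField, which: str = "tot") -> tuple[np.ndarray, bool]:
    """Normalized fiber density p(r); sums to 1 over the island.

    Returns ``(p, empty)``; ``empty`` flags an all-zero field (p is then
    zero everywhere rather than raising).
    """
    lengths = field._class(which).sum(axis=1)
    s = lengths.sum()
    if s <= 0:
        return np.zeros_like(lengths), True
    return lengths / s, False


def orientation_summary(field: FiberField, which: str = "tot") -> OrientationSummary:
    """Director and orientational order parameter per lattice point.

    The local direction distribution p(theta; r) is expanded in its Fourier
    series on the rod period pi; the director is the frame angle that
    leaves only the cosine mode, and the OOP is that mode's amplitude,
    normalized so 0 is isotropic and 1 fully aligned.
    """
    L = field._class(which)
    density, empty = fiber_density(field, which)
    local = L.sum(axis=1)
    defined = local > 0
    c2 = np.cos(2 * field.bin_angles)
    s2 = np.sin(2 * field.bin_angles)
    a = np.zeros(L.shape[0])
    b = np.zeros(L.shape[0])
    a[defined] = (L[defined] * c2).sum(axis=1) / local[defined]
    b[defined] = (L[defined] * s2).sum(axis=1) / local[defined]
    oop = np.sqrt(a**2 + b**2)
    director = np.full(L.shape[0], np.nan)
    director[defined] = np.mod(0.5 * np.arctan2(b[defined], a[defined]), np.pi)
    oop[~defined] = 0.0
    return OrientationSummary(
        density=density, director=director, oop=oop, defined=defined, empty=empty
    )


def global_orientation(field: FiberField, which: str = "n") -> tuple[float, float]:
    """Cell-wide (director, OOP) of one fiber class from the pooled
    direction distribution."""
    L = field._class(which).sum(axis=0)
    s = L.sum()
    if s <= 0:
        return float("nan"), 0.0
    a = float((L * np.cos(2 * field.bin_angles)).sum() / s)
    b = float((L * np.sin(2 * field.bin_angles)).sum() / s)
    return float(np.mod(0.5 * np.arctan2(b, a), np.pi)), float(np.hypot(a, b))


def parallel_coupling(summary_n: OrientationSummary) -> tuple[np.ndarray, float]:
    """Degree of parallel coupling psi and its island average.

    psi(r) = (nascent density normalized to its cell-wide maximum at this
    frame) * nascent OOP; 0 for no local coupling, 1 for maximal coupling.
    """
    dmax = summary_n.density.max(initial=0.0)
    if dmax <= 0:
        psi = np.zeros_like(summary_n.density)
        return psi, 0.0
    psi = (summary_n.density / dmax) * summary_n.oop
    return psi, float(psi.mean())
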