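"""Reduction of sigma-potentials to spot descriptors and affinity indices.

The 61-point mu(sigma) curve is reduced to six "spot" descriptors: the
arithmetic means of mu over six 0.01-wide sigma windows.  Window
membership is closed-left / half-open-right, with the final window closed
on the right so every grid point belongs to exactly one window:

    spot1: [-0.03, -0.02)    spot4: [ 0.00,  0.01)
    spot2: [-0.02, -0.01)    spot5: [ 0.01,  0.02)
    spot3: [-0.01,  0.00)    spot6: [ 0.02,  0.03]

Grouped descriptors sum adjacent spots:  HBA = spot1 + spot2 (affinity of
the ensemble for hydrogen-bond donors, negative-sigma side), HYD = spot3 +
spot4 (hydrophobic/nonpolar midsection), HBD = spot5 + spot6 (affinity for
hydrogen-bond acceptors, positive-sigma side).

Solute-solvent affinity indices combine the grouped descriptors of the two
ensembles:  DA = HBD_solute - HBA_solvent, AD = HBA_solute - HBD_solvent,
HH = HYD_solute - HYD_solvent, and the affinity-complementarity index
AC = AD + DA + HH.  A small AC signals complementary mu(sigma) curves.

The TA ("trend area") index is the integral over sigma of the gap between
the solvent curve and the solute curve drawn in reversed form (mirrored
sigma -> -sigma and sign-flipped), so that complementary donor/acceptor
regions face each other; a larger TA means a wider separation of curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import N_GRID, SIGMA_GRID
from .potential import SigmaPotential

__all__ = [
    "SPOT_INTERVALS",
    "DescriptorVector",
    "AffinityIndices",
    "spot_descriptors",
    "affinity_indices",
    "ta_index",
    "spot_slices",
]

#: Window edges (closed-left/half-open-right; last window closed), e/A^2.
SPOT_INTERVALS: tuple[tuple[float, float], ...] = (
    (-0.03, -0.02),
    (-0.02, -0.01),
    (-0.01, 0.00),
    (0.00, 0.01),
    (0.01, 0.02),
    (0.02, 0.03),
)


def spot_slices(grid: np.ndarray = SIGMA_GRID) -> list[np.ndarray]:
    """Boolean masks assigning each grid point to exactly one spot window."""
    masks = []
    for i, (lo, hi) in enumerate(SPOT_INTERVALS):
        last = i == len(SPOT_INTERVALS) - 1
        # tiny tolerance guards against float rounding of the grid values
        if last:
            m = (grid >= lo - 1e-12) & (grid <= hi + 1e-12)
        else:
            m = (grid >= lo - 1e-12) & (grid < hi - 1e-12)
        masks.append(m)
    return masks


@dataclass(frozen=True)
class DescriptorVector:
    """Six spot descriptors plus grouped sums, kcal/mol."""

    spots: tuple[float, float, float, float, float, float]
    T: float
    ensemble_name: str = ""

    @property
    def spot1(self) -> float: return self.spots[0]
    @property
    def spot2(self) -> float: return self.spots[1]
    @property
    def spot3(self) -> float: return self.spots[2]
    @property
    def spot4(self) -> float: return self.spots[3]
    @property
    def spot5(self) -> float: return self.spots[4]
    @property
    def spot6(self) -> float: return self.spots[5]

    @property
    def HBA(self) -> float:
        return self.spots[0] + self.spots[1]

    @property
    def HYD(self) -> float:
        return self.spots[2] + self.spots[3]

    @property
    def HBD(self) -> float:
        return self.spots[4] + self.spots[5]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.spots, dtype=float)

    def as_dict(self) -> dict[str, float]:
        d = {f"spot{i+1}": v for i, v in enumerate(self.spots)}
        d.update(HBA=self.HBA, HYD=self.HYD, HBD=self.HBD)
        return d


@dataclass(frozen=True)
class AffinityIndices:
    """Solute-solvent affinity indices, kcal/mol.  AC = AD + DA + HH."""

    DA: float
    AD: float
    HH: float

    @property
    def AC(self) -> float:
        return self.AD + self.DA + self.HH


def spot_descriptors(potential: SigmaPotential) -> DescriptorVector:
    """Average mu(sigma) within each of the six spot windows."""
    if potential.grid.shape != (N_GRID,) or not np.allclose(potential.grid, SIGMA_GRID):
        raise ValueError("spot descriptors are defined on the canonical 61-point grid")
    spots = tuple(float(potential.mu[m].mean()) for m in spot_slices(potential.grid))
    return DescriptorVector(spots=spots, T=potential.T, ensemble_name=potential.ensemble_name)


def affinity_indices(solute: DescriptorVector, solvent: DescriptorVector) -> AffinityIndices:
    """DA/AD/HH indices of a solute against a solvent ensemble."""
    if abs(solute.T - solvent.T) > 1e-9:
        raise ValueError(
            f"temperature mismatch: solute at {solute.T} K, solvent at {solvent.T} K"
        )
    return AffinityIndices(
        DA=solute.HBD - solvent.HBA,
        AD=solute.HBA - solvent.HBD,
        HH=solute.HYD - solvent.HYD,
    )


def ta_index(solute: SigmaPotential, solvent: SigmaPotential) -> float:
    """Trend-area index: integral gap between solvent and reversed solute curves.

    The solute curve is mirrored (sigma -> -sigma) and sign-reversed, then
    the signed area between it and the solvent curve is integrated over the
    grid with the trapezoid rule.  Units: kcal mol^-1 (e/A^2).
    """
    if solute.grid.shape != solvent.grid.shape or not np.allclose(solute.grid, solvent.grid):
        raise ValueError("solute and solvent potentials must share one grid")
    if abs(solute.T - solvent.T) > 1e-9:
        raise ValueError("solute and solvent potentials must share one temperature")
    # the grid is symmetric about 0, so mirroring is an index reversal
    reversed_solute = -solute.mu[::-1]
    integrand = reversed_solute - solvent.mu
    return float(np.trapezoid(integrand, solute.grid))
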