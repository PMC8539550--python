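"""Reading, resampling, mixing and synthesis of sigma-profiles.

A sigma-profile is the area-weighted histogram of a molecule's (or liquid
ensemble's) COSMO screening-charge density sigma.  All profiles in this
package live on one canonical grid of 61 points spanning sigma in
[-0.03, +0.03] e/A^2 with a step of 0.001 e/A^2; every file read in is
resampled onto that grid by area-conserving (cumulative) interpolation.

The per-point values ``p_k`` carry units of A^2 per grid bin, so that
``sum(p) == total_area`` of the molecular surface.  The normalized form
``P_k = p_k / sum(p)`` is the probability distribution used by the
sigma-potential solver.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np

# Canonical charge-density grid: sigma_k = -0.03 + 0.001*k, k = 0..60 (e/A^2)
N_GRID: int = 61
SIGMA_STEP: float = 0.001
SIGMA_GRID: np.ndarray = np.linspace(-0.03, 0.03, N_GRID)
SIGMA_GRID.setflags(write=False)

__all__ = [
    "N_GRID",
    "SIGMA_GRID",
    "SIGMA_STEP",
    "SigmaProfile",
    "MixtureSpec",
    "ProfileParseError",
    "ProfileValidationError",
    "read_sigma_profile",
    "write_sigma_profile",
    "mix_profiles",
    "generate_synthetic_profile",
    "demo_library",
    "demo_solute_profile",
]


class ProfileParseError(ValueError):
    """Raised when a sigma-profile file cannot be parsed."""


class ProfileValidationError(ValueError):
    """Raised when profile data violate a structural invariant."""


@dataclass(frozen=True)
class SigmaProfile:
    """Area-weighted charge-density distribution on the canonical grid.

    Attributes
    ----------
    name : str
        Compound or mixture label.
    p : ndarray, shape (61,)
        Surface area per grid bin, A^2.  Non-negative.
    """

    name: str
    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.shape != (N_GRID,):
            raise ProfileValidationError(
                f"profile {self.name!r}: expected {N_GRID} grid values, got {p.shape}"
            )
        if np.any(p < 0):
            raise ProfileValidationError(f"profile {self.name!r}: negative p(sigma) values")
        p = p.copy()
        p.setflags(write=False)
        object.__setattr__(self, "p", p)

    @property
    def grid(self) -> np.ndarray:
        return SIGMA_GRID

    @property
    def total_area(self) -> float:
        """Total molecular surface area, A^2 (sum over bins)."""
        return float(self.p.sum())

    @property
    def is_degenerate(self) -> bool:
        """True for an all-zero profile (no surface area)."""
        return self.total_area == 0.0

    def normalized(self) -> np.ndarray:
        """Probability form P_k = p_k / sum(p); sums to exactly 1."""
        if self.is_degenerate:
            raise ProfileValidationError(
                f"profile {self.name!r} is degenerate (zero total area); cannot normalize"
            )
        return self.p / self.p.sum()


@dataclass(frozen=True)
class MixtureSpec:
    """Components of a liquid mixture with their mole fractions."""

    components: Sequence[tuple[SigmaProfile, float]]

    def __post_init__(self) -> None:
        fractions = np.array([x for _, x in self.components], dtype=float)
        if len(fractions) == 0:
            raise ProfileValidationError("mixture must have at least one component")
        if np.any(fractions < 0):
            raise ProfileValidationError("mole fractions must be non-negative")
        if abs(fractions.sum() - 1.0) > 1e-12:
            raise ProfileValidationError(
                f"mole fractions must sum to 1 (got {fractions.sum()!r})"
            )


def _as_lines(source: str | Path | TextIO) -> Iterable[str]:
    if isinstance(source, (str, Path)):
        path = Path(source)
        return path.read_text().splitlines()
    return source.read().splitlines()


def read_sigma_profile(source: str | Path | TextIO, name: str | None = None) -> SigmaProfile:
    """Read a two-column (sigma, p*A) text file and resample to the canonical grid.

    The dialect is two whitespace-separated numeric columns; lines starting
    with ``#`` and blank lines are skipped.  The input grid may have any
    (roughly uniform) spacing; the profile is transferred to the canonical
    61-point grid by interpolating the cumulative area at bin edges, which
    conserves total surface area.

    Parameters
    ----------
    source : path or open text stream
    name : optional profile label; defaults to the file stem or ``"profile"``.
    """
    if name is None:
        name = Path(source).stem if isinstance(source, (str, Path)) else "profile"
    sigmas: list[float] = []
    areas: list[float] = []
    for lineno, raw in enumerate(_as_lines(source), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ProfileParseError(f"line {lineno}: expected two columns, got {line!r}")
        try:
            s, a = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise ProfileParseError(f"line {lineno}: non-numeric value in {line!r}") from exc
        sigmas.append(s)
        areas.append(a)
    if len(sigmas) < 2:
        raise ProfileParseError("profile file must contain at least two data rows")
    sig = np.array(sigmas)
    area = np.array(areas)
    if np.any(np.diff(sig) <= 0):
        raise ProfileParseError("sigma column must be strictly increasing")
    if np.any(area < 0):
        raise ProfileValidationError("negative p(sigma) value in profile file")
    p = _resample_to_grid(sig, area)
    return SigmaProfile(name=name, p=p)


def _resample_to_grid(sig: np.ndarray, area: np.ndarray) -> np.ndarray:
    """Area-conserving transfer of per-bin areas onto the canonical grid.

    Each input point is treated as a bin centred on its sigma value; the
    cumulative area at input bin edges is linearly interpolated onto the
    canonical bin edges and differenced.  Any residual mismatch (mass just
    outside the canonical span) is removed by a final exact rescale.
    """
    total = float(area.sum())
    if total == 0.0:
        return np.zeros(N_GRID)
    # input bin edges: midpoints, extended by half the end spacings
    mid = 0.5 * (sig[:-1] + sig[1:])
    edges_in = np.concatenate(
        ([sig[0] - (sig[1] - sig[0]) / 2], mid, [sig[-1] + (sig[-1] - sig[-2]) / 2])
    )
    cum_in = np.concatenate(([0.0], np.cumsum(area)))
    edges_out = np.linspace(-0.03 - SIGMA_STEP / 2, 0.03 + SIGMA_STEP / 2, N_GRID + 1)
    cum_out = np.interp(edges_out, edges_in, cum_in, left=0.0, right=total)
    p = np.diff(cum_out)
    p = np.clip(p, 0.0, None)
    captured = p.sum()
    if captured == 0.0:
        raise ProfileValidationError("profile has no area inside the canonical sigma range")
    return p * (total / captured)


def write_sigma_profile(profile: SigmaProfile, target: str | Path | TextIO) -> None:
    """Write a profile in the two-column text dialect."""
    buf = io.StringIO()
    buf.write(f"# sigma-profile: {profile.name}\n")
    buf.write("# sigma [e/A^2]    p(sigma)*A [A^2]\n")
    for s, a in zip(SIGMA_GRID, profile.p):
        buf.write(f"{s: .6f}  {a:.10e}\n")
    text = buf.getvalue()
    if isinstance(target, (str, Path)):
        Path(target).write_text(text)
    else:
        target.write(text)


def mix_profiles(spec: MixtureSpec, name: str | None = None) -> SigmaProfile:
    """Mole-fraction-weighted mixture profile.

    p_mix,k = sum_i x_i * p_i,k, so the mixture's total area is the
    mole-fraction average of component areas.  Weighting is linear in the
    area densities; normalization to the probability form happens downstream.
    """
    p_mix = np.zeros(N_GRID)
    labels = []
    for prof, x in spec.components:
        p_mix += x * prof.p
        labels.append(f"{prof.name}:{x:g}")
    return SigmaProfile(name=name or "+".join(labels), p=p_mix)


def generate_synthetic_profile(
    peaks: Sequence[tuple[float, float, float]],
    seed: int | None = None,
    name: str = "synthetic",
) -> SigmaProfile:
    """Build a profile as a sum of Gaussians on the canonical grid.

    Parameters
    ----------
    peaks : sequence of (center, width, area)
        Gaussian center (e/A^2, within +/-0.03), standard deviation
        (e/A^2, > 0) and surface area carried by the peak (A^2).
    seed : optional int
        When given, applies a small reproducible log-normal jitter
        (sd 2 percent) to the bin values before the final renormalization,
        emulating conformer-to-conformer variability.

    The result is renormalized so that ``total_area`` equals the sum of the
    requested peak areas exactly.
    """
    if not peaks:
        raise ProfileValidationError("at least one peak is required")
    target_area = 0.0
    p = np.zeros(N_GRID)
    for center, width, area in peaks:
        if width <= 0:
            raise ProfileValidationError(f"peak width must be > 0 (got {width})")
        if not -0.03 <= center <= 0.03:
            raise ProfileValidationError(f"peak center {center} outside +/-0.03 e/A^2")
        if area < 0:
            raise ProfileValidationError(f"peak area must be >= 0 (got {area})")
        shape = np.exp(-0.5 * ((SIGMA_GRID - center) / width) ** 2)
        if shape.sum() > 0:
            p += area * shape / shape.sum()
        target_area += area
    if seed is not None:
        rng = np.random.default_rng(seed)
        p = p * np.exp(rng.normal(0.0, 0.02, size=N_GRID))
    if target_area > 0 and p.sum() > 0:
        p *= target_area / p.sum()
    return SigmaProfile(name=name, p=p)


# ---------------------------------------------------------------------------
# Demonstration library of synthetic solvent (and solute) profiles.
#
# These are SYNTHETIC stand-ins shaped after the qualitative features of the
# real compounds (bimodal donor/acceptor peaks for water, a strong acceptor
# lobe and apolar bulk for the dipolar aprotics, a broad apolar hump for the
# ether), with plausible COSMO cavity areas.  They let the full pipeline run
# without any quantum-chemistry input; they are not DFT-derived surfaces.
# Convention: hydrogen-bond donor surface screens at negative sigma, acceptor
# (lone-pair) surface at positive sigma.
# ---------------------------------------------------------------------------

_DEMO_PEAKS: dict[str, list[tuple[float, float, float]]] = {
    "water": [(-0.0155, 0.0035, 16.0), (0.0005, 0.004, 10.0), (0.0150, 0.0035, 17.0)],
    "methanol": [(-0.0135, 0.0035, 12.0), (-0.002, 0.005, 38.0), (0.0140, 0.0035, 15.0)],
    "DMSO": [(-0.004, 0.005, 60.0), (0.0185, 0.0035, 26.0), (0.006, 0.004, 12.0)],
    "DMF": [(-0.005, 0.005, 72.0), (0.0170, 0.0040, 26.0), (0.004, 0.004, 14.0)],
    "1,4-dioxane": [(-0.004, 0.0045, 84.0), (0.0125, 0.0040, 26.0)],
    "acetonitrile": [(-0.006, 0.0045, 42.0), (0.0150, 0.0035, 18.0), (0.002, 0.004, 10.0)],
}

_DEMO_SOLUTE_PEAKS: list[tuple[float, float, float]] = [
    # sulfonamide-like solute: sizeable apolar surface, a donor N-H lobe and
    # several acceptor centers (SO2, ring N) of moderate polarity
    (-0.0170, 0.0030, 22.0),
    (-0.004, 0.006, 150.0),
    (0.0065, 0.005, 60.0),
    (0.0140, 0.0035, 38.0),
]


def demo_library() -> dict[str, SigmaProfile]:
    """Synthetic demonstration solvent library keyed by solvent name."""
    return {
        name: generate_synthetic_profile(peaks, name=name)
        for name, peaks in _DEMO_PEAKS.items()
    }


def demo_solute_profile() -> SigmaProfile:
    """Synthetic sulfonamide-like solute profile for demos and tests."""
    return generate_synthetic_profile(_DEMO_SOLUTE_PEAKS, name="solute")
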