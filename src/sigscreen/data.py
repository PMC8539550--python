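"""Solubility dataset, unit arithmetic and the synthetic-dataset generator.

The packaged fixture ``data/table2.csv`` holds the measured mole-fraction
solubility of sulfamethizole in water and five aqueous organic binary
mixtures (1,4-dioxane, methanol, DMF, DMSO, acetonitrile) at 298.15,
303.15, 308.15 and 313.15 K: 104 records.  Values are stored exactly as
printed (mantissa strings plus a per-block power-of-ten scale); the loader
applies the scale.  ``x2_star`` is the mole fraction of the organic
cosolvent in the solute-free binary solvent; the ``x2_star = 0`` rows are
neat water.

The solubility advantage of a solvent system over water at the same
temperature is ``SA = log10(x_system / x_water)``.

The synthetic dataset generator drives the whole model chain on data with
a known ground truth: it samples binary systems of random synthetic
solvents, computes their spot descriptors through the actual
profile -> potential -> descriptor pipeline, and assigns
``log10 x = f(descriptors) + N(0, noise_sd)`` for a fixed smooth nonlinear
``f`` that is recorded on the returned object, so model-recovery tests can
compare against the exact target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .profiles import MixtureSpec, SigmaProfile, generate_synthetic_profile, mix_profiles
from .potential import KernelParams, solve_sigma_potential
from .descriptors import spot_descriptors

__all__ = [
    "SOLUTE_NAME",
    "SolubilityRecord",
    "load_inpaper_dataset",
    "table2_frame",
    "get_solubility",
    "solubility_advantage",
    "SyntheticDataset",
    "generate_synthetic_dataset",
]

SOLUTE_NAME = "sulfamethizole"
DESCRIPTOR_COLUMNS = ["spot1", "spot2", "spot3", "spot4", "spot5", "spot6"]


@dataclass(frozen=True)
class SolubilityRecord:
    """One equilibrium solubility measurement."""

    solute: str
    solvent_a: str          # organic cosolvent
    solvent_b: str | None   # water (or None for a non-aqueous system)
    x2_star: float          # mole fraction of organic in solute-free solvent
    T: float                # K
    x: float                # mole-fraction solubility
    x_sd: float
    source: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.x < 1.0:
            raise ValueError(f"mole-fraction solubility must be in (0, 1); got {self.x}")
        if not 0.0 <= self.x2_star <= 1.0:
            raise ValueError(f"x2_star must be in [0, 1]; got {self.x2_star}")
        if self.T <= 0:
            raise ValueError("temperature must be > 0 K")


def _fixture_path():
    return resources.files("sigscreen").joinpath("data/table2.csv")


def table2_frame() -> pd.DataFrame:
    """The packaged solubility table with printed strings preserved.

    Columns: solvent, scale, x2_star, T, x_printed, x_sd_printed (all str
    except the derived float column ``x``).
    """
    with resources.as_file(_fixture_path()) as path:
        df = pd.read_csv(path, dtype=str)
    df["x"] = df["x_printed"].astype(float) * df["scale"].astype(float)
    df["x_sd"] = df["x_sd_printed"].astype(float) * df["scale"].astype(float)
    df["x2_star_f"] = df["x2_star"].astype(float)
    df["T_f"] = df["T"].astype(float)
    return df


def load_inpaper_dataset() -> list[SolubilityRecord]:
    """All 104 packaged measurements as records."""
    df = table2_frame()
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SolubilityRecord(
                solute=SOLUTE_NAME,
                solvent_a=row.solvent,
                solvent_b="water",
                x2_star=row.x2_star_f,
                T=row.T_f,
                x=row.x,
                x_sd=row.x_sd,
                source="shake-flask, packaged table",
            )
        )
    return records


def get_solubility(solvent: str, x2_star: float, T: float) -> float:
    """Mole-fraction solubility for one (solvent block, composition, T).

    Neat water is the ``x2_star = 0`` entry (stored under the
    1,4-dioxane block); pass ``solvent="water"`` as a convenience alias.
    """
    df = table2_frame()
    if solvent == "water":
        solvent, x2_star = "1,4-dioxane", 0.0
    hit = df[
        (df["solvent"] == solvent)
        & (np.isclose(df["x2_star_f"], x2_star))
        & (np.isclose(df["T_f"], T))
    ]
    if len(hit) != 1:
        raise KeyError(f"no unique record for ({solvent!r}, x2*={x2_star}, T={T})")
    return float(hit["x"].iloc[0])


def solubility_advantage(x_system: float, x_water: float) -> float:
    """SA = log10(x_system / x_water).

    The decimal log of the solubility ratio against water at the same
    temperature; 0 for water itself, ~3.8 for the strongest enhancer in
    the packaged dataset.
    """
    if x_system <= 0 or x_water <= 0:
        raise ValueError("mole-fraction solubilities must be > 0")
    return float(np.log10(x_system / x_water))


# ---------------------------------------------------------------------------
# Synthetic dataset with a recorded ground-truth descriptor -> log10 x map
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    """Descriptor table plus targets drawn from a recorded smooth function."""

    X: pd.DataFrame            # columns spot1..spot6
    y: np.ndarray              # log10 mole-fraction solubility, with noise
    y_true: np.ndarray         # noiseless targets
    truth: Callable[[pd.DataFrame], np.ndarray]
    noise_sd: float
    seed: int
    systems: pd.DataFrame = field(default_factory=pd.DataFrame)
    solvent_profiles: dict[str, SigmaProfile] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.y)


def _truth_function(
    center: np.ndarray, scale: np.ndarray, active: Sequence[int]
) -> Callable[[pd.DataFrame], np.ndarray]:
    """Fixed smooth map from standardized descriptors to log10 x in ~[-5, -1].

    Shape: a saturating base level plus bounded tanh interactions, so the
    surface is smooth, nonlinear and learnable by a small network.  Only the
    descriptors listed in ``active`` enter (all six by default), which lets
    sensitivity tests plant a signal in a single column.
    """
    active = list(active)

    def f(X: pd.DataFrame) -> np.ndarray:
        Z = (X[DESCRIPTOR_COLUMNS].to_numpy(dtype=float) - center) / scale
        z = np.zeros((len(Z), 6))
        z[:, active] = Z[:, active]
        y = (
            -3.0
            + 1.1 * np.tanh(0.9 * z[:, 4] - 0.5 * z[:, 1])
            + 0.6 * np.tanh(0.7 * z[:, 0] + 0.4 * z[:, 2])
            - 0.5 * np.tanh(0.6 * z[:, 3] - 0.3 * z[:, 5])
            + 0.3 * np.tanh(0.5 * z[:, 4] * z[:, 3])
        )
        return y

    return f


def generate_synthetic_dataset(
    n_systems: int,
    noise_sd: float,
    seed: int,
    active_descriptors: Sequence[int] = (0, 1, 2, 3, 4, 5),
    n_base_solvents: int = 10,
    params: KernelParams = KernelParams(),
) -> SyntheticDataset:
    """Descriptor table and noisy log-solubility targets with known truth.

    Systems are random binary mixtures of ``n_base_solvents`` randomly
    shaped synthetic solvents at compositions {0, 0.2, ..., 1.0} and
    temperatures uniform in [288.15, 318.15] K; each system's descriptors
    come from an actual sigma-potential solve, so their ranges and mutual
    correlations mimic what the reduction produces on real profiles.
    """
    if n_systems < 20:
        raise ValueError("n_systems must be >= 20")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)

    solvents: list[SigmaProfile] = []
    for i in range(n_base_solvents):
        n_peaks = int(rng.integers(1, 4))
        peaks = []
        for _ in range(n_peaks):
            center = float(rng.uniform(-0.022, 0.022))
            width = float(rng.uniform(0.002, 0.006))
            area = float(rng.uniform(20.0, 120.0))
            peaks.append((center, width, area))
        solvents.append(generate_synthetic_profile(peaks, name=f"solvent{i}"))

    compositions = np.array([0.0, 0.2, 0.4, 0.6, 0.8, 1.0])
    rows = []
    meta = []
    for _ in range(n_systems):
        ia, ib = rng.choice(len(solvents), size=2, replace=False)
        x2 = float(rng.choice(compositions))
        T = float(rng.uniform(288.15, 318.15))
        mixture = mix_profiles(
            MixtureSpec([(solvents[ia], x2), (solvents[ib], 1.0 - x2)])
        )
        pot = solve_sigma_potential(mixture, T, params)
        desc = spot_descriptors(pot)
        rows.append(desc.as_array())
        meta.append((solvents[ia].name, solvents[ib].name, x2, T))

    X = pd.DataFrame(np.asarray(rows), columns=DESCRIPTOR_COLUMNS)
    systems = pd.DataFrame(meta, columns=["solvent_a", "solvent_b", "x2_star", "T"])
    center = X.to_numpy().mean(axis=0)
    scale = X.to_numpy().std(axis=0)
    scale[scale == 0] = 1.0
    truth = _truth_function(center, scale, active_descriptors)
    y_true = truth(X)
    y = y_true + rng.normal(0.0, noise_sd, size=len(y_true))
    return SyntheticDataset(
        X=X,
        y=y,
        y_true=y_true,
        truth=truth,
        noise_sd=noise_sd,
        seed=seed,
        systems=systems,
        solvent_profiles={s.name: s for s in solvents},
    )
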