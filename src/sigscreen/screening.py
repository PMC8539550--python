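"""Enumeration, prediction and ranking of candidate solvent systems.

Given a library of solvent sigma-profiles, a whitelist of miscible pairs
and a composition ladder, the screen builds every neat and binary system,
computes its descriptors through the profile -> potential -> descriptor
chain, gates it on the leverage applicability domain, predicts log10
solubility with the network ensemble, attaches the solute-solvent
affinity-complementarity (AC) index, and ranks everything against a
reference solvent.  Out-of-domain systems are kept in the result list for
bookkeeping but never carry a prediction.

The AC-vs-solubility map reproduces the screening scatter: all in-domain
(AC, predicted log10 x) pairs, with a "green zone" subset — high predicted
solubility at near-zero AC — selected by configurable quantile thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .profiles import MixtureSpec, SigmaProfile, mix_profiles
from .potential import KernelParams, solve_sigma_potential
from .descriptors import DescriptorVector, affinity_indices, spot_descriptors
from .domain import ADModel, leverage
from .ensemble import Ensemble, predict

__all__ = [
    "DEFAULT_COMPOSITIONS",
    "SolventSystem",
    "SystemEnumeration",
    "ScreeningResult",
    "enumerate_systems",
    "screen",
    "ac_map",
    "results_frame",
]

DEFAULT_COMPOSITIONS: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass(frozen=True)
class SolventSystem:
    """One neat or binary solvent at a composition and temperature."""

    solvent_a: str
    solvent_b: str | None
    x2_star: float            # mole fraction of solvent_a in the solvent
    T: float
    profile: SigmaProfile

    @property
    def label(self) -> str:
        if self.solvent_b is None:
            return self.solvent_a
        return f"{self.solvent_a}+{self.solvent_b} (x2*={self.x2_star:g})"


@dataclass(frozen=True)
class SystemEnumeration:
    """Deduplicated system list plus both counting conventions."""

    systems: tuple[SolventSystem, ...]
    n_pair_composition: int   # pairs x compositions, endpoints included
    n_unique: int             # after merging shared neat endpoints

    def __iter__(self):
        return iter(self.systems)

    def __len__(self) -> int:
        return len(self.systems)


def enumerate_systems(
    library: dict[str, SigmaProfile],
    miscible_pairs: Sequence[tuple[str, str]],
    compositions: Sequence[float] = DEFAULT_COMPOSITIONS,
    T: float = 298.15,
) -> SystemEnumeration:
    """All neat solvents plus one system per (miscible pair, composition).

    Compositions of 0 or 1 collapse onto the neat endpoint solvents, which
    are deduplicated across pairs; every library solvent also appears as a
    neat system even with an empty whitelist.
    """
    for a, b in miscible_pairs:
        for name in (a, b):
            if name not in library:
                raise KeyError(f"whitelist references unknown solvent {name!r}")
    systems: dict[tuple, SolventSystem] = {}
    for name, prof in library.items():
        systems[("neat", name)] = SolventSystem(name, None, 1.0, T, prof)
    for a, b in miscible_pairs:
        for x2 in compositions:
            if x2 in (0.0, 1.0):
                continue  # endpoints are the neat systems above
            mixture = mix_profiles(
                MixtureSpec([(library[a], x2), (library[b], 1.0 - x2)]),
                name=f"{a}+{b} x2*={x2:g}",
            )
            systems[("pair", a, b, round(x2, 6))] = SolventSystem(a, b, x2, T, mixture)
    return SystemEnumeration(
        systems=tuple(systems.values()),
        n_pair_composition=len(miscible_pairs) * len(compositions),
        n_unique=len(systems),
    )


@dataclass(frozen=True)
class ScreeningResult:
    """Prediction and domain status of one screened system."""

    solvent_a: str
    solvent_b: str | None
    x2_star: float
    T: float
    log10_x_pred: float | None     # None when out of domain
    log10_x_sd: float | None
    AC: float
    h: float
    in_domain: bool
    delta_vs_reference: float | None = None

    @property
    def label(self) -> str:
        if self.solvent_b is None:
            return self.solvent_a
        return f"{self.solvent_a}+{self.solvent_b} (x2*={self.x2_star:g})"


def screen(
    ensemble: Ensemble,
    ad: ADModel,
    systems: SystemEnumeration | Sequence[SolventSystem],
    reference: str,
    solute_profile: SigmaProfile,
    params: KernelParams = KernelParams(),
) -> list[ScreeningResult]:
    """Predict every in-domain system and rank against a reference solvent.

    The reference is named by its neat-solvent label and must itself be in
    the domain.  The AC index pairs the solute's grouped descriptors with
    each solvent system's, both at the system temperature.
    """
    solute_cache: dict[float, DescriptorVector] = {}

    def solute_desc(T: float) -> DescriptorVector:
        if T not in solute_cache:
            solute_cache[T] = spot_descriptors(solve_sigma_potential(solute_profile, T, params))
        return solute_cache[T]

    rows: list[ScreeningResult] = []
    for system in systems:
        pot = solve_sigma_potential(system.profile, system.T, params)
        desc = spot_descriptors(pot)
        ac = affinity_indices(solute_desc(system.T), desc).AC
        h = leverage(ad, desc)
        in_domain = h <= ad.h_star
        if in_domain:
            mean, sd = predict(ensemble, desc)
        else:
            mean, sd = None, None
        rows.append(
            ScreeningResult(
                solvent_a=system.solvent_a,
                solvent_b=system.solvent_b,
                x2_star=system.x2_star,
                T=system.T,
                log10_x_pred=mean,
                log10_x_sd=sd,
                AC=ac,
                h=h,
                in_domain=in_domain,
            )
        )

    ref_hits = [r for r in rows if r.solvent_b is None and r.solvent_a == reference]
    if not ref_hits:
        raise KeyError(f"reference solvent {reference!r} not among the screened systems")
    ref = ref_hits[0]
    if not ref.in_domain:
        raise ValueError(f"reference solvent {reference!r} is outside the applicability domain")
    out = []
    for r in rows:
        delta = None if r.log10_x_pred is None else r.log10_x_pred - ref.log10_x_pred
        out.append(
            ScreeningResult(
                **{**r.__dict__, "delta_vs_reference": delta}
            )
        )
    out.sort(key=lambda r: (-np.inf if r.delta_vs_reference is None else r.delta_vs_reference), reverse=True)
    return out


def results_frame(results: Sequence[ScreeningResult]) -> pd.DataFrame:
    """Screening results as a flat table (one row per system)."""
    return pd.DataFrame(
        {
            "solvent_a": [r.solvent_a for r in results],
            "solvent_b": [r.solvent_b for r in results],
            "x2_star": [r.x2_star for r in results],
            "T": [r.T for r in results],
            "log10_x_pred": [r.log10_x_pred for r in results],
            "log10_x_sd": [r.log10_x_sd for r in results],
            "AC": [r.AC for r in results],
            "h": [r.h for r in results],
            "in_domain": [r.in_domain for r in results],
            "delta_vs_reference": [r.delta_vs_reference for r in results],
        }
    )


def ac_map(
    results: Sequence[ScreeningResult],
    solubility_quantile: float = 0.9,
    ac_band: str = "median",
) -> pd.DataFrame:
    """(AC, predicted log10 x) scatter with a "green zone" label.

    The green zone is the in-domain subset in the top
    ``1 - solubility_quantile`` of predicted solubility whose |AC| lies
    below the in-domain median |AC| (repo convention; both thresholds are
    configurable).  Returns an empty frame when nothing is in domain.
    """
    rows = [r for r in results if r.in_domain and r.log10_x_pred is not None]
    if not rows:
        return pd.DataFrame(columns=["label", "AC", "log10_x_pred", "green_zone"])
    df = pd.DataFrame(
        {
            "label": [r.label for r in rows],
            "AC": [r.AC for r in rows],
            "log10_x_pred": [r.log10_x_pred for r in rows],
        }
    )
    sol_cut = df["log10_x_pred"].quantile(solubility_quantile)
    abs_ac = df["AC"].abs()
    ac_cut = abs_ac.median() if ac_band == "median" else float(ac_band)
    df["green_zone"] = (df["log10_x_pred"] >= sol_cut) & (abs_ac <= ac_cut)
    return df
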