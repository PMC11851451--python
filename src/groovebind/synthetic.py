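"""Seeded synthetic-data generators with ground-truth manifests.

Every generator is a pure function of (parameters, seed): it simulates
the corresponding noise-free curve through the physics modules, adds
i.i.d. Gaussian noise, and returns the dataset together with a
:class:`GroundTruthManifest` recording everything needed to regenerate
it bit-for-bit.  The defaults mirror the published study conditions:

* SPR injections at 2–1000 nM (the fourteen-point concentration series
  used for every compound), with association/dissociation windows long
  enough to reach plateau for the rate regimes studied;
* competition mixtures of two DNAs at 10 uM each sharing 20 uM ligand
  (a 2:1 compound:DNA ratio);
* closed-cell titrations of 5 uM DNA with ten 1 uM ligand increments.

Named presets carry the published equilibrium and rate constants for
each compound/site pair so examples and recovery studies run against
realistic ground truth.  Noise is additive Gaussian only; instrument
artifacts such as drift or spikes are not emulated, so recovery results
here bound what the estimators can do on ideal, not real, data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from .competition import DnaSpeciesSpec, LigandSpec, SpeciesDistribution, species_distribution
from .equilibrium import StepwiseConstants
from .isotherm import SteadyStateIsotherm
from .kinetics import (
    InjectionSchedule,
    OneSiteKinetics,
    Sensorgram,
    TwoSiteKinetics,
    simulate_one_site_sensorgram,
    simulate_two_site_sensorgram,
)
from .titration import TitrationCurve, TitrationDesign, simulate_titration_curve

__all__ = [
    "GroundTruthManifest",
    "DEFAULT_CONCENTRATIONS_M",
    "EQUILIBRIUM_PRESETS",
    "KINETIC_PRESETS",
    "generate_sensorgram_set",
    "generate_isotherm",
    "generate_competition_dataset",
    "generate_titration_dataset",
]

#: Injected concentration series (M): 2–1000 nM, fourteen points.
DEFAULT_CONCENTRATIONS_M = tuple(
    c * 1e-9 for c in (2, 5, 10, 15, 20, 30, 40, 50, 70, 100, 200, 300, 500, 1000)
)

#: Published equilibrium constants per compound/site pair (M^-1).
EQUILIBRIUM_PRESETS: dict[str, StepwiseConstants] = {
    # cooperative stacked dimers at -TTAA-
    "DB1003-TTAA": StepwiseConstants.two_site(2.6e6, 7.5e7),
    "DB1992-TTAA": StepwiseConstants.two_site(1.7e6, 1.3e8),
    # 1:1 monomer binding
    "DB2009-TTAA": StepwiseConstants.one_site(1.6e6),
    "DB1898-TTAA": StepwiseConstants.one_site(6.9e6),
    "DB2009-AATT": StepwiseConstants.one_site(2.4e8),
    "DB1898-AATT": StepwiseConstants.one_site(1.5e8),
    "DB1003-AATT": StepwiseConstants.one_site(0.2e7),
    "DB1871-AATT": StepwiseConstants.one_site(0.7e7),
    "DB1992-AATT": StepwiseConstants.one_site(0.6e7),
    "DB1896-AATT": StepwiseConstants.one_site(0.6e7),
    "DB2868-AATT": StepwiseConstants.one_site(3.0e7),
    "DB1897-AATT": StepwiseConstants.one_site(6.7e7),
    "DB2868-TTAA": StepwiseConstants.one_site(1.0e6),
    "DB1897-TTAA": StepwiseConstants.one_site(2.8e6),
}

#: Published 1:1 rate constants (strong -AATT- binders); Rmax is an
#: arbitrary-but-typical surface capacity since absolute RU scales are
#: instrument specific.
KINETIC_PRESETS: dict[str, OneSiteKinetics] = {
    "DB2009-AATT": OneSiteKinetics(ka=3.4e6, kd=11.9e-3, Rmax=80.0),
    "DB1898-AATT": OneSiteKinetics(ka=1.3e6, kd=5.9e-3, Rmax=80.0),
}


@dataclass(frozen=True)
class GroundTruthManifest:
    """Everything needed to regenerate a synthetic dataset exactly."""

    generator: str
    seed: int
    parameters: dict = field(default_factory=dict)
    files: tuple = ()

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "generator": self.generator,
                "seed": self.seed,
                "parameters": self.parameters,
                "files": list(self.files),
            },
            sort_keys=False,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "GroundTruthManifest":
        d = yaml.safe_load(text)
        return cls(
            generator=d["generator"],
            seed=int(d["seed"]),
            parameters=d.get("parameters", {}),
            files=tuple(d.get("files", ())),
        )


def _kinetics_dict(params) -> dict:
    if isinstance(params, OneSiteKinetics):
        return {"model": "one_site", "ka": params.ka, "kd": params.kd, "Rmax": params.Rmax}
    return {
        "model": "two_site",
        "ka1": params.ka1,
        "ka2": params.ka2,
        "kd1": params.kd1,
        "kd2": params.kd2,
        "Rmax1": params.Rmax1,
    }


def _constants_dict(constants: StepwiseConstants) -> dict:
    d = {"model": constants.model.value}
    if constants.K_A is not None:
        d["K_A"] = constants.K_A
    else:
        d.update(K_A1=constants.K_A1, K_A2=constants.K_A2)
    return d


def default_schedule(C: float, t_assoc: float = 600.0, t_dissoc: float = 600.0) -> InjectionSchedule:
    """Association/dissociation windows sized to reach plateau for the
    rate regimes studied (kd ~ 1e-2 s^-1, K_A ~ 1e6-1e8 M^-1)."""
    return InjectionSchedule(t_start=0.0, t_stop=t_assoc, t_end=t_assoc + t_dissoc, C_inject=C)


def generate_sensorgram_set(
    params: OneSiteKinetics | TwoSiteKinetics,
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS_M,
    noise_sigma: float = 0.0,
    seed: int = 0,
    t_assoc: float = 600.0,
    t_dissoc: float = 600.0,
    points_per_curve: int = 240,
) -> tuple[list[Sensorgram], GroundTruthManifest]:
    """Multi-concentration sensorgram set with Gaussian RU noise."""
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for C in concentrations:
        sched = default_schedule(C, t_assoc, t_dissoc)
        grid = np.linspace(sched.t_start, sched.t_end, points_per_curve)
        if isinstance(params, OneSiteKinetics):
            sg = simulate_one_site_sensorgram(params, sched, grid, label=f"{C:.3g} M")
        else:
            sg = simulate_two_site_sensorgram(params, sched, grid, label=f"{C:.3g} M")
        if noise_sigma > 0:
            sg = Sensorgram(
                sg.time,
                sg.response + rng.normal(0.0, noise_sigma, sg.response.shape),
                sched,
                sg.label,
            )
        out.append(sg)
    manifest = GroundTruthManifest(
        generator="generate_sensorgram_set",
        seed=seed,
        parameters={
            "kinetics": _kinetics_dict(params),
            "concentrations_M": [float(c) for c in concentrations],
            "noise_sigma_RU": float(noise_sigma),
            "t_assoc_s": t_assoc,
            "t_dissoc_s": t_dissoc,
            "points_per_curve": points_per_curve,
        },
    )
    return out, manifest


def generate_isotherm(
    constants: StepwiseConstants,
    C_grid: Sequence[float] = DEFAULT_CONCENTRATIONS_M,
    noise_sigma_r: float = 0.0,
    seed: int = 0,
    RUmax: float = 1.0,
) -> tuple[SteadyStateIsotherm, GroundTruthManifest]:
    """Steady-state isotherm r(C) with Gaussian noise on r."""
    if noise_sigma_r < 0:
        raise ValueError("noise_sigma_r must be >= 0")
    rng = np.random.default_rng(seed)
    C = np.asarray(sorted(C_grid), dtype=float)
    r = np.asarray(constants.fraction_bound(C), dtype=float)
    if noise_sigma_r > 0:
        r = r + rng.normal(0.0, noise_sigma_r, r.shape)
    r = np.clip(r, 0.0, None)  # keep the isotherm physically valid
    iso = SteadyStateIsotherm(C_free=C, r=r, RUmax=RUmax)
    manifest = GroundTruthManifest(
        generator="generate_isotherm",
        seed=seed,
        parameters={
            "constants": _constants_dict(constants),
            "C_grid_M": [float(c) for c in C],
            "noise_sigma_r": float(noise_sigma_r),
            "RUmax": RUmax,
        },
    )
    return iso, manifest


def generate_competition_dataset(
    mixture: Sequence[DnaSpeciesSpec] | None = None,
    ligand: LigandSpec | None = None,
    seed: int = 0,
) -> tuple[list[DnaSpeciesSpec], LigandSpec, SpeciesDistribution, GroundTruthManifest]:
    """Config-ready competition mixture plus its ground-truth speciation.

    Defaults to the published competition design: -AATT- and -TTAA-
    hairpins at 10 uM each sharing 20 uM DB1003 (a 2:1 compound:DNA
    ratio).
    """
    if mixture is None:
        mixture = [
            DnaSpeciesSpec("TTAA", 10e-6, EQUILIBRIUM_PRESETS["DB1003-TTAA"]),
            DnaSpeciesSpec("AATT", 10e-6, EQUILIBRIUM_PRESETS["DB1003-AATT"]),
        ]
    if ligand is None:
        ligand = LigandSpec("DB1003", 20e-6)
    dist = species_distribution(mixture, ligand)
    manifest = GroundTruthManifest(
        generator="generate_competition_dataset",
        seed=seed,
        parameters={
            "dna": [
                {
                    "name": s.name,
                    "total_M": s.total,
                    "binding": _constants_dict(s.binding),
                    "mass_Da": s.mass,
                }
                for s in mixture
            ],
            "ligand": {"name": ligand.name, "total_M": ligand.total, "mass_Da": ligand.mass},
            "expected": {
                "free_ligand_M": dist.free_ligand,
                **{
                    name: {"free": s.free, "1:1": s.complex_1to1, "2:1": s.complex_2to1}
                    for name, s in dist.per_dna.items()
                },
            },
        },
    )
    return list(mixture), ligand, dist, manifest


def generate_titration_dataset(
    design: TitrationDesign | None = None,
    constants: StepwiseConstants | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    signal_weights: tuple[float, float] = (1.0, 2.0),
) -> tuple[TitrationCurve, GroundTruthManifest]:
    """Closed-cell titration curve with Gaussian signal noise.

    Defaults to the published titration design (5 uM DNA, ten 1 uM
    ligand increments) with the DB1003 -TTAA- dimer constants.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if design is None:
        design = TitrationDesign(D_total=5e-6, increment=1e-6, n_steps=10)
    if constants is None:
        constants = EQUILIBRIUM_PRESETS["DB1003-TTAA"]
    rng = np.random.default_rng(seed)
    curve = simulate_titration_curve(design, constants, signal_weights=signal_weights)
    signal = curve.signal
    if noise_sigma > 0:
        signal = signal + rng.normal(0.0, noise_sigma, signal.shape)
    curve = TitrationCurve(ratio=curve.ratio, signal=signal)
    manifest = GroundTruthManifest(
        generator="generate_titration_dataset",
        seed=seed,
        parameters={
            "design": {
                "D_total_M": design.D_total,
                "increment_M": design.increment,
                "n_steps": design.n_steps,
            },
            "constants": _constants_dict(constants),
            "signal_weights": list(signal_weights),
            "noise_sigma": float(noise_sigma),
        },
    )
    return curve, manifest
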