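"""Multi-DNA shared-ligand equilibrium speciation and native-MS prediction.

The competition ESI-MS experiment mixes several hairpin DNAs with one
ligand pool in a closed cell; at equilibrium every DNA sees the same
free ligand concentration L, so the deconvoluted neutral-mass peak
pattern directly reports each sequence's preferred stoichiometry.  The
solver finds L from total-ligand conservation,

    L_tot = L + sum_j D_tot,j * r_j(L),

where r_j is the bound fraction from the j-th DNA's binding polynomial.
The left side is strictly increasing in L and brackets L_tot on
[0, L_tot], so the root is unique; it is found with a guaranteed
bracketed root search.  Back-substitution through each binding
polynomial P = 1 + K_A1*L + K_A1*K_A2*L^2 yields every species
concentration:

    [D] = D_tot/P,  [DL] = D_tot*K_A1*L/P,  [DL2] = D_tot*K_A1*K_A2*L^2/P.

Predicted spectra assume equal electrospray response factors for free
DNA and complexes (relative peak heights read as mole fractions) —
charge-state deconvolution, adducts and isotope envelopes are out of
scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import brentq

from .equilibrium import BindingModel, StepwiseConstants

__all__ = [
    "DnaSpeciesSpec",
    "LigandSpec",
    "DnaSpeciation",
    "SpeciesDistribution",
    "MassPeak",
    "solve_free_ligand",
    "species_distribution",
    "oligo_average_mass",
    "predict_ms_spectrum",
]


@dataclass(frozen=True)
class DnaSpeciesSpec:
    """One DNA hairpin in the mixture: totals, binding model, neutral mass."""

    name: str
    total: float  # M
    binding: StepwiseConstants
    mass: float | None = None  # Da, optional until spectra are predicted

    def __post_init__(self) -> None:
        if not (np.isfinite(self.total) and self.total > 0):
            raise ValueError(f"total concentration must be > 0, got {self.total!r}")
        if self.mass is not None and not self.mass > 0:
            raise ValueError(f"mass must be > 0, got {self.mass!r}")


@dataclass(frozen=True)
class LigandSpec:
    name: str
    total: float  # M
    mass: float | None = None  # Da

    def __post_init__(self) -> None:
        if not (np.isfinite(self.total) and self.total >= 0):
            raise ValueError(f"total concentration must be >= 0, got {self.total!r}")
        if self.mass is not None and not self.mass > 0:
            raise ValueError(f"mass must be > 0, got {self.mass!r}")


class DnaSpeciation(NamedTuple):
    """Equilibrium concentrations (M) of one DNA's ligation states."""

    free: float
    complex_1to1: float
    complex_2to1: float

    @property
    def total(self) -> float:
        return self.free + self.complex_1to1 + self.complex_2to1

    @property
    def bound_ligand(self) -> float:
        return self.complex_1to1 + 2.0 * self.complex_2to1


@dataclass(frozen=True)
class SpeciesDistribution:
    """Solved equilibrium of a competition mixture."""

    free_ligand: float  # M
    per_dna: dict  # name -> DnaSpeciation
    mixture: tuple  # the DnaSpeciesSpec inputs
    ligand: LigandSpec

    def mass_balance_errors(self) -> dict:
        """Relative conservation errors for the ligand and each DNA."""
        errors = {}
        bound = sum(s.bound_ligand for s in self.per_dna.values())
        if self.ligand.total > 0:
            errors["ligand"] = abs(self.free_ligand + bound - self.ligand.total) / self.ligand.total
        else:
            errors["ligand"] = abs(self.free_ligand + bound)
        for spec in self.mixture:
            s = self.per_dna[spec.name]
            errors[spec.name] = abs(s.total - spec.total) / spec.total
        return errors


def _total_ligand_at(L: float, mixture: Sequence[DnaSpeciesSpec]) -> float:
    return L + sum(spec.total * spec.binding.fraction_bound(L) for spec in mixture)


def solve_free_ligand(
    mixture: Sequence[DnaSpeciesSpec],
    ligand: LigandSpec,
    rtol: float = 1e-14,
) -> float:
    """Free ligand concentration (M) at equilibrium of the mixture.

    Unique root of L_tot = L + sum_j D_tot,j * r_j(L) on [0, L_tot].
    """
    names = [spec.name for spec in mixture]
    if len(set(names)) != len(names):
        raise ValueError("DNA species names must be unique")
    Ltot = ligand.total
    if Ltot == 0 or not mixture:
        return float(Ltot)
    f = lambda L: _total_ligand_at(L, mixture) - Ltot
    # f(0) = -Ltot < 0, f(Ltot) >= 0: guaranteed bracket
    return float(brentq(f, 0.0, Ltot, rtol=max(rtol, 4.0 * np.finfo(float).eps), xtol=1e-300))


def species_distribution(
    mixture: Sequence[DnaSpeciesSpec],
    ligand: LigandSpec,
) -> SpeciesDistribution:
    """Full speciation: free ligand plus every DNA ligation state (M)."""
    L = solve_free_ligand(mixture, ligand)
    per_dna = {}
    for spec in mixture:
        b = spec.binding
        free_frac, frac_1, frac_2 = b.species_fractions(L)
        per_dna[spec.name] = DnaSpeciation(
            free=spec.total * float(free_frac),
            complex_1to1=spec.total * float(frac_1),
            complex_2to1=spec.total * float(frac_2),
        )
    return SpeciesDistribution(
        free_ligand=L, per_dna=per_dna, mixture=tuple(mixture), ligand=ligand
    )


# Average masses (Da) of 2'-deoxynucleoside-5'-monophosphate residues as
# incorporated in a chain (nucleoside monophosphate), standard isotope
# abundances.  An oligo of n residues linked by phosphodiesters carries
# n-1 waters fewer than the free monophosphates; the 5' terminus is
# either phosphate (keep the 5'-terminal HPO3) or hydroxyl (drop it).
_DNMP_AVERAGE_MASS = {
    "A": 331.2218,
    "C": 307.1971,
    "G": 347.2212,
    "T": 322.2085,
}
_WATER = 18.01528
_HPO3 = 79.9799


def oligo_average_mass(sequence: str, five_prime: str = "OH") -> float:
    """Average neutral mass (Da) of a single-stranded DNA oligo.

    Hairpin duplexes are single strands and use this convention
    directly.  ``five_prime`` is ``"OH"`` (synthetic oligo default) or
    ``"phosphate"``.
    """
    if not sequence:
        raise ValueError("sequence must be nonempty")
    seq = sequence.upper()
    bad = set(seq) - set(_DNMP_AVERAGE_MASS)
    if bad:
        raise ValueError(f"non-ACGT characters in sequence: {sorted(bad)}")
    if five_prime not in ("OH", "phosphate"):
        raise ValueError("five_prime must be 'OH' or 'phosphate'")
    mass = sum(_DNMP_AVERAGE_MASS[b] for b in seq) - (len(seq) - 1) * _WATER
    if five_prime == "OH":
        mass -= _HPO3  # R-O-PO3H2 -> R-OH
    return mass


@dataclass(frozen=True)
class MassPeak:
    species: str
    mass: float  # Da, neutral
    intensity: float  # relative, max = 100


def predict_ms_spectrum(
    dist: SpeciesDistribution,
    populated_threshold: float = 1e-12,
) -> list[MassPeak]:
    """Deconvoluted neutral-mass peak list from a solved distribution.

    One peak per DNA-containing species, with mass(DNA·nL) =
    mass(DNA) + n*mass(ligand) and intensity proportional to molar
    concentration (equal response factors), normalized to max = 100.
    Species below ``populated_threshold`` (relative to the most
    abundant species) are omitted; a populated species with a missing
    mass raises.
    """
    concentrations: list[tuple[str, float, float | None]] = []
    for spec in dist.mixture:
        s = dist.per_dna[spec.name]
        lig_mass = dist.ligand.mass
        for n, conc in ((0, s.free), (1, s.complex_1to1), (2, s.complex_2to1)):
            label = spec.name if n == 0 else f"{spec.name}+{n}{dist.ligand.name}"
            mass = None
            if spec.mass is not None and (n == 0 or lig_mass is not None):
                mass = spec.mass + n * lig_mass if n else spec.mass
            concentrations.append((label, conc, mass))
    cmax = max(c for _, c, _ in concentrations)
    if cmax <= 0:
        return []
    peaks = []
    for label, conc, mass in concentrations:
        if conc / cmax < populated_threshold:
            continue
        if mass is None:
            raise ValueError(f"species {label!r} is populated but has no mass assigned")
        peaks.append(MassPeak(species=label, mass=mass, intensity=100.0 * conc / cmax))
    peaks.sort(key=lambda p: p.mass)
    return peaks
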