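"""Closed-form equilibrium binding models and cooperativity metrics.

A heterocyclic diamidine binding the minor groove of a hairpin DNA is
described either by a single association constant ``K_A`` (1:1 complex)
or by two stepwise association constants ``K_A1``/``K_A2`` (sequential
2:1 complex, the Adair scheme).  The binding polynomial

    P(C) = 1 + K_A1*C + K_A1*K_A2*C**2

is the partition function over ligation states at free ligand
concentration ``C``; moles of ligand bound per DNA is

    r(C) = (C/P) dP/dC = (K_A1*C + 2*K_A1*K_A2*C**2) / P(C).

For two *independent, equivalent* sites statistical factors impose
``K_A1 = 4*K_A2``, so the cooperativity index ``K_coop = 4*K_A2/K_A1``
equals 1 at the non-cooperative baseline, >1 for positive cooperativity
(the stacked-dimer case) and <1 for negative cooperativity.

All concentrations are molar and all association constants M^-1;
unit conversion from nM/uM happens only at the I/O boundary.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BindingModel",
    "Cooperativity",
    "StepwiseConstants",
    "CooperativityReport",
    "SelectivityReport",
    "STATISTICAL_FACTOR_BASELINE",
    "fraction_bound_one_site",
    "fraction_bound_two_site",
    "cooperativity_index",
    "average_equilibrium_constant",
    "selectivity_ratio",
    "classify_cooperativity",
]

#: K_A2/K_A1 for two independent equivalent sites (pure statistics,
#: no interaction between the bound ligands).
STATISTICAL_FACTOR_BASELINE = 0.25


class BindingModel(str, enum.Enum):
    ONE_SITE = "one_site"
    TWO_SITE = "two_site"


class Cooperativity(str, enum.Enum):
    POSITIVE = "positive"
    NON_COOPERATIVE = "non_cooperative"
    NEGATIVE = "negative"


def _require_positive(value: float, name: str) -> None:
    if not (np.isfinite(value) and value > 0):
        raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")


@dataclass(frozen=True)
class StepwiseConstants:
    """Equilibrium description of one ligand/DNA-site pair.

    Use :meth:`one_site` or :meth:`two_site` to construct.  A one-site
    system carries ``K_A`` only; a two-site system carries ``K_A1`` and
    ``K_A2`` (both M^-1, both strictly positive).
    """

    model: BindingModel
    K_A: float | None = None
    K_A1: float | None = None
    K_A2: float | None = None

    def __post_init__(self) -> None:
        model = BindingModel(self.model)
        object.__setattr__(self, "model", model)
        if model is BindingModel.ONE_SITE:
            if self.K_A is None or self.K_A1 is not None or self.K_A2 is not None:
                raise ValueError("one_site model takes exactly one constant K_A")
            _require_positive(self.K_A, "K_A")
        else:
            if self.K_A is not None or self.K_A1 is None or self.K_A2 is None:
                raise ValueError("two_site model takes exactly K_A1 and K_A2")
            _require_positive(self.K_A1, "K_A1")
            _require_positive(self.K_A2, "K_A2")

    @classmethod
    def one_site(cls, K_A: float) -> "StepwiseConstants":
        return cls(model=BindingModel.ONE_SITE, K_A=K_A)

    @classmethod
    def two_site(cls, K_A1: float, K_A2: float) -> "StepwiseConstants":
        return cls(model=BindingModel.TWO_SITE, K_A1=K_A1, K_A2=K_A2)

    @property
    def max_stoichiometry(self) -> int:
        return 1 if self.model is BindingModel.ONE_SITE else 2

    def fraction_bound(self, C_free):
        """Moles of ligand bound per DNA at free ligand concentration C (M)."""
        if self.model is BindingModel.ONE_SITE:
            return fraction_bound_one_site(self.K_A, C_free)
        return fraction_bound_two_site(self.K_A1, self.K_A2, C_free)

    def binding_polynomial(self, C_free):
        """Partition function P(C) over ligation states."""
        C = _validated_concentration(C_free)
        if self.model is BindingModel.ONE_SITE:
            return 1.0 + self.K_A * C
        return 1.0 + self.K_A1 * C + self.K_A1 * self.K_A2 * C**2

    def species_fractions(self, C_free):
        """Fractions (free DNA, 1:1 complex, 2:1 complex) at free ligand C.

        The 2:1 entry is identically zero for a one-site system.
        """
        C = _validated_concentration(C_free)
        P = self.binding_polynomial(C)
        if self.model is BindingModel.ONE_SITE:
            return 1.0 / P, self.K_A * C / P, np.zeros_like(np.asarray(C, dtype=float))
        return (
            1.0 / P,
            self.K_A1 * C / P,
            self.K_A1 * self.K_A2 * C**2 / P,
        )

    def cooperativity(self, tolerance: float = 0.25) -> "CooperativityReport":
        if self.model is not BindingModel.TWO_SITE:
            raise ValueError("cooperativity is defined for two_site systems only")
        k_coop = cooperativity_index(self.K_A1, self.K_A2)
        return CooperativityReport(
            K_coop=k_coop,
            K_avg=average_equilibrium_constant(self.K_A1, self.K_A2),
            classification=classify_cooperativity(k_coop, tolerance),
        )

    @property
    def overall_constant(self) -> float:
        """Single-number affinity: K_A for 1:1, geometric-mean K for 2:1."""
        if self.model is BindingModel.ONE_SITE:
            return self.K_A
        return average_equilibrium_constant(self.K_A1, self.K_A2)


@dataclass(frozen=True)
class CooperativityReport:
    K_coop: float
    K_avg: float
    classification: Cooperativity


@dataclass(frozen=True)
class SelectivityReport:
    ratio: float
    numerator_label: str
    denominator_label: str


def _validated_concentration(C_free):
    C = np.asarray(C_free, dtype=float)
    if np.any(~np.isfinite(C)) or np.any(C < 0):
        raise ValueError("free ligand concentration must be finite and >= 0")
    return C if C.ndim else float(C)


def fraction_bound_one_site(K_A: float, C_free):
    """r = K*C / (1 + K*C): moles ligand bound per DNA for a 1:1 complex.

    Monotone in C, r(0) = 0, r -> 1 as C -> inf; r = 0.5 at C = 1/K_A.
    """
    _require_positive(K_A, "K_A")
    C = _validated_concentration(C_free)
    x = K_A * C
    return x / (1.0 + x)


def fraction_bound_two_site(K_A1: float, K_A2: float, C_free):
    """Sequential two-site (Adair) bound fraction, in [0, 2).

    r = (K_A1*C + 2*K_A1*K_A2*C^2) / (1 + K_A1*C + K_A1*K_A2*C^2),
    i.e. (C/P) dP/dC of the binding polynomial P.
    """
    _require_positive(K_A1, "K_A1")
    _require_positive(K_A2, "K_A2")
    C = _validated_concentration(C_free)
    x1 = K_A1 * C
    x2 = K_A1 * K_A2 * C**2
    return (x1 + 2.0 * x2) / (1.0 + x1 + x2)


def cooperativity_index(K_A1: float, K_A2: float) -> float:
    """Cooperativity index K_coop = 4*K_A2/K_A1.

    The statistical factor 4 makes K_coop = 1 for independent equivalent
    sites (where K_A1 = 4*K_A2 on entropic grounds alone).
    """
    _require_positive(K_A1, "K_A1")
    _require_positive(K_A2, "K_A2")
    return 4.0 * K_A2 / K_A1

def average_equilibrium_constant(K_A1: float, K_A2: float) -> float:
    """Geometric-mean association constant sqrt(K_A1*K_A2), M^-1.

    Symmetric and scale-equivariant; the conventional single-number
    affinity for a two-step system.
    """
    _require_positive(K_A1, "K_A1")
    _require_positive(K_A2, "K_A2")
    return math.sqrt(K_A1) * math.sqrt(K_A2)


def selectivity_ratio(
    K_target: float,
    K_reference: float,
    numerator_label: str = "target",
    denominator_label: str = "reference",
) -> SelectivityReport:
    """Affinity ratio between two sequences (e.g. K_TTAA / K_AATT)."""
    _require_positive(K_target, "K_target")
    _require_positive(K_reference, "K_reference")
    return SelectivityReport(
        ratio=K_target / K_reference,
        numerator_label=numerator_label,
        denominator_label=denominator_label,
    )


def classify_cooperativity(K_coop: float, tolerance: float = 0.25) -> Cooperativity:
    """Label a cooperativity index relative to the K_coop = 1 baseline.

    ``tolerance`` is the half-width of the band called non-cooperative
    (default 0.25: K_coop in [0.75, 1.25]).
    """
    _require_positive(K_coop, "K_coop")
    if not (0.0 < tolerance < 1.0):
        raise ValueError(f"tolerance must lie in (0, 1), got {tolerance!r}")
    if K_coop > 1.0 + tolerance:
        return Cooperativity.POSITIVE
    if K_coop < 1.0 - tolerance:
        return Cooperativity.NEGATIVE
    return Cooperativity.NON_COOPERATIVE
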