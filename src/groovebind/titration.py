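"""Closed-cell titration curves and saturation-stoichiometry breakpoints.

An induced-CD titration adds ligand stepwise to a cuvette holding a
fixed DNA concentration; the ICD signal appears only on binding, so a
tight binder traces a straight line that kinks to a plateau when the
DNA saturates.  The kink abscissa, in ligand:DNA ratio units, IS the
stoichiometry: 1.0 for a monomer complex, 2.0 for a stacked dimer.

The signal model is a linear combination of bound species,
signal = w1*[DL] + w2*[DL2], default weights (1, 2) (signal tracks
bound-ligand count).  ICD amplitudes are not calibrated to any
instrument; only curve shape and breakpoint position are meaningful.
Breakpoints come from an exhaustive two-segment linear fit, and a
curve that is adequately linear overall is flagged as having *no*
detectable breakpoint rather than returning a meaningless ratio —
weak binding never yields a stoichiometry claim.

Dilution on addition is ignored by default (increments are
post-addition concentrations); ``volume_tracking`` applies the
cumulative dilution of both DNA and ligand instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .competition import DnaSpeciesSpec, DnaSpeciation, LigandSpec, solve_free_ligand
from .equilibrium import StepwiseConstants

__all__ = [
    "TitrationDesign",
    "TitrationCurve",
    "BreakpointEstimate",
    "closed_system_species",
    "simulate_titration_curve",
    "estimate_breakpoint",
]


@dataclass(frozen=True)
class TitrationDesign:
    """Fixed DNA total, equal ligand increments, n_steps additions."""

    D_total: float  # M
    increment: float  # M ligand added per step (post-addition concentration)
    n_steps: int

    def __post_init__(self) -> None:
        if not self.D_total > 0:
            raise ValueError("D_total must be positive")
        if not self.increment > 0:
            raise ValueError("increment must be positive")
        if self.n_steps < 3:
            raise ValueError("need at least 3 titration steps")

    def ligand_totals(self) -> np.ndarray:
        return self.increment * np.arange(1, self.n_steps + 1)

    def ratios(self) -> np.ndarray:
        return self.ligand_totals() / self.D_total


@dataclass
class TitrationCurve:
    """Signal vs ligand:DNA ratio, optionally with an estimated breakpoint."""

    ratio: np.ndarray
    signal: np.ndarray
    breakpoint: float | None = None

    def __post_init__(self) -> None:
        self.ratio = np.asarray(self.ratio, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.ratio.ndim != 1 or self.ratio.size == 0:
            raise ValueError("ratio must be a nonempty 1-D array")
        if np.any(self.ratio <= 0) or np.any(np.diff(self.ratio) <= 0):
            raise ValueError("ratio must be strictly increasing from > 0")
        if self.signal.shape != self.ratio.shape or np.any(~np.isfinite(self.signal)):
            raise ValueError("signal must be finite and match ratio in length")


def closed_system_species(
    D_total: float,
    L_total: float,
    binding: StepwiseConstants,
) -> tuple[float, DnaSpeciation]:
    """Equilibrium of one DNA + ligand at fixed totals (closed cell).

    Returns (free ligand M, DnaSpeciation).  L_total = 0 is valid and
    gives all DNA free.
    """
    if not D_total > 0:
        raise ValueError("D_total must be positive")
    if L_total < 0:
        raise ValueError("L_total must be nonnegative")
    spec = DnaSpeciesSpec(name="dna", total=D_total, binding=binding)
    ligand = LigandSpec(name="ligand", total=L_total)
    L = solve_free_ligand([spec], ligand)
    f0, f1, f2 = binding.species_fractions(L)
    return L, DnaSpeciation(
        free=D_total * float(f0),
        complex_1to1=D_total * float(f1),
        complex_2to1=D_total * float(f2),
    )


def simulate_titration_curve(
    design: TitrationDesign,
    binding: StepwiseConstants,
    signal_weights: tuple[float, float] = (1.0, 2.0),
    volume_tracking: bool = False,
    initial_volume: float = 1.0,
    addition_volume: float = 0.0,
) -> TitrationCurve:
    """Forward-simulate signal vs ligand:DNA ratio for one binding model.

    ``signal_weights`` = (w1, w2) weight the 1:1 and 2:1 complexes; the
    default (1, 2) makes the signal proportional to bound ligand.  With
    ``volume_tracking`` each addition of ``addition_volume`` dilutes
    everything in the cell.
    """
    w1, w2 = signal_weights
    if w1 < 0 or w2 < 0:
        raise ValueError("signal weights must be nonnegative")
    ratios = []
    signals = []
    for i, L_total in enumerate(design.ligand_totals(), start=1):
        D_total = design.D_total
        if volume_tracking:
            if addition_volume <= 0:
                raise ValueError("volume_tracking requires addition_volume > 0")
            dilution = initial_volume / (initial_volume + i * addition_volume)
            D_total = design.D_total * dilution
            L_total = L_total * dilution
        _, s = closed_system_species(D_total, L_total, binding)
        ratios.append(L_total / D_total)
        signals.append(w1 * s.complex_1to1 + w2 * s.complex_2to1)
    return TitrationCurve(ratio=np.array(ratios), signal=np.array(signals))


class BreakpointEstimate(NamedTuple):
    breakpoint: float | None
    rss: float
    flagged_absent: bool
    slopes: tuple[float, float] | None


def _line_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    rss = float(np.sum((slope * x + intercept - y) ** 2))
    return float(slope), float(intercept), rss


def estimate_breakpoint(
    curve: TitrationCurve,
    slope_similarity: float = 0.2,
) -> BreakpointEstimate:
    """Two-segment linear breakpoint of a titration curve.

    Every admissible split (>= 2 points per segment) is scored by total
    RSS; the winner's segment-line intersection gives the breakpoint
    ratio.  If the two best-fit slopes differ by less than
    ``slope_similarity`` (relative to the steeper one) the curve is
    effectively a single line and the breakpoint is flagged absent.
    """
    x, y = curve.ratio, curve.signal
    n = x.size
    if n < 5:
        raise ValueError("breakpoint estimation needs >= 5 points spanning the kink")
    best = None
    for split in range(2, n - 1):  # segments x[:split], x[split:]
        s1, b1, rss1 = _line_fit(x[:split], y[:split])
        s2, b2, rss2 = _line_fit(x[split:], y[split:])
        total = rss1 + rss2
        if best is None or total < best[0]:
            best = (total, s1, b1, s2, b2)
    total, s1, b1, s2, b2 = best
    steeper = max(abs(s1), abs(s2))
    if steeper == 0 or abs(s1 - s2) < slope_similarity * steeper:
        return BreakpointEstimate(None, total, True, (s1, s2))
    bp = (b2 - b1) / (s1 - s2)
    if not (x[0] <= bp <= x[-1]):
        return BreakpointEstimate(None, total, True, (s1, s2))
    return BreakpointEstimate(float(bp), total, False, (s1, s2))
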