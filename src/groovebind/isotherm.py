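"""Steady-state isotherm construction and one-site vs two-site fitting.

The steady-state route to binding constants reads the plateau response
RU_ss off each sensorgram, normalizes it to moles bound per DNA
(r = RU/RUmax, where RUmax is the response at ONE ligand per DNA so a
saturated 2:1 dimer plateaus near r = 2), and fits r against the free
ligand concentration with either the 1:1 hyperbola or the sequential
two-site binding polynomial.  Under flow conditions the free
concentration equals the injected concentration, so no depletion
correction is applied.

Model choice is formalized through AIC; near-ties fall back to the
plateau-stoichiometry heuristic (max observed r > 1.3 implies a 2:1
complex) that practitioners read directly off the saturation level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import lmfit
import numpy as np

from .equilibrium import (
    BindingModel,
    StepwiseConstants,
    fraction_bound_one_site,
    fraction_bound_two_site,
)
from .kinetics import Sensorgram

__all__ = [
    "SteadyStateIsotherm",
    "PlateauEstimate",
    "extract_plateau",
    "normalize_response",
    "IsothermModel",
    "IsothermResults",
    "ModelSelection",
    "select_model",
]

#: |slope| above which a plateau window is flagged as drifting (RU/s).
DRIFT_SLOPE_THRESHOLD = 0.05

#: max observed r above which the plateau heuristic calls a 2:1 complex.
STOICHIOMETRY_HEURISTIC_R = 1.3


@dataclass
class SteadyStateIsotherm:
    """Paired (free ligand concentration, normalized response) data.

    ``r`` is moles of ligand bound per DNA; ``RUmax`` records the
    normalization convention (response at one ligand per DNA).
    """

    C_free: np.ndarray
    r: np.ndarray
    RUmax: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        self.C_free = np.asarray(self.C_free, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.C_free.ndim != 1 or self.C_free.size == 0:
            raise ValueError("C_free must be a nonempty 1-D array")
        if np.any(self.C_free <= 0) or np.any(np.diff(self.C_free) <= 0):
            raise ValueError("C_free must be strictly positive and strictly increasing")
        if self.r.shape != self.C_free.shape:
            raise ValueError("C_free and r must have matching shapes")
        if np.any(~np.isfinite(self.r)) or np.any(self.r < 0):
            raise ValueError("r must be finite and nonnegative")
        if not self.RUmax > 0:
            raise ValueError("RUmax must be positive")

    @classmethod
    def from_responses(cls, C_free, RU_ss, RUmax: float, label: str = ""):
        """Build from raw plateau responses, applying r = RU/RUmax."""
        r = np.array([normalize_response(v, RUmax) for v in np.atleast_1d(RU_ss)])
        return cls(C_free=np.asarray(C_free, float), r=r, RUmax=RUmax, label=label)

    @staticmethod
    def average(isotherms: list["SteadyStateIsotherm"]) -> tuple["SteadyStateIsotherm", np.ndarray]:
        """Average replicate isotherms point-wise (replicates on one grid).

        Returns the averaged isotherm and the point-wise half-range
        (max-min)/2, reported as spread rather than a formal CI.
        """
        if not isotherms:
            raise ValueError("need at least one isotherm")
        grids = np.array([iso.C_free for iso in isotherms])
        if not np.allclose(grids, grids[0], rtol=1e-12):
            raise ValueError("replicate isotherms must share the concentration grid")
        stack = np.array([iso.r for iso in isotherms])
        mean = SteadyStateIsotherm(
            C_free=isotherms[0].C_free,
            r=stack.mean(axis=0),
            RUmax=isotherms[0].RUmax,
            label="mean of %d replicates" % len(isotherms),
        )
        spread = (stack.max(axis=0) - stack.min(axis=0)) / 2.0
        return mean, spread


class PlateauEstimate(NamedTuple):
    RU_ss: float
    slope: float  # RU/s over the averaging window
    drift_flagged: bool


def extract_plateau(
    sensorgram: Sensorgram,
    window_fraction: float = 0.2,
    drift_threshold: float = DRIFT_SLOPE_THRESHOLD,
) -> PlateauEstimate:
    """Mean response over the trailing window of the association phase.

    The window covers the last ``window_fraction`` of the association
    time; a linear trend steeper than ``drift_threshold`` RU/s flags the
    estimate as not at steady state (returned, not raised).
    """
    if not (0.0 < window_fraction <= 0.5):
        raise ValueError("window_fraction must lie in (0, 0.5]")
    sched = sensorgram.schedule
    t_window = sched.t_stop - window_fraction * (sched.t_stop - sched.t_start)
    mask = (sensorgram.time >= t_window) & (sensorgram.time <= sched.t_stop)
    if not np.any(mask):
        raise ValueError("no association-phase samples inside the plateau window")
    t, R = sensorgram.time[mask], sensorgram.response[mask]
    slope = 0.0 if t.size < 2 else float(np.polyfit(t, R, 1)[0])
    return PlateauEstimate(
        RU_ss=float(np.mean(R)),
        slope=slope,
        drift_flagged=abs(slope) > drift_threshold,
    )


def normalize_response(RU_ss: float, RUmax: float) -> float:
    """r = RU_ss / RUmax (moles bound per DNA; ~2 at dimer saturation)."""
    if not (np.isfinite(RUmax) and RUmax > 0):
        raise ValueError(f"RUmax must be strictly positive, got {RUmax!r}")
    return float(RU_ss) / float(RUmax)


class IsothermModel:
    """Equilibrium binding model for a steady-state isotherm.

    Fits r(C) with positivity-bounded least squares (via lmfit).  The
    one-site model needs >= 4 points, the two-site model >= 6.  Default
    initialization follows the half-saturation rule: K_A1 = 1/C_half
    with C_half the concentration nearest half the maximal observed r,
    and K_A2 = K_A1/4 (the non-cooperative start).

    Parameters
    ----------
    data : SteadyStateIsotherm
    model : {"one_site", "two_site"}
    weights : array-like, optional
        Per-point least-squares weights; default unweighted.  Pass
        ``1/r``-style weights explicitly if desired.
    """

    _MIN_POINTS = {BindingModel.ONE_SITE: 4, BindingModel.TWO_SITE: 6}

    def __init__(self, data: SteadyStateIsotherm, model="two_site", weights=None):
        self.data = data
        self.model = BindingModel(model)
        n = data.C_free.size
        if n < self._MIN_POINTS[self.model]:
            raise ValueError(
                f"{self.model.value} fit needs >= {self._MIN_POINTS[self.model]} "
                f"points, got {n}"
            )
        self.weights = None if weights is None else np.asarray(weights, dtype=float)
        if self.weights is not None and self.weights.shape != data.r.shape:
            raise ValueError("weights must match the data length")

    def _default_init(self) -> dict:
        r = self.data.r
        C = self.data.C_free
        half = 0.5 * float(np.max(r))
        C_half = float(C[np.argmin(np.abs(r - half))])
        K1 = 1.0 / C_half
        if self.model is BindingModel.ONE_SITE:
            return {"K_A": K1}
        return {"K_A1": K1, "K_A2": K1 / 4.0}

    def _predict(self, pars, C) -> np.ndarray:
        if self.model is BindingModel.ONE_SITE:
            return fraction_bound_one_site(pars["K_A"], C)
        return fraction_bound_two_site(pars["K_A1"], pars["K_A2"], C)

    def fit(self, init: dict | StepwiseConstants | None = None) -> "IsothermResults":
        if isinstance(init, StepwiseConstants):
            if init.model is not self.model:
                raise ValueError("init constants do not match the requested model")
            init = (
                {"K_A": init.K_A}
                if self.model is BindingModel.ONE_SITE
                else {"K_A1": init.K_A1, "K_A2": init.K_A2}
            )
        start = self._default_init()
        if init:
            start.update(init)
        pars = lmfit.Parameters()
        for name, value in start.items():
            pars.add(name, value=value, min=1e-3, max=1e18)

        def residual(p):
            res = self._predict(p, self.data.C_free) - self.data.r
            return res if self.weights is None else res * self.weights

        out = lmfit.minimize(residual, pars, method="least_squares")
        values = {k: float(out.params[k].value) for k in start}
        stderr = {
            k: (float(out.params[k].stderr) if out.params[k].stderr is not None else float("nan"))
            for k in start
        }
        constants = (
            StepwiseConstants.one_site(values["K_A"])
            if self.model is BindingModel.ONE_SITE
            else StepwiseConstants.two_site(values["K_A1"], values["K_A2"])
        )
        return IsothermResults(
            model=self,
            constants=constants,
            bse=stderr,
            rss=float(out.chisqr),
            aic=float(out.aic),
            n_obs=int(out.ndata),
            converged=bool(out.success),
            message=str(out.message),
        )


@dataclass
class IsothermResults:
    """Fitted equilibrium constants with uncertainties and fit metrics."""

    model: IsothermModel
    constants: StepwiseConstants
    bse: dict
    rss: float
    aic: float
    n_obs: int
    converged: bool
    message: str = ""

    def predict(self, C_free) -> np.ndarray:
        return self.constants.fraction_bound(C_free)

    def cooperativity(self, tolerance: float = 0.25):
        return self.constants.cooperativity(tolerance)

    def summary(self) -> str:
        c = self.constants
        lines = [
            f"Steady-state isotherm fit ({c.model.value})",
            "=" * 46,
            f"observations: {self.n_obs}   converged: {self.converged}",
            f"{'param':<8}{'estimate':>14}{'std err':>14}",
        ]
        names = ("K_A",) if c.model is BindingModel.ONE_SITE else ("K_A1", "K_A2")
        for name in names:
            lines.append(f"{name:<8}{getattr(c, name):>14.5g}{self.bse[name]:>14.3g}")
        if c.model is BindingModel.TWO_SITE:
            rep = self.cooperativity()
            lines.append(f"K_coop = {rep.K_coop:.4g} ({rep.classification.value})")
            lines.append(f"K_avg  = {rep.K_avg:.4g} M^-1")
        lines.append(f"RSS = {self.rss:.6g}   AIC = {self.aic:.4g}")
        if self.message:
            lines.append(f"note: {self.message}")
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Quick-look r vs C with the fitted curve on a log axis."""
        import matplotlib.pyplot as plt

        data = self.model.data
        if ax is None:
            _, ax = plt.subplots()
        ax.semilogx(data.C_free, data.r, "o", label="data")
        grid = np.geomspace(data.C_free[0], data.C_free[-1], 200)
        ax.semilogx(grid, self.predict(grid), "-", label="fit")
        ax.set_xlabel("free ligand (M)")
        ax.set_ylabel("r (mol ligand / mol DNA)")
        ax.legend()
        return ax


@dataclass
class ModelSelection:
    preferred: BindingModel | None
    delta_aic: float  # AIC(one_site) - AIC(two_site); >0 favors two_site
    indeterminate: bool
    heuristic: BindingModel = field(default=BindingModel.ONE_SITE)

    @property
    def recommendation(self) -> BindingModel:
        return self.heuristic if self.indeterminate else self.preferred


def select_model(fit1: IsothermResults, fit2: IsothermResults) -> ModelSelection:
    """Choose between one-site and two-site fits of the same data by AIC.

    |dAIC| < 2 is reported indeterminate together with the
    plateau-stoichiometry heuristic (max observed r > 1.3 => two_site).
    """
    if fit1.model.data is not fit2.model.data and not (
        np.array_equal(fit1.model.data.C_free, fit2.model.data.C_free)
        and np.array_equal(fit1.model.data.r, fit2.model.data.r)
    ):
        raise ValueError("model selection requires fits of identical data")
    fits = {f.constants.model: f for f in (fit1, fit2)}
    if set(fits) != {BindingModel.ONE_SITE, BindingModel.TWO_SITE}:
        raise ValueError("need one one_site fit and one two_site fit")
    delta = fits[BindingModel.ONE_SITE].aic - fits[BindingModel.TWO_SITE].aic
    max_r = float(np.max(fit1.model.data.r))
    heuristic = (
        BindingModel.TWO_SITE if max_r > STOICHIOMETRY_HEURISTIC_R else BindingModel.ONE_SITE
    )
    if abs(delta) < 2.0:
        return ModelSelection(None, delta, True, heuristic)
    preferred = BindingModel.TWO_SITE if delta > 0 else BindingModel.ONE_SITE
    return ModelSelection(preferred, delta, False, heuristic)
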