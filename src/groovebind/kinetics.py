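"""SPR sensorgram simulation and global 1:1 kinetic fitting.

Surface plasmon resonance reports mass bound at a sensor surface in
resonance units (RU) versus time.  Under constant-flow conditions the
free analyte concentration C is held at the injected value during the
association phase and at zero during dissociation, so a 1:1 (Langmuir)
surface interaction has the closed form

    association:  R(t) = Req * (1 - exp(-(ka*C + kd)*(t - t_start))),
                  Req  = Rmax * ka*C / (ka*C + kd)
    dissociation: R(t) = R(t_stop) * exp(-kd*(t - t_stop))

A sequential 2:1 surface complex (ligand stacking as a dimer in the
minor groove) has no closed form and is integrated as an ODE system in
surface-species fractions D, DL, DL2 with D + DL + DL2 = 1:

    d[DL]/dt  = ka1*C*D - kd1*DL - ka2*C*DL + kd2*DL2
    d[DL2]/dt = ka2*C*DL - kd2*DL2
    R = Rmax1 * (DL + 2*DL2)

where Rmax1 is the response at one ligand per DNA.  The 2:1 simulator
is simulation-only (it feeds the synthetic-data generators); 2:1
systems are fitted at steady state by :mod:`groovebind.isotherm`,
because reliable 2:1 rate constants are rarely extractable from
sensorgrams that reach their plateau quickly.

Mass-transport limitation, bulk refractive-index jumps and baseline
drift are deliberately not modeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .equilibrium import StepwiseConstants, fraction_bound_two_site

__all__ = [
    "InjectionSchedule",
    "OneSiteKinetics",
    "TwoSiteKinetics",
    "Sensorgram",
    "simulate_one_site_sensorgram",
    "simulate_single_cycle",
    "simulate_two_site_sensorgram",
    "equilibrium_constant_from_rates",
    "OneSiteKineticsModel",
    "KineticsResults",
]


@dataclass(frozen=True)
class InjectionSchedule:
    """One injection cycle: association on [t_start, t_stop], dissociation to t_end."""

    t_start: float
    t_stop: float
    t_end: float
    C_inject: float  # M, constant during association (flow conditions)

    def __post_init__(self) -> None:
        if not (0 <= self.t_start < self.t_stop < self.t_end):
            raise ValueError(
                "schedule must satisfy 0 <= t_start < t_stop < t_end, got "
                f"({self.t_start}, {self.t_stop}, {self.t_end})"
            )
        if not (np.isfinite(self.C_inject) and self.C_inject >= 0):
            raise ValueError(f"C_inject must be >= 0, got {self.C_inject!r}")

    def default_grid(self, n: int = 200) -> np.ndarray:
        return np.linspace(self.t_start, self.t_end, n)


@dataclass(frozen=True)
class OneSiteKinetics:
    """1:1 surface kinetics: ka (M^-1 s^-1), kd (s^-1), Rmax (RU)."""

    ka: float
    kd: float
    Rmax: float

    def __post_init__(self) -> None:
        for name in ("ka", "kd", "Rmax"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")

    @property
    def K_A(self) -> float:
        return self.ka / self.kd

    def equilibrium(self) -> StepwiseConstants:
        return StepwiseConstants.one_site(self.K_A)


@dataclass(frozen=True)
class TwoSiteKinetics:
    """Sequential 2:1 surface kinetics; Rmax1 is the response at 1 ligand/DNA."""

    ka1: float
    ka2: float
    kd1: float
    kd2: float
    Rmax1: float

    def __post_init__(self) -> None:
        for name in ("ka1", "ka2", "kd1", "kd2", "Rmax1"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")

    @property
    def K_A1(self) -> float:
        return self.ka1 / self.kd1

    @property
    def K_A2(self) -> float:
        return self.ka2 / self.kd2

    def equilibrium(self) -> StepwiseConstants:
        return StepwiseConstants.two_site(self.K_A1, self.K_A2)


@dataclass
class Sensorgram:
    """RU-vs-time trace for one injected concentration."""

    time: np.ndarray
    response: np.ndarray
    schedule: InjectionSchedule
    label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.time.ndim != 1 or self.time.size == 0:
            raise ValueError("time grid must be a nonempty 1-D array")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.response.shape != self.time.shape:
            raise ValueError("time and response must have matching shapes")
        if np.any(~np.isfinite(self.response)):
            raise ValueError("responses must be finite")

    @property
    def concentration(self) -> float:
        return self.schedule.C_inject

    def association_mask(self) -> np.ndarray:
        return (self.time >= self.schedule.t_start) & (self.time <= self.schedule.t_stop)

    def dissociation_mask(self) -> np.ndarray:
        return self.time > self.schedule.t_stop

    def plot(self, ax=None, **kwargs):
        """Quick-look RU vs time; returns the matplotlib axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        label = kwargs.pop("label", self.label or f"{self.concentration:.3g} M")
        ax.plot(self.time, self.response, label=label, **kwargs)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("response (RU)")
        return ax


def _validated_grid(time_grid, schedule: InjectionSchedule) -> np.ndarray:
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("time grid must be a nonempty 1-D array")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    if t[0] < schedule.t_start - 1e-12 or t[-1] > schedule.t_end + 1e-12:
        raise ValueError("time grid must lie within [t_start, t_end] of the schedule")
    return t


def _one_site_response(
    params: OneSiteKinetics, schedule: InjectionSchedule, t: np.ndarray, R0: float = 0.0
) -> np.ndarray:
    """Piecewise closed form; R0 is the response carried in at t_start."""
    ka, kd, Rmax = params.ka, params.kd, params.Rmax
    C = schedule.C_inject
    kobs = ka * C + kd
    Req = Rmax * ka * C / kobs
    R = np.empty_like(t)
    assoc = t <= schedule.t_stop
    R[assoc] = Req + (R0 - Req) * np.exp(-kobs * (t[assoc] - schedule.t_start))
    R_stop = Req + (R0 - Req) * math.exp(-kobs * (schedule.t_stop - schedule.t_start))
    R[~assoc] = R_stop * np.exp(-kd * (t[~assoc] - schedule.t_stop))
    return R


def simulate_one_site_sensorgram(
    params: OneSiteKinetics,
    schedule: InjectionSchedule,
    time_grid=None,
    label: str = "",
) -> Sensorgram:
    """Noise-free 1:1 sensorgram from a regenerated (R = 0) surface."""
    if time_grid is None:
        time_grid = schedule.default_grid()
    t = _validated_grid(time_grid, schedule)
    return Sensorgram(t, _one_site_response(params, schedule, t), schedule, label)


def simulate_single_cycle(
    params: OneSiteKinetics,
    schedules: Sequence[InjectionSchedule],
    points_per_cycle: int = 200,
) -> list[Sensorgram]:
    """Successive injections without surface regeneration (single-cycle mode).

    Each cycle starts from the response the previous cycle ended with.
    Off by default everywhere else; the multi-cycle (regenerated)
    protocol is the package standard.
    """
    out: list[Sensorgram] = []
    R0 = 0.0
    for i, sched in enumerate(schedules):
        t = sched.default_grid(points_per_cycle)
        R = _one_site_response(params, sched, t, R0=R0)
        out.append(Sensorgram(t, R, sched, label=f"cycle{i}"))
        R0 = float(R[-1])
    return out


def simulate_two_site_sensorgram(
    params: TwoSiteKinetics,
    schedule: InjectionSchedule,
    time_grid=None,
    label: str = "",
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> Sensorgram:
    """Sequential 2:1 sensorgram by stiff ODE integration.

    Integrates surface fractions (DL, DL2) phase by phase (C drops to 0
    at t_stop) and converts to response R = Rmax1*(DL + 2*DL2).
    """
    if time_grid is None:
        time_grid = schedule.default_grid()
    t = _validated_grid(time_grid, schedule)

    def rhs(_t, y, C):
        dl, dl2 = y
        d = 1.0 - dl - dl2
        ddl = params.ka1 * C * d - params.kd1 * dl - params.ka2 * C * dl + params.kd2 * dl2
        ddl2 = params.ka2 * C * dl - params.kd2 * dl2
        return (ddl, ddl2)

    response = np.empty_like(t)
    y = np.array([0.0, 0.0])
    segments = [
        (schedule.t_start, schedule.t_stop, schedule.C_inject, t <= schedule.t_stop),
        (schedule.t_stop, schedule.t_end, 0.0, t > schedule.t_stop),
    ]
    for t0, t1, C, mask in segments:
        # evaluate at the grid points of this phase plus the phase endpoint,
        # so the next phase restarts from the exact state at t1
        t_eval = np.unique(np.concatenate([t[mask], [t1]]))
        sol = solve_ivp(
            rhs,
            (t0, t1),
            y,
            method="LSODA",
            t_eval=t_eval,
            args=(C,),
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(
                f"2:1 sensorgram integration failed on [{t0}, {t1}] at C={C}: {sol.message}"
            )
        lookup = {tv: i for i, tv in enumerate(sol.t)}
        idx = np.array([lookup[tv] for tv in t[mask]], dtype=int)
        if idx.size:
            dl, dl2 = sol.y[:, idx]
            response[mask] = params.Rmax1 * (dl + 2.0 * dl2)
        y = sol.y[:, -1]
    return Sensorgram(t, response, schedule, label)


def equilibrium_constant_from_rates(ka: float, kd: float) -> float:
    """K_A = ka/kd (M^-1). Kinetic and steady-state estimates of K_A
    need not agree; the package reports both and never reconciles them."""
    if not (np.isfinite(ka) and ka > 0):
        raise ValueError(f"ka must be strictly positive, got {ka!r}")
    if not (np.isfinite(kd) and kd > 0):
        raise ValueError(f"kd must be strictly positive, got {kd!r}")
    return ka / kd


class OneSiteKineticsModel:
    """Global 1:1 kinetic fit across a multi-concentration sensorgram set.

    All curves share (ka, kd, Rmax); parameters are fitted in log space
    so positivity is structural rather than enforced by bounds.  At
    least two concentrations are required — from a single curve Rmax
    and ka are not separable at typical C.

    Parameters
    ----------
    sensorgrams : sequence of Sensorgram
        One trace per injected concentration, each from a regenerated
        surface.

    Examples
    --------
    >>> model = OneSiteKineticsModel(curves)      # doctest: +SKIP
    >>> res = model.fit()                         # doctest: +SKIP
    >>> print(res.summary())                      # doctest: +SKIP
    """

    def __init__(self, sensorgrams: Iterable[Sensorgram]):
        self.sensorgrams = list(sensorgrams)
        if not self.sensorgrams:
            raise ValueError("at least one sensorgram is required")
        self._dissociation_only = all(
            sg.schedule.C_inject == 0 or not np.any(sg.association_mask())
            for sg in self.sensorgrams
        )
        if not self._dissociation_only and len(self.sensorgrams) < 2:
            raise ValueError(
                "global 1:1 kinetic fitting needs >= 2 concentrations "
                "(Rmax and ka are not separable from one curve)"
            )

    # -- residuals -------------------------------------------------------
    def _predict(self, params: OneSiteKinetics, sg: Sensorgram) -> np.ndarray:
        return _one_site_response(params, sg.schedule, sg.time)

    def _residuals(self, log_theta: np.ndarray) -> np.ndarray:
        params = OneSiteKinetics(*np.exp(log_theta))
        return np.concatenate(
            [self._predict(params, sg) - sg.response for sg in self.sensorgrams]
        )

    def _default_init(self) -> OneSiteKinetics:
        rmax0 = max(float(np.max(sg.response)) for sg in self.sensorgrams)
        rmax0 = max(rmax0, 1e-6)
        # crude kd from the tail decade of the largest-response curve
        sg = max(self.sensorgrams, key=lambda s: float(np.max(s.response)))
        kd0 = 1.0 / max(sg.schedule.t_end - sg.schedule.t_stop, 1.0)
        cmax = max(sg.schedule.C_inject for sg in self.sensorgrams)
        ka0 = 1.0 / max(cmax, 1e-12) * kd0  # start at K_A*C ~ 1
        return OneSiteKinetics(ka=ka0, kd=kd0, Rmax=rmax0)

    def fit(self, init: OneSiteKinetics | None = None) -> "KineticsResults":
        if self._dissociation_only:
            return self._fit_dissociation_only()
        theta0 = init or self._default_init()
        x0 = np.log([theta0.ka, theta0.kd, theta0.Rmax])
        sol = least_squares(self._residuals, x0, method="lm", xtol=1e-14, ftol=1e-14)
        params = OneSiteKinetics(*np.exp(sol.x))
        n_obs = sum(sg.time.size for sg in self.sensorgrams)
        dof = max(n_obs - 3, 1)
        rss = float(2.0 * sol.cost)
        # delta method: se on the natural scale from the log-scale covariance
        try:
            JTJ = sol.jac.T @ sol.jac
            cov_log = np.linalg.inv(JTJ) * rss / dof
            se = np.sqrt(np.diag(cov_log)) * np.exp(sol.x)
            bse = dict(zip(("ka", "kd", "Rmax"), se))
        except np.linalg.LinAlgError:
            bse = {k: float("nan") for k in ("ka", "kd", "Rmax")}
        per_curve = {
            sg.label
            or f"{sg.concentration:.3g} M": float(
                np.sqrt(np.mean((self._predict(params, sg) - sg.response) ** 2))
            )
            for sg in self.sensorgrams
        }
        return KineticsResults(
            model=self,
            params=params,
            bse=bse,
            rss=rss,
            n_obs=n_obs,
            per_curve_rms=per_curve,
            converged=bool(sol.success),
            unidentifiable=frozenset(),
            message=str(sol.message),
        )

    def _fit_dissociation_only(self) -> "KineticsResults":
        """kd from exponential decays; ka and Rmax flagged unidentifiable."""
        curves = [sg for sg in self.sensorgrams if np.any(sg.dissociation_mask())]
        if not curves:
            raise ValueError("no dissociation-phase data present")

        def resid(x):
            log_kd = x[0]
            out = []
            for i, sg in enumerate(curves):
                m = sg.dissociation_mask()
                r0 = np.exp(x[1 + i])
                out.append(
                    r0 * np.exp(-np.exp(log_kd) * (sg.time[m] - sg.schedule.t_stop))
                    - sg.response[m]
                )
            return np.concatenate(out)

        x0 = np.concatenate(
            [[np.log(0.01)], [np.log(max(sg.response.max(), 1e-6)) for sg in curves]]
        )
        sol = least_squares(resid, x0, method="lm", xtol=1e-14, ftol=1e-14)
        kd = float(np.exp(sol.x[0]))
        n_obs = sum(int(np.count_nonzero(sg.dissociation_mask())) for sg in curves)
        rss = float(2.0 * sol.cost)
        dof = max(n_obs - len(sol.x), 1)
        try:
            cov = np.linalg.inv(sol.jac.T @ sol.jac) * rss / dof
            kd_se = float(np.sqrt(cov[0, 0]) * kd)
        except np.linalg.LinAlgError:
            kd_se = float("nan")
        return KineticsResults(
            model=self,
            params=OneSiteKinetics(ka=1.0, kd=kd, Rmax=1.0),
            bse={"ka": float("nan"), "kd": kd_se, "Rmax": float("nan")},
            rss=rss,
            n_obs=n_obs,
            per_curve_rms={},
            converged=bool(sol.success),
            unidentifiable=frozenset({"ka", "Rmax"}),
            message="dissociation-phase-only data: ka and Rmax are structurally "
            "unidentifiable; kd fitted from the decay",
        )


@dataclass
class KineticsResults:
    """Fitted 1:1 kinetics with uncertainties and residual diagnostics."""

    model: OneSiteKineticsModel
    params: OneSiteKinetics
    bse: dict
    rss: float
    n_obs: int
    per_curve_rms: dict
    converged: bool
    unidentifiable: frozenset = field(default_factory=frozenset)
    message: str = ""

    @property
    def K_A(self) -> float:
        """Kinetically derived equilibrium constant ka/kd (M^-1)."""
        if "ka" in self.unidentifiable:
            return float("nan")
        return equilibrium_constant_from_rates(self.params.ka, self.params.kd)

    def summary(self) -> str:
        lines = [
            "Global 1:1 kinetic fit",
            "=" * 46,
            f"curves: {len(self.model.sensorgrams)}   observations: {self.n_obs}",
            f"converged: {self.converged}",
            f"{'param':<8}{'estimate':>14}{'std err':>14}",
        ]
        for name in ("ka", "kd", "Rmax"):
            if name in self.unidentifiable:
                lines.append(f"{name:<8}{'unidentifiable':>14}{'-':>14}")
            else:
                lines.append(
                    f"{name:<8}{getattr(self.params, name):>14.5g}{self.bse[name]:>14.3g}"
                )
        if "ka" not in self.unidentifiable:
            lines.append(f"K_A = ka/kd = {self.K_A:.4g} M^-1")
        lines.append(f"residual RSS = {self.rss:.6g} RU^2")
        for label, rms in self.per_curve_rms.items():
            lines.append(f"  rms[{label}] = {rms:.4g} RU")
        if self.message:
            lines.append(f"note: {self.message}")
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Overlay data and fitted curves."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for sg in self.model.sensorgrams:
            ax.plot(sg.time, sg.response, ".", ms=2)
            ax.plot(sg.time, self.model._predict(self.params, sg), "-", lw=1)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("response (RU)")
        return ax


def two_site_plateau(params: TwoSiteKinetics, C: float) -> float:
    """Equilibrium plateau of the 2:1 simulator at constant C (RU)."""
    return params.Rmax1 * fraction_bound_two_site(params.K_A1, params.K_A2, C)
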