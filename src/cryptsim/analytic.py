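"""Tissue-scale analytic models of postnatal intestinal surface growth.

Two coarse-grained descriptions of the growing intestinal surface are
implemented here, complementing the individual cell-based simulator:

1. An exponentially decaying surface growth law,

       dA/dt = r_G * exp(-t / tau_G) * A,

   whose closed-form solution is

       A(t) = A_0 * exp(r_G * tau_G * (1 - exp(-t / tau_G))).

   The total fold-expansion is exp(r_G * tau_G); for the mouse small
   intestine the surface increases roughly five-fold after birth, placing
   r_G in the range 1-2 per week for tau_G of one to two weeks.  If the
   crypt density n_C = N_C / A is held constant, the crypt fission
   activity required to keep up with surface growth is n_C * dA/dt, which
   peaks at t_mf = tau_G * ln(r_G * tau_G).

2. A crypt-density-controlled fission model in which the fission rate
   saturates as the density approaches its equilibrium value n_CE:

       dN_C/dt = r_M * (1 - n_C / n_CE) * N_C,
       dA/dt   = r_C * N_C * exp(-t / tau_G),

   i.e. surface production is carried by the crypts themselves (r_C is
   the surface production rate per crypt) while fission is throttled by
   crowding.  The instantaneous fission rate c = r_M * (1 - n_C/n_CE)
   equals the inverse stem-cell doubling time, t_d = ln(2) / c.

All times are in weeks, areas in arbitrary area units, and rates in
per-week units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AnalyticParams",
    "SurfaceTrajectory",
    "surface_area",
    "max_fission_time",
    "constant_density_fission_activity",
    "density_controlled_trajectory",
    "fit_growth_law",
]


@dataclass(frozen=True)
class AnalyticParams:
    """Parameters of the analytic growth models.

    Attributes
    ----------
    A_0 : float
        Initial surface area (area units, > 0).
    r_G : float
        Initial surface growth rate (per week).
    tau_G : float
        Decay constant of growth (weeks).
    r_M : float
        Maximum crypt fission rate (per week).
    r_C : float
        Surface production rate per crypt (area per crypt per week).
    n_CE : float
        Equilibrium crypt density (crypts per area unit).
    N_C0 : float
        Initial crypt count (> 0).
    """

    A_0: float = 1.0
    r_G: float = 1.609  # ~ln(5), five-fold total expansion at tau_G = 1 wk
    tau_G: float = 2.0
    r_M: float = 5.0
    r_C: float = 1.0
    n_CE: float = 1.0
    N_C0: float = 100.0

    def __post_init__(self) -> None:
        for name in ("A_0", "r_G", "tau_G", "r_M", "r_C", "n_CE", "N_C0"):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass
class SurfaceTrajectory:
    """Time course of the coupled surface-area / crypt-count system.

    ``n_C`` is the crypt density ``N_C / A`` pointwise, ``c`` the
    instantaneous fission rate and ``t_d_analytic = ln(2)/c`` the implied
    stem-cell doubling time (``inf`` where ``c <= 0``).
    """

    times: np.ndarray
    A: np.ndarray
    N_C: np.ndarray
    n_C: np.ndarray = field(default=None)  # type: ignore[assignment]
    c: np.ndarray = field(default=None)  # type: ignore[assignment]
    t_d_analytic: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.N_C = np.asarray(self.N_C, dtype=float)
        if not (len(self.times) == len(self.A) == len(self.N_C)):
            raise ValueError("times, A and N_C must have equal lengths")
        if self.n_C is None:
            self.n_C = self.N_C / self.A


def surface_area(t, p: AnalyticParams):
    """Closed-form surface area A(t) of the decaying-growth law.

    Accepts a scalar or array of times (weeks, >= 0).  As ``t -> inf``
    the value approaches ``A_0 * exp(r_G * tau_G)``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    out = p.A_0 * np.exp(p.r_G * p.tau_G * (1.0 - np.exp(-t / p.tau_G)))
    return out if out.ndim else float(out)


def max_fission_time(p: AnalyticParams) -> float:
    """Time of maximum constant-density fission activity.

    Returns ``tau_G * ln(r_G * tau_G)``; when ``r_G * tau_G < 1`` the
    activity is monotonically decreasing and the maximum sits at the
    boundary t = 0.
    """
    x = p.r_G * p.tau_G
    if x < 1.0:
        return 0.0
    return p.tau_G * math.log(x)


def constant_density_fission_activity(t, p: AnalyticParams):
    """Fission activity (new crypts per week) keeping n_C constant.

    Equals ``n_C * dA/dt`` with ``n_C = N_C0 / A_0`` fixed.  Its integral
    over [0, inf) is ``N_C0 * (exp(r_G * tau_G) - 1)`` new crypts.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    out = (p.N_C0 / p.A_0) * p.r_G * np.exp(-t / p.tau_G) * surface_area(t, p)
    return out if out.ndim else float(out)


def _density_rhs(t: float, y: np.ndarray, p: AnalyticParams) -> np.ndarray:
    A, N = y
    n_c = N / A
    dA = p.r_C * N * math.exp(-t / p.tau_G)
    dN = p.r_M * (1.0 - n_c / p.n_CE) * N
    return np.array([dA, dN])


def density_controlled_trajectory(
    p: AnalyticParams,
    t_end: float,
    dt: float = 1e-3,
    n_C0: float | None = None,
) -> SurfaceTrajectory:
    """Integrate the crypt-density-controlled fission model.

    The coupled system

        dA/dt   = r_C * N_C * exp(-t/tau_G)
        dN_C/dt = r_M * (1 - n_C/n_CE) * N_C

    is integrated with a fixed-step classical Runge-Kutta (RK4) scheme
    (the system is non-stiff; a fixed step keeps results bit-reproducible).
    By default the run starts at the equilibrium density, ``n_C(0) =
    n_CE``: the density first drops while the non-epithelial layers grow,
    then reconstitutes as growth decays.  ``n_C0`` overrides the initial
    density.

    Raises ``ValueError`` for non-positive ``t_end``/``dt``.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_steps = int(round(t_end / dt))
    if n_steps < 1:
        raise ValueError("t_end shorter than one step")

    start_density = p.n_CE if n_C0 is None else float(n_C0)
    A0 = p.N_C0 / start_density
    y = np.array([A0, p.N_C0])
    times = np.empty(n_steps + 1)
    ys = np.empty((n_steps + 1, 2))
    times[0] = 0.0
    ys[0] = y
    t = 0.0
    for i in range(n_steps):
        k1 = _density_rhs(t, y, p)
        k2 = _density_rhs(t + dt / 2, y + dt / 2 * k1, p)
        k3 = _density_rhs(t + dt / 2, y + dt / 2 * k2, p)
        k4 = _density_rhs(t + dt, y + dt * k3, p)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(y)) or np.any(y <= 0):
            raise ArithmeticError(f"integration diverged at t = {t + dt:.4g} weeks")
        t += dt
        times[i + 1] = t
        ys[i + 1] = y

    A, N = ys[:, 0], ys[:, 1]
    n_c = N / A
    c = p.r_M * (1.0 - n_c / p.n_CE)
    with np.errstate(divide="ignore"):
        t_d = np.where(c > 0, math.log(2.0) / np.where(c > 0, c, 1.0), np.inf)
    return SurfaceTrajectory(times=times, A=A, N_C=N, n_C=n_c, c=c, t_d_analytic=t_d)


def fit_growth_law(times, areas, p0: tuple[float, float] = (1.5, 1.5)):
    """Least-squares fit of (r_G, tau_G) of the closed-form growth law.

    Convenience plumbing for small (time, area) tables; ``A_0`` is taken
    from the first sample.  Returns ``(r_G, tau_G)``.
    """
    from scipy.optimize import curve_fit

    times = np.asarray(times, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if times.size < 3:
        raise ValueError("need at least 3 samples to fit (r_G, tau_G)")
    A0 = areas[0]

    def model(t, r_G, tau_G):
        return A0 * np.exp(r_G * tau_G * (1.0 - np.exp(-t / tau_G)))

    popt, _ = curve_fit(model, times, areas, p0=p0, maxfev=10000)
    return float(popt[0]), float(popt[1])
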