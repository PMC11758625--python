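"""One-compartment model of serum 3-hydroxybutyrate (3-HB) after an oral dose.

The body is a single well-stirred compartment of volume ``Vd`` (L) holding
serum 3-HB at concentration ``C`` (mM).  An oral dose is placed in a
gastrointestinal depot holding amount ``X`` (mmol) and is absorbed through two
parallel pathways: a saturable, transporter-mediated route with
Michaelis-Menten kinetics (``Vmax``, ``Km_prime``) and a non-saturable
first-order route (``ka``).  Endogenous ketogenesis runs at the constant rate
``CL * C0`` so that, with linear elimination at clearance ``CL``, the system
rests at the basal concentration ``C0`` whenever the gut is empty:

    dX/dt = -Vmax * X / (Km' + X) - ka * X
    Vd * dC/dt = CL*C0 + Vmax * X / (Km' + X) + ka * X - CL * C

Units are mmol for amounts, mM for concentrations, L for volumes and minutes
for time; an oral dose in grams is converted to mmol with the molar mass of
3-hydroxybutyric acid (C4H8O3, 104.10 g/mol).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar

__all__ = [
    "MOLAR_MASS_3HB",
    "PKParameters",
    "DoseInput",
    "ModelVariant",
    "SimProfile",
    "InvalidStateError",
    "IntegrationFailureError",
    "DegenerateRateError",
    "derivatives",
    "simulate",
    "simulate_conc_at",
    "analytic_linear_profile",
    "summarize_cmax",
]

#: Molar mass of 3-hydroxybutyric acid (C4H8O3), g/mol.
MOLAR_MASS_3HB = 104.10

# Largest negative gut-amount excursion (mmol) tolerated from the integrator
# before the run is declared a failure; smaller dips are reporting noise and
# are clipped to zero in the returned profile.
_NEGATIVE_STATE_TOL = 1e-7


class InvalidStateError(ValueError):
    """Raised when a model state (X, C) is negative or non-finite."""


class IntegrationFailureError(RuntimeError):
    """Raised when the ODE solver fails or produces an unphysical trajectory."""


class DegenerateRateError(ValueError):
    """Raised when the closed-form first-order solution is indeterminate
    (absorption and elimination rate constants coincide); the caller should
    use the t*exp(-k*t) limit instead."""


@dataclass(frozen=True)
class PKParameters:
    """The six kinetic parameters of the one-compartment model.

    Attributes
    ----------
    CL : float
        Systemic clearance, L/min.
    C0 : float
        Basal (endogenous steady-state) serum concentration, mM.
    ka : float
        First-order absorption rate constant of the non-saturable
        pathway, 1/min.  ``ka = 0`` removes the pathway.
    Km_prime : float
        Michaelis constant times GI-compartment volume, mmol: the gut
        amount at which the saturable pathway runs at half speed.
    Vd : float
        Volume of distribution, L.
    Vmax : float
        Maximum rate of the saturable pathway, mmol/min.  ``Vmax = 0``
        removes the pathway.
    """

    CL: float
    C0: float
    ka: float
    Km_prime: float
    Vd: float
    Vmax: float

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.CL, self.C0, self.ka,
                                       self.Km_prime, self.Vd, self.Vmax))):
            raise ValueError("all parameters must be finite")
        if self.CL <= 0:
            raise ValueError(f"CL must be positive, got {self.CL}")
        if self.Vd <= 0:
            raise ValueError(f"Vd must be positive, got {self.Vd}")
        if self.Km_prime <= 0:
            raise ValueError(f"Km_prime must be positive, got {self.Km_prime}")
        if self.C0 < 0:
            raise ValueError(f"C0 must be non-negative, got {self.C0}")
        if self.ka < 0:
            raise ValueError(f"ka must be non-negative, got {self.ka}")
        if self.Vmax < 0:
            raise ValueError(f"Vmax must be non-negative, got {self.Vmax}")

    @property
    def production_rate(self) -> float:
        """Endogenous 3-HB production rate, mmol/min (always ``CL * C0``)."""
        return self.CL * self.C0

    @property
    def k_elim(self) -> float:
        """First-order elimination rate constant ``CL / Vd``, 1/min."""
        return self.CL / self.Vd

    def replace(self, **kwargs: float) -> "PKParameters":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {"CL": self.CL, "C0": self.C0, "ka": self.ka,
                "Km_prime": self.Km_prime, "Vd": self.Vd, "Vmax": self.Vmax}

    @classmethod
    def from_dict(cls, d: dict) -> "PKParameters":
        return cls(CL=d["CL"], C0=d["C0"], ka=d["ka"],
                   Km_prime=d["Km_prime"], Vd=d["Vd"], Vmax=d["Vmax"])


@dataclass(frozen=True)
class DoseInput:
    """An oral dose, stored in grams and converted to mmol on demand."""

    dose_grams: float
    molar_mass: float = MOLAR_MASS_3HB

    def __post_init__(self) -> None:
        if self.dose_grams < 0:
            raise ValueError(f"dose must be non-negative, got {self.dose_grams} g")
        if self.molar_mass <= 0:
            raise ValueError("molar mass must be positive")

    @property
    def dose_mmol(self) -> float:
        """Amount placed in the GI compartment at t = 0, mmol."""
        return 1000.0 * self.dose_grams / self.molar_mass


class ModelVariant(str, enum.Enum):
    """Which absorption pathways the model includes."""

    FULL = "full"
    NONSATURABLE_ONLY = "nonsaturable_only"
    SATURABLE_ONLY = "saturable_only"

    def mask(self, params: PKParameters) -> PKParameters:
        """Return ``params`` with the removed pathway's rate forced to zero."""
        if self is ModelVariant.NONSATURABLE_ONLY:
            return params.replace(Vmax=0.0)
        if self is ModelVariant.SATURABLE_ONLY:
            return params.replace(ka=0.0)
        return params

    @property
    def free_parameters(self) -> tuple[str, ...]:
        """Names of the kinetic parameters this variant estimates."""
        if self is ModelVariant.NONSATURABLE_ONLY:
            return ("CL", "C0", "ka", "Vd")
        if self is ModelVariant.SATURABLE_ONLY:
            return ("CL", "C0", "Km_prime", "Vd", "Vmax")
        return ("CL", "C0", "ka", "Km_prime", "Vd", "Vmax")


@dataclass
class SimProfile:
    """A simulated trajectory: gut amount X(t) (mmol) and serum C(t) (mM)."""

    times: np.ndarray
    gut_amount: np.ndarray
    conc: np.ndarray
    # continuous interpolant from the solver, used for Cmax/Tmax refinement
    interpolant: Callable[[float], np.ndarray] | None = field(
        default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.gut_amount = np.asarray(self.gut_amount, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.times.size == 0:
            raise ValueError("profile must contain at least one timepoint")
        if self.times[0] != 0.0:
            raise ValueError("profile must start at t = 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


def _rhs(t: float, y: np.ndarray, CL: float, C0: float, ka: float,
         Km: float, Vd: float, Vmax: float) -> list[float]:
    # X may dip infinitesimally below 0 inside the solver; guard the MM term.
    X, C = y
    Xp = X if X > 0.0 else 0.0
    absorbed = Vmax * Xp / (Km + Xp) + ka * Xp
    return [-absorbed, (CL * C0 + absorbed - CL * C) / Vd]


def derivatives(state: tuple[float, float], params: PKParameters,
                variant: ModelVariant = ModelVariant.FULL) -> tuple[float, float]:
    """Time derivatives (dX/dt, dC/dt) of the mass-balance equations.

    ``state`` is the pair (gut amount X in mmol, serum concentration C
    in mM).  Raises :class:`InvalidStateError` for negative or non-finite
    states.
    """
    X, C = state
    if not (math.isfinite(X) and math.isfinite(C)):
        raise InvalidStateError(f"non-finite state ({X}, {C})")
    if X < 0:
        raise InvalidStateError(f"negative gut amount X = {X} mmol")
    p = variant.mask(params)
    saturable = p.Vmax * X / (p.Km_prime + X)
    dX = -saturable - p.ka * X
    dC = (p.CL * p.C0 + saturable + p.ka * X - p.CL * C) / p.Vd
    return dX, dC


def simulate(params: PKParameters, dose: DoseInput, t_end: float = 240.0,
             variant: ModelVariant = ModelVariant.FULL,
             grid_step: float = 0.1, rtol: float = 1e-8,
             atol: float = 1e-10) -> SimProfile:
    """Integrate the model from (X, C)(0) = (dose_mmol, C0) to ``t_end`` min.

    Uses an adaptive solver with automatic stiffness switching (the
    Michaelis-Menten flux is mildly stiff as the gut empties) and reports
    the solution on a uniform grid of spacing ``grid_step`` minutes.  The
    continuous solver interpolant is attached to the returned profile so
    that Cmax/Tmax can be refined off-grid.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    p = variant.mask(params)
    grid = np.arange(0.0, t_end + 0.5 * grid_step, grid_step)
    if grid[-1] > t_end:
        grid[-1] = t_end
    sol = solve_ivp(
        _rhs, (0.0, t_end), [dose.dose_mmol, p.C0],
        method="LSODA", t_eval=grid, dense_output=True,
        rtol=rtol, atol=atol,
        args=(p.CL, p.C0, p.ka, p.Km_prime, p.Vd, p.Vmax),
    )
    if not sol.success:
        raise IntegrationFailureError(
            f"ODE solver failed at dose {dose.dose_grams} g: {sol.message}")
    X, C = sol.y
    if X.min() < -_NEGATIVE_STATE_TOL or C.min() < -_NEGATIVE_STATE_TOL:
        raise IntegrationFailureError(
            f"unphysical negative excursion (min X = {X.min():.3e} mmol, "
            f"min C = {C.min():.3e} mM)")
    return SimProfile(times=sol.t, gut_amount=np.clip(X, 0.0, None),
                      conc=np.clip(C, 0.0, None), interpolant=sol.sol)


def simulate_conc_at(params: PKParameters, dose: DoseInput,
                     times: Sequence[float],
                     variant: ModelVariant = ModelVariant.FULL,
                     rtol: float = 1e-8, atol: float = 1e-10) -> np.ndarray:
    """Serum concentration at the requested times only (fast path for fitting)."""
    times = np.asarray(times, dtype=float)
    p = variant.mask(params)
    sol = solve_ivp(
        _rhs, (0.0, float(times[-1])), [dose.dose_mmol, p.C0],
        method="LSODA", t_eval=times, rtol=rtol, atol=atol,
        args=(p.CL, p.C0, p.ka, p.Km_prime, p.Vd, p.Vmax),
    )
    if not sol.success:
        raise IntegrationFailureError(
            f"ODE solver failed at dose {dose.dose_grams} g: {sol.message}")
    return np.clip(sol.y[1], 0.0, None)


def analytic_linear_profile(params: PKParameters, dose: DoseInput,
                            t: float | np.ndarray) -> float | np.ndarray:
    """Closed-form concentration when only first-order absorption acts.

    With ``Vmax = 0`` the model is linear and superposition applies: the
    dose contributes a Bateman term on top of the constant baseline,

        C(t) = C0 + ka * D / (Vd * (ka - k)) * (exp(-k t) - exp(-ka t)),

    with ``k = CL / Vd`` and ``D`` the dose in mmol.  Serves as the exact
    oracle for the numerical integrator in the linear limit.
    """
    if params.Vmax != 0:
        raise ValueError("closed form requires Vmax = 0 (first-order limit)")
    k = params.k_elim
    ka = params.ka
    if abs(ka - k) < 1e-12:
        raise DegenerateRateError(
            "ka equals CL/Vd; the Bateman form is indeterminate — use the "
            "limit C0 + ka*D*t*exp(-k*t)/Vd instead")
    t = np.asarray(t, dtype=float)
    bateman = (ka * dose.dose_mmol / (params.Vd * (ka - k))
               * (np.exp(-k * t) - np.exp(-ka * t)))
    out = params.C0 + bateman
    return float(out) if out.ndim == 0 else out


def summarize_cmax(profile: SimProfile) -> tuple[float, float]:
    """Peak concentration and its time, ``(Cmax mM, Tmax min)``.

    Takes the discrete argmax of the profile and, when the profile carries
    the solver's continuous interpolant, refines the peak by bounded scalar
    minimisation within one grid step either side.  Ties are broken to the
    earliest time, so a flat baseline profile reports Tmax = 0.
    """
    conc = profile.conc
    cmax = float(conc.max())
    i = int(np.argmax(conc >= cmax - 1e-15))  # earliest attaining the max
    tmax = float(profile.times[i])
    if profile.interpolant is None or i == 0 or i == conc.size - 1:
        return cmax, tmax
    lo, hi = profile.times[i - 1], profile.times[i + 1]
    res = minimize_scalar(lambda t: -float(profile.interpolant(t)[1]),
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-6})
    refined_c = -res.fun
    if refined_c > cmax + 1e-15:
        return float(refined_c), float(res.x)
    return cmax, tmax
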