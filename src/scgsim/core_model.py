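"""Force-balance model of an actin-filled membrane protrusion.

A stereocilium (or microvillus) is modelled as a cylindrical actin bundle
that treadmills: actin polymerizes at the tip with rate ``A(h)``, flows
rearward, and is severed at the rootlet with effective rate ``beta``.  The
rearward flux drags the rootlet through the viscous cuticular plate
(effective viscosity coefficient ``gamma_c``), which produces the pushing
force that elongates the protrusion.  Growth is opposed by actin-membrane
myosin connectors distributed along the length (restoring force
``alpha * nu * h``) and by a constant membrane-bending term ``f_md0``.

Height dynamics follow

    dh/dt = [gamma_c * Sc(h) * A(h) - alpha*nu*h - f_md0]
            / (gamma_c * Sc(h) + mu)

with the rootlet drag area closed as

    Sc(h) = c_S * R_tip(h) * (A/beta) / (1 + (A/beta)^2),

a closure chosen so that for a height-independent polymerization rate the
fixed point of the dynamics coincides exactly with the closed-form
steady-state height

    h_st = (gamma_c / (alpha*nu)) * c_S * R_tip * A * (A/beta)
           / (1 + (A/beta)^2).

In the severing-dominated regime (beta >> A) this reduces to the rootlet
drag scaling h_st ~ A^2 / beta.

The tip radius is described by a parametric steady-state family

    R_st(h, A) = r_ref * (1 - h_min/h)^q * (A/a_ref)^(-s)   for h >= h_min
    R_st(h, A) = 0                                          for h <  h_min

which captures the qualitative behaviour of dynamically regulated tip
complexes: a minimal height below which no stable tip complex (and hence no
bundle) exists, and a radius that shrinks (s > 0) or grows (s < 0) with
increasing polymerization rate.

All quantities are in nondimensional model units; see ``docs/methods.md``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple, Union

import numpy as np
from scipy.integrate import solve_ivp

logger = logging.getLogger("scgsim")

#: default tolerances of the adaptive height integrator
ODE_RTOL = 1e-8
ODE_ATOL = 1e-10

POLYM_FAMILIES = ("constant", "promoter_sum", "sigmoid", "sharp_sigmoid")

ArrayLike = Union[float, np.ndarray]


class ModelDomainError(ValueError):
    """An argument lies outside the physical domain of the model."""


class ModelInternalError(RuntimeError):
    """An internal consistency guard failed (should not happen for valid params)."""


class IntegrationError(RuntimeError):
    """The height ODE integrator failed to produce a trajectory."""


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ModelDomainError(f"{name} must be finite, got {value!r}")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Promoter:
    """One species of actin-polymerization promoter transported to the tip.

    Its contribution to A(h) is a Hill term
    ``amplitude * (h/h_sat)^steepness / (1 + (h/h_sat)^steepness)`` that
    saturates at ``amplitude`` for heights well above ``h_sat``.
    """

    amplitude: float
    h_sat: float
    steepness: float

    def __post_init__(self) -> None:
        for name in ("amplitude", "h_sat", "steepness"):
            _require_finite(name, getattr(self, name))
        if self.amplitude < 0:
            raise ModelDomainError("promoter amplitude must be >= 0")
        if self.h_sat <= 0:
            raise ModelDomainError("promoter saturation height h_sat must be > 0")
        if self.steepness < 1:
            raise ModelDomainError("promoter steepness must be >= 1")


@dataclass(frozen=True)
class PolymerizationModel:
    """Functional family for the tip polymerization rate A(h).

    families
        ``constant``      A(h) = a0
        ``promoter_sum``  a0 plus a sum of saturating promoter terms with
                          distinct saturation heights (the mechanism behind
                          multi-stability in a spatially uniform cell)
        ``sigmoid``       a0 + a1 * h^m / (h^m + h_half^m), the
                          height-polymerization positive feedback carried by
                          tip-transported promoters (e.g. Eps8/whirlin via
                          myosin-XV)
        ``sharp_sigmoid`` same form with a large Hill exponent m; produces
                          the tall-first-row phenotype
    """

    family: str
    a0: float = 0.0
    promoters: Tuple[Promoter, ...] = ()
    a1: float = 0.0
    h_half: float = 1.0
    m: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in POLYM_FAMILIES:
            raise ModelDomainError(
                f"unknown polymerization family {self.family!r}; "
                f"expected one of {POLYM_FAMILIES}"
            )
        for name in ("a0", "a1", "h_half", "m"):
            _require_finite(name, getattr(self, name))
        if self.a0 < 0:
            raise ModelDomainError("basal rate a0 must be >= 0")
        if self.family == "promoter_sum":
            object.__setattr__(self, "promoters", tuple(self.promoters))
        if self.family in ("sigmoid", "sharp_sigmoid"):
            if self.a1 < 0:
                raise ModelDomainError("feedback amplitude a1 must be >= 0")
            if self.h_half <= 0:
                raise ModelDomainError("h_half must be > 0")
            if self.m < 1:
                raise ModelDomainError("Hill exponent m must be >= 1")

    @property
    def a_max(self) -> float:
        """Upper bound of A(h) over h >= 0 (the plateau value)."""
        if self.family == "constant":
            return self.a0
        if self.family == "promoter_sum":
            return self.a0 + sum(p.amplitude for p in self.promoters)
        return self.a0 + self.a1


@dataclass(frozen=True)
class TipRadiusModel:
    """Parametric steady-state tip-complex radius R_st(h, A).

    ``h_min`` is the minimal height below which a stable tip complex cannot
    be maintained and the radius falls to zero.  Above it the radius rises
    with height as ``(1 - h_min/h)^q`` toward the reference radius ``r_ref``
    and responds to the polymerization rate as ``(A/a_ref)^(-s)``: for
    ``s > 0`` faster-polymerizing (taller) protrusions are thinner, for
    ``s < 0`` thicker, for ``s = 0`` the radius is rate-independent.
    """

    h_min: float
    r_ref: float
    a_ref: float
    s: float = 0.5
    q: float = 0.5

    def __post_init__(self) -> None:
        for name in ("h_min", "r_ref", "a_ref", "s", "q"):
            _require_finite(name, getattr(self, name))
        if self.h_min < 0:
            raise ModelDomainError("h_min must be >= 0")
        if self.r_ref <= 0:
            raise ModelDomainError("r_ref must be > 0")
        if self.a_ref <= 0:
            raise ModelDomainError("a_ref must be > 0")
        if self.q <= 0:
            raise ModelDomainError("onset exponent q must be > 0")


@dataclass(frozen=True)
class ProtrusionParams:
    """All physical coefficients for one protrusion site.

    gamma_c  effective cuticular-plate (cytoplasm) viscosity coefficient, > 0
    alpha    restoring force per actin-membrane myosin connector, > 0
    nu       connector line density along the protrusion, > 0
    mu       membrane-cytoplasm friction coefficient, >= 0
    f_md0    constant membrane-bending restoring force, >= 0
    beta     effective severing rate at the rootlet, > 0
    c_s      rootlet-area calibration length (nondimensional default 1)
    """

    gamma_c: float
    alpha: float
    nu: float
    mu: float
    f_md0: float
    beta: float
    polym: PolymerizationModel
    tip: TipRadiusModel
    c_s: float = 1.0

    def __post_init__(self) -> None:
        for name in ("gamma_c", "alpha", "nu", "mu", "f_md0", "beta", "c_s"):
            _require_finite(name, getattr(self, name))
        if self.gamma_c <= 0:
            raise ModelDomainError("gamma_c must be > 0")
        if self.alpha <= 0:
            raise ModelDomainError("alpha must be > 0")
        if self.nu <= 0:
            raise ModelDomainError("nu must be > 0")
        if self.mu < 0:
            raise ModelDomainError("mu must be >= 0")
        if self.f_md0 < 0:
            raise ModelDomainError("f_md0 must be >= 0")
        if self.beta <= 0:
            raise ModelDomainError("beta must be > 0 (it appears in a denominator)")
        if self.c_s <= 0:
            raise ModelDomainError("c_s must be > 0")


@dataclass(frozen=True)
class Trajectory:
    """A height trajectory h(t) from the integrator."""

    times: np.ndarray
    heights: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        heights = np.asarray(self.heights, dtype=float)
        if times.shape != heights.shape:
            raise ModelDomainError("times and heights must have equal length")
        if times.size and np.any(np.diff(times) <= 0):
            raise ModelDomainError("times must be strictly increasing")
        if heights.size and np.any(heights < 0):
            raise ModelDomainError("heights must be non-negative")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "heights", heights)


def with_param(p: ProtrusionParams, name: str, value: float) -> ProtrusionParams:
    """Return a copy of ``p`` with one scalar model parameter replaced.

    ``name`` is one of ``gamma_c``, ``a0`` (basal polymerization rate) or
    ``beta`` — the three parameters the apical-surface gradient can target.
    """
    if name == "gamma_c":
        return replace(p, gamma_c=value)
    if name == "beta":
        return replace(p, beta=value)
    if name == "a0":
        return replace(p, polym=replace(p.polym, a0=value))
    raise ModelDomainError(
        f"unknown parameter {name!r}; expected 'gamma_c', 'a0' or 'beta'"
    )


# ---------------------------------------------------------------------------
# elementary evaluations
# ---------------------------------------------------------------------------

def eval_polymerization_rate(pm: PolymerizationModel, h: ArrayLike) -> ArrayLike:
    """Evaluate the tip polymerization rate A(h).

    Accepts scalar or array heights; negative heights are a domain error.
    """
    h_arr = np.asarray(h, dtype=float)
    if np.any(h_arr < 0):
        raise ModelDomainError("height must be >= 0")
    if pm.family == "constant":
        out = np.full_like(h_arr, pm.a0)
    elif pm.family == "promoter_sum":
        out = np.full_like(h_arr, pm.a0)
        for promoter in pm.promoters:
            x = (h_arr / promoter.h_sat) ** promoter.steepness
            out = out + promoter.amplitude * x / (1.0 + x)
    else:  # sigmoid / sharp_sigmoid share the Hill form
        x = h_arr ** pm.m
        out = pm.a0 + pm.a1 * x / (x + pm.h_half ** pm.m)
    return float(out) if np.isscalar(h) or np.ndim(h) == 0 else out


def tip_radius_steady(tm: TipRadiusModel, h: ArrayLike, a: ArrayLike) -> ArrayLike:
    """Steady-state tip radius R_st(h, A).

    Zero below the minimal height ``h_min``; continuous at ``h_min``;
    non-decreasing in h at fixed A; strictly decreasing in A at fixed
    h > h_min when s > 0.
    """
    h_arr = np.asarray(h, dtype=float)
    a_arr = np.asarray(a, dtype=float)
    if np.any(h_arr < 0):
        raise ModelDomainError("height must be >= 0")
    if np.any(a_arr <= 0):
        raise ModelDomainError("polymerization rate must be > 0")
    h_safe = np.where(h_arr > 0, h_arr, 1.0)
    base = np.clip(1.0 - tm.h_min / h_safe, 0.0, None)
    onset = np.where(h_arr > tm.h_min, base ** tm.q, 0.0)
    if tm.h_min == 0:
        # degenerate limit: no minimal-height cutoff (radius vanishes only at h=0)
        onset = np.where(h_arr > 0, 1.0, 0.0)
    r = tm.r_ref * onset * (a_arr / tm.a_ref) ** (-tm.s)
    scalar = np.ndim(h) == 0 and np.ndim(a) == 0
    return float(r) if scalar else r


def _rootlet_area(p: ProtrusionParams, a: ArrayLike, r: ArrayLike) -> ArrayLike:
    """Rootlet drag area closure Sc = c_S * R_tip * (A/beta)/(1+(A/beta)^2)."""
    ratio = np.asarray(a, dtype=float) / p.beta
    return p.c_s * np.asarray(r, dtype=float) * ratio / (1.0 + ratio ** 2)


def rootlet_area(
    p: ProtrusionParams, h: ArrayLike, r_override: Optional[float] = None
) -> ArrayLike:
    """Rootlet surface area Sc(h) with the tip radius slaved (or overridden)."""
    a = eval_polymerization_rate(p.polym, h)
    r = r_override if r_override is not None else tip_radius_steady(p.tip, h, a)
    out = _rootlet_area(p, a, r)
    return float(out) if np.ndim(h) == 0 else out


def pushing_force(
    p: ProtrusionParams,
    h: ArrayLike,
    r_override: Optional[float] = None,
    r_floor: float = 0.0,
) -> ArrayLike:
    """Treadmilling pushing force gamma_c * Sc(h) * A(h).

    ``r_override`` fixes the tip radius (force-balance analysis at given
    width); otherwise the radius is slaved to the steady-state tip model.
    ``r_floor`` imposes a lower bound on the radius (used to emulate a
    nascent microvillus seed during developmental growth).
    """
    a = eval_polymerization_rate(p.polym, h)
    if r_override is not None:
        r = np.broadcast_to(np.asarray(r_override, dtype=float), np.shape(a))
        if np.ndim(a) == 0:
            r = float(r_override)
    else:
        r = tip_radius_steady(p.tip, h, a)
    r = np.maximum(r, r_floor)
    out = p.gamma_c * _rootlet_area(p, a, r) * a
    return float(out) if np.ndim(h) == 0 else out


def restoring_force(p: ProtrusionParams, h: ArrayLike) -> ArrayLike:
    """Total restoring force magnitude alpha*nu*h + f_md0.

    The linear term is the summed actin-membrane myosin connector force; the
    offset is the membrane-bending contribution.  Sign convention (opposing
    growth) is applied in :func:`height_rhs`.
    """
    h_arr = np.asarray(h, dtype=float)
    if np.any(h_arr < 0):
        raise ModelDomainError("height must be >= 0")
    out = p.alpha * p.nu * h_arr + p.f_md0
    return float(out) if np.ndim(h) == 0 else out


def net_force(
    p: ProtrusionParams,
    h: ArrayLike,
    r_override: Optional[float] = None,
    r_floor: float = 0.0,
) -> ArrayLike:
    """Pushing minus restoring force; its zeros are the height fixed points."""
    return pushing_force(p, h, r_override=r_override, r_floor=r_floor) - restoring_force(p, h)


# ---------------------------------------------------------------------------
# closed-form steady state and dynamics
# ---------------------------------------------------------------------------

def steady_state_height(
    p: ProtrusionParams, r_tip: float, a_override: Optional[float] = None
) -> float:
    """Closed-form steady-state height of a cylindrical protrusion.

        h_st = (gamma_c/(alpha*nu)) * c_S * r_tip * A * (A/beta)
               / (1 + (A/beta)^2)

    Valid for a height-independent polymerization rate; pass ``a_override``
    to evaluate at a specific rate, otherwise the model must be the
    ``constant`` family.  Returns 0 for r_tip = 0 (no bundle, no protrusion).
    """
    if r_tip < 0:
        raise ModelDomainError("r_tip must be >= 0")
    if a_override is None:
        if p.polym.family != "constant":
            raise ModelDomainError(
                "steady_state_height requires a constant polymerization rate; "
                "for height-dependent A(h) use steady_state_solver.solve_joint"
            )
        a = p.polym.a0
    else:
        if a_override <= 0:
            raise ModelDomainError("a_override must be > 0")
        a = a_override
    if r_tip == 0 or a == 0:
        return 0.0
    ratio = a / p.beta
    return (p.gamma_c / (p.alpha * p.nu)) * p.c_s * r_tip * a * ratio / (1.0 + ratio ** 2)


def height_rhs(
    p: ProtrusionParams,
    h: float,
    t: float = 0.0,
    r_override: Optional[float] = None,
    r_floor: float = 0.0,
) -> float:
    """Right-hand side of the height dynamics dh/dt.

        dh/dt = [gamma_c*Sc(h)*A(h) - alpha*nu*h - f_md0]
                / (gamma_c*Sc(h) + mu)

    Restoring terms oppose growth (enter with negative sign); fixed points
    coincide with :func:`steady_state_height` for constant A and f_md0 = 0.
    """
    del t  # autonomous dynamics; signature matches ODE conventions
    if h < 0:
        raise ModelDomainError("height must be >= 0")
    a = eval_polymerization_rate(p.polym, h)
    if r_override is not None:
        r = float(r_override)
    else:
        r = tip_radius_steady(p.tip, h, a)
    r = max(r, r_floor)
    sc = _rootlet_area(p, a, r)
    denom = p.gamma_c * sc + p.mu
    if denom <= 0:
        raise ModelInternalError(
            "non-positive drag denominator gamma_c*Sc + mu; for a protrusion "
            "below h_min with no radius floor, set mu > 0"
        )
    return (p.gamma_c * sc * a - p.alpha * p.nu * h - p.f_md0) / denom


def integrate_height(
    p: ProtrusionParams,
    h0: float,
    t_end: float,
    dt_out: float,
    r_override: Optional[float] = None,
    r_floor: float = 0.0,
) -> Trajectory:
    """Integrate the height dynamics from ``h0`` to ``t_end``.

    Heights are clamped at zero from below (a fully resorbed protrusion
    stays resorbed).  Uses an adaptive stiff-capable integrator at
    rtol=1e-8 / atol=1e-10.
    """
    if h0 < 0:
        raise ModelDomainError("h0 must be >= 0")
    if t_end <= 0:
        raise ModelDomainError("t_end must be > 0")
    if dt_out <= 0:
        raise ModelDomainError("dt_out must be > 0")

    def rhs(t: float, y: np.ndarray) -> list:
        h = max(float(y[0]), 0.0)
        v = height_rhs(p, h, t, r_override=r_override, r_floor=r_floor)
        if h <= 0.0 and v < 0.0:
            return [0.0]
        return [v]

    t_eval = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    t_eval = t_eval[t_eval <= t_end]
    if t_eval[-1] < t_end:
        t_eval = np.append(t_eval, t_end)
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        [h0],
        method="LSODA",
        t_eval=t_eval,
        rtol=ODE_RTOL,
        atol=ODE_ATOL,
    )
    if not sol.success:
        raise IntegrationError(
            f"height integration failed ({sol.message}) for params {p!r}, "
            f"h0={h0}, r_override={r_override}"
        )
    return Trajectory(times=sol.t, heights=np.clip(sol.y[0], 0.0, None))
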