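"""Steady-state finding, stability classification and existence detection.

Two layers of fixed-point problems arise:

* at a *fixed* tip radius, the force balance ``F_push(h) = F_restore(h)``
  may have several roots when A(h) is height-dependent (multi-stability in
  a spatially uniform cell);
* the *joint* problem couples height and radius: the radius must equal the
  steady-state tip-complex radius at the achieved height,
  ``r = R_st(h, A(h))``, while the height satisfies the force balance at
  that radius.  When the two curves do not intersect there is no stable
  protrusion at all — the microvilli-free outcome.

Roots are located by a uniform scan plus bracketed bisection; stability is
classified by the sign of the net-force derivative at the root (negative
slope = stable).  The joint problem is solved by a damped alternating
iteration from a ladder of seeds, backed by a dense scan of the
radius-slaved net force which guarantees no branch is missed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .core_model import (
    ModelDomainError,
    ModelInternalError,
    ProtrusionParams,
    eval_polymerization_rate,
    net_force,
    tip_radius_steady,
    with_param,
)

logger = logging.getLogger("scgsim")

DEFAULT_N_SCAN = 2000
#: damping factor of the alternating height<->radius iteration
JOINT_DAMPING = 0.5
JOINT_MAX_ITER = 200
#: relative residual at which the joint iteration is declared converged
JOINT_RTOL = 1e-8
#: distinct solutions closer than this (relative in h) are merged
DEDUP_RTOL = 1e-6
SWEEPABLE_PARAMS = ("gamma_c", "a0", "beta")


@dataclass(frozen=True)
class SteadyState:
    """A jointly consistent (height, radius) steady state with stability flag."""

    h: float
    r: float
    stable: bool
    residual: float


class SolverError(RuntimeError):
    """Root finding or fixed-point iteration failed irrecoverably."""


# ---------------------------------------------------------------------------
# problem scaling
# ---------------------------------------------------------------------------

def _radius_bound(p: ProtrusionParams) -> float:
    """Upper bound of the slaved tip radius over all heights."""
    tm = p.tip
    a_lo = max(p.polym.a0, 1e-12)
    a_hi = max(p.polym.a_max, a_lo)
    # R_st is monotone in A with sign -s, so the extreme is at a_lo or a_hi
    return tm.r_ref * max((a_lo / tm.a_ref) ** (-tm.s), (a_hi / tm.a_ref) ** (-tm.s))


def default_h_max(p: ProtrusionParams, r_tip: Optional[float] = None) -> float:
    """Default scan ceiling for root searches.

    Any force-balance root satisfies alpha*nu*h <= max pushing force, and
    the pushing force is bounded because x/(1+x^2) <= 1/2 and both A and
    the radius are bounded.  The ceiling is twice that bound, and at least
    10x every characteristic height of the configuration, so all roots lie
    strictly inside the scanned interval.
    """
    r_bound = _radius_bound(p) if r_tip is None else r_tip
    a_max = max(p.polym.a_max, 1e-12)
    push_bound = p.gamma_c * p.c_s * r_bound * a_max * 0.5
    h_bound = 2.0 * push_bound / (p.alpha * p.nu)
    scales = [p.tip.h_min]
    pm = p.polym
    if pm.family in ("sigmoid", "sharp_sigmoid"):
        scales.append(pm.h_half)
    if pm.family == "promoter_sum":
        scales.extend(pr.h_sat for pr in pm.promoters)
    char = 10.0 * max(scales) if any(s > 0 for s in scales) else 0.0
    out = max(h_bound, char, 1e-9)
    if not math.isfinite(out):
        raise SolverError(f"non-finite h_max bound for params {p!r}")
    return out


# ---------------------------------------------------------------------------
# force balance at fixed tip radius
# ---------------------------------------------------------------------------

def _scan_roots(
    f: Callable[[np.ndarray], np.ndarray], h_lo: float, h_max: float, n_scan: int
) -> List[float]:
    """Locate all sign changes of ``f`` on [h_lo, h_max] by scan + bisection."""
    grid = np.linspace(h_lo, h_max, n_scan)
    vals = np.asarray(f(grid), dtype=float)
    if not np.all(np.isfinite(vals)):
        raise SolverError("non-finite force values encountered during root scan")
    roots: List[float] = []
    scalar_f = lambda x: float(f(np.asarray([x]))[0])  # noqa: E731
    for i in range(len(grid) - 1):
        lo, hi = vals[i], vals[i + 1]
        if lo == 0.0:
            roots.append(float(grid[i]))
        elif lo * hi < 0.0:
            roots.append(
                float(brentq(scalar_f, grid[i], grid[i + 1], xtol=1e-10 * h_max))
            )
    if vals[-1] == 0.0:
        roots.append(float(grid[-1]))
    return roots


def _classify(
    f: Callable[[np.ndarray], np.ndarray], h: float, h_max: float
) -> bool:
    """Stability from the local slope of the net force (negative = stable)."""
    step = max(1e-6 * h_max, 1e-12)
    lo = h - step
    if lo < 0:  # boundary root: one-sided derivative
        lo = h
    vals = np.asarray(f(np.asarray([lo, h + step])), dtype=float)
    return bool(vals[1] - vals[0] < 0.0)


def find_force_balance_roots(
    p: ProtrusionParams,
    r_tip: float,
    h_max: Optional[float] = None,
    n_scan: int = DEFAULT_N_SCAN,
) -> List[SteadyState]:
    """All height fixed points at a fixed tip radius, ordered by height.

    Sign changes of ``F_push(h) - F_restore(h)`` on [0, h_max] are located
    by a uniform ``n_scan``-point scan followed by bisection to
    1e-10 * h_max.  Roots closer together than the scan spacing may be
    missed — choose ``n_scan`` to resolve the narrowest feature of A(h).
    """
    if r_tip < 0:
        raise ModelDomainError("r_tip must be >= 0")
    if n_scan < 100:
        raise ModelDomainError("n_scan must be >= 100")
    if h_max is None:
        h_max = default_h_max(p, r_tip=r_tip)
    if h_max <= 0:
        raise ModelDomainError("h_max must be > 0")

    def f(h: np.ndarray) -> np.ndarray:
        return np.asarray(net_force(p, h, r_override=r_tip), dtype=float)

    roots = _scan_roots(f, 0.0, h_max, n_scan)
    out = [
        SteadyState(h=h, r=r_tip, stable=_classify(f, h, h_max), residual=float(f(np.asarray([h]))[0]))
        for h in roots
    ]
    return sorted(out, key=lambda s: s.h)


# ---------------------------------------------------------------------------
# joint height-radius problem
# ---------------------------------------------------------------------------

def _slaved_net(p: ProtrusionParams) -> Callable[[np.ndarray], np.ndarray]:
    """Net force with the radius slaved to the steady-state tip model."""

    def f(h: np.ndarray) -> np.ndarray:
        return np.asarray(net_force(p, h), dtype=float)

    return f


def _force_scale(p: ProtrusionParams, h: float) -> float:
    return max(p.alpha * p.nu * max(h, p.tip.h_min, 1e-12), p.f_md0, 1e-300)


def _default_seeds(p: ProtrusionParams, h_max: float) -> np.ndarray:
    lo = p.tip.h_min / 2.0 if p.tip.h_min > 0 else 1e-4 * h_max
    lo = max(lo, 1e-12)
    return np.geomspace(lo, h_max, 16)


def _iterate_seed(
    p: ProtrusionParams, seed: float, h_max: float, n_scan: int
) -> Optional[float]:
    """Damped alternating iteration h -> force-balance root at r = R_st(h)."""
    h = float(seed)
    g = _slaved_net(p)
    for _ in range(JOINT_MAX_ITER):
        a = eval_polymerization_rate(p.polym, h)
        if a <= 0:
            return None
        r = tip_radius_steady(p.tip, h, a)
        if r <= 0:
            return None
        roots = find_force_balance_roots(p, r_tip=r, h_max=h_max, n_scan=max(100, n_scan // 10))
        if not roots:
            return None
        target = min(roots, key=lambda s: abs(s.h - h))
        h_new = h + JOINT_DAMPING * (target.h - h)
        if h_new <= 0:
            return None
        resid = float(g(np.asarray([h_new]))[0])
        if abs(h_new - h) <= JOINT_RTOL * max(h_new, 1e-12) and abs(resid) <= 1e-6 * _force_scale(p, h_new):
            return h_new
        h = h_new
    return None  # oscillating / non-convergent seed; the dense scan covers it


def _polish(g: Callable[[np.ndarray], np.ndarray], h: float, h_lo: float, h_max: float) -> float:
    """Tighten a root of the slaved net force by local bracketing."""
    for widen in (1e-6, 1e-4, 1e-2):
        lo = max(h * (1 - widen), h_lo)
        hi = min(h * (1 + widen), h_max)
        vlo = float(g(np.asarray([lo]))[0])
        vhi = float(g(np.asarray([hi]))[0])
        if vlo == 0.0:
            return lo
        if vhi == 0.0:
            return hi
        if vlo * vhi < 0.0:
            return float(brentq(lambda x: float(g(np.asarray([x]))[0]), lo, hi, xtol=1e-13 * h_max))
    return h


def solve_joint(
    p: ProtrusionParams,
    seeds: Optional[Sequence[float]] = None,
    h_max: Optional[float] = None,
    n_scan: int = DEFAULT_N_SCAN,
) -> List[SteadyState]:
    """Solve the joint height-radius fixed point.

    Returns all jointly consistent steady states (stable and unstable,
    flagged), ordered by height.  An empty list means no protrusion can be
    sustained: the microvilli-free outcome.

    The damped alternating iteration from a 16-point geometric seed ladder
    is backed by a dense scan of the radius-slaved net force over
    (h_min, h_max]; the two sets are merged and deduplicated, so a seed
    that oscillates without converging cannot hide a branch.
    """
    if h_max is None:
        h_max = default_h_max(p)
    h_min = p.tip.h_min
    h_lo = h_min * (1.0 + 1e-9) if h_min > 0 else 1e-9 * h_max
    if seeds is None:
        seeds = _default_seeds(p, h_max)
    if len(seeds) == 0:
        raise ModelDomainError("seeds must be non-empty")

    g = _slaved_net(p)
    candidates: List[float] = []
    n_converged = 0
    for seed in seeds:
        h = _iterate_seed(p, float(seed), h_max, n_scan)
        if h is not None and h >= h_lo:
            candidates.append(_polish(g, h, h_lo, h_max))
            n_converged += 1
    # completeness net: dense scan of the slaved net force
    candidates.extend(_scan_roots(g, h_lo, h_max, max(n_scan, 2000)))
    logger.debug(
        "solve_joint: %d/%d seeds converged, %d candidate roots",
        n_converged, len(seeds), len(candidates),
    )
    if not candidates:
        return []

    candidates.sort()
    groups: List[List[float]] = []
    for h in candidates:
        if groups and abs(h - groups[-1][-1]) <= DEDUP_RTOL * max(abs(h), 1e-12):
            groups[-1].append(h)
        else:
            groups.append([h])
    # keep the member of each group with the smallest slaved-net residual
    merged = [
        min(grp, key=lambda h: abs(float(g(np.asarray([h]))[0]))) for grp in groups
    ]

    out: List[SteadyState] = []
    for h in merged:
        a = eval_polymerization_rate(p.polym, h)
        r = float(tip_radius_steady(p.tip, h, a))
        resid = float(g(np.asarray([h]))[0])
        if abs(resid) > 1e-6 * _force_scale(p, h):
            continue  # scan artefact (e.g. grazing minimum), not a true root
        if r <= 0 or h < h_min:
            continue
        out.append(SteadyState(h=h, r=r, stable=_classify(g, h, h_max), residual=resid))
    return out


def existence_threshold(
    p: ProtrusionParams,
    param_name: str,
    lo: float,
    hi: float,
    rtol: float = 1e-4,
) -> float:
    """Critical value of a scalar parameter separating protrusion existence.

    ``param_name`` is one of ``gamma_c``, ``a0``, ``beta``.  The joint
    problem must have no stable solution at ``lo`` and at least one at
    ``hi``; the boundary is located by bisection to relative tolerance
    ``rtol``.
    """
    if param_name not in SWEEPABLE_PARAMS:
        raise ModelDomainError(
            f"unknown parameter {param_name!r}; expected one of {SWEEPABLE_PARAMS}"
        )
    if lo == hi:
        raise ModelDomainError("lo and hi must differ")

    def exists(value: float) -> bool:
        sols = solve_joint(with_param(p, param_name, value))
        return any(s.stable for s in sols)

    if exists(lo):
        raise ModelDomainError(
            f"precondition violated: stable protrusion already exists at lo={lo}"
        )
    if not exists(hi):
        raise ModelDomainError(
            f"precondition violated: no stable protrusion at hi={hi}"
        )
    a, b = float(lo), float(hi)
    while abs(b - a) > rtol * max(abs(a), abs(b)):
        mid = 0.5 * (a + b)
        if exists(mid):
            b = mid
        else:
            a = mid
    return 0.5 * (a + b)
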