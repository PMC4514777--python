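"""Assembly of a stereocilia bundle across a spatially graded apical surface.

The planar polarization of the epithelium is represented as a linear
gradient in one scalar model parameter — the cuticular-plate viscosity
``gamma_c``, the basal polymerization rate ``a0``, or the severing rate
``beta`` — along an abstract coordinate x that increases toward the tall
(kinocilium) edge of the bundle.  Each stereocilia row sits at a position
x, inherits the local parameter value, and is solved independently for its
joint height-radius steady state.  Rows whose local parameters admit no
stable protrusion are marked absent: this is the microvilli-free region of
the apical surface.

When a row's parameters admit several stable states, the branch is chosen
by a rule:

``developmental``
    integrate the height dynamics from a microvillus-scale seed
    (h0 = 0.1 * h_min) with a small nucleation radius floor, and take the
    stable state the dynamics reach — the state a nascent microvillus grows
    into (default);
``tallest``
    take the highest stable state (sensitivity analysis).

Inter-stereocilia linkers near the tips equalize heights within a row;
:func:`apply_row_coupling` implements this as discrete relaxation toward
the row mean.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core_model import (
    IntegrationError,
    ModelDomainError,
    ProtrusionParams,
    integrate_height,
    height_rhs,
    with_param,
)
from .steady_state_solver import SolverError, SteadyState, default_h_max, solve_joint

logger = logging.getLogger("scgsim")

FIELD_TARGETS = ("gamma_c", "a0", "beta")
BRANCH_RULES = ("developmental", "tallest")
#: relative band within which row radii count as "constant"
RADIUS_CONSTANT_RTOL = 0.01
#: nucleation radius floor for developmental growth, as a fraction of r_ref
NUCLEATION_RADIUS_FRACTION = 0.02


class BundleBuildError(RuntimeError):
    """Solving one row of the bundle failed."""


@dataclass(frozen=True)
class ApicalField:
    """A linear spatial gradient in one scalar parameter of the model."""

    target: str
    x_lo: float
    x_hi: float
    v_lo: float
    slope: float
    row_positions: Tuple[float, ...]

    def __post_init__(self) -> None:
        if self.target not in FIELD_TARGETS:
            raise ModelDomainError(
                f"unknown gradient target {self.target!r}; expected one of {FIELD_TARGETS}"
            )
        if not self.x_hi > self.x_lo:
            raise ModelDomainError("x_hi must exceed x_lo")
        v_hi = self.v_lo + self.slope * (self.x_hi - self.x_lo)
        if self.v_lo <= 0 or v_hi <= 0:
            raise ModelDomainError(
                f"{self.target} must stay positive over the field "
                f"(endpoint values {self.v_lo}, {v_hi})"
            )
        pos = tuple(float(x) for x in self.row_positions)
        if any(x < self.x_lo or x > self.x_hi for x in pos):
            raise ModelDomainError("row positions must lie within [x_lo, x_hi]")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ModelDomainError("row positions must be strictly increasing")
        object.__setattr__(self, "row_positions", pos)


@dataclass(frozen=True)
class BundleRow:
    index: int
    x: float
    status: str  # "absent" | "protrusion"
    h: float
    r: float


@dataclass(frozen=True)
class StaircaseMetrics:
    """Shape descriptors of a bundle's height profile.

    ``diffs``        consecutive height differences among protrusion rows
    ``second_diffs`` differences of those differences (>0 everywhere means
                     a convex staircase)
    ``radius_trend`` "constant" | "decreasing" | "increasing" | "mixed",
                     or None when fewer than two protrusion rows exist
    ``jump_ratio``   (h_tallest - h_second) / (h_second - h_third), or None
                     when fewer than three protrusion rows exist
    """

    diffs: Tuple[float, ...]
    second_diffs: Tuple[float, ...]
    radius_trend: Optional[str]
    jump_ratio: Optional[float]


@dataclass(frozen=True)
class Bundle:
    rows: Tuple[BundleRow, ...]
    metrics: StaircaseMetrics


def field_value(f: ApicalField, x: float) -> float:
    """Local parameter value v_lo + slope * (x - x_lo)."""
    if x < f.x_lo or x > f.x_hi:
        raise ModelDomainError(
            f"position {x} outside field interval [{f.x_lo}, {f.x_hi}]"
        )
    return f.v_lo + f.slope * (x - f.x_lo)


def uniform_row_positions(n_rows: int, x_lo: float = 0.0, x_hi: float = 1.0) -> Tuple[float, ...]:
    """Uniformly spaced row positions spanning [x_lo, x_hi]."""
    if n_rows < 1:
        raise ModelDomainError("need at least one row")
    if n_rows == 1:
        return (0.5 * (x_lo + x_hi),)
    return tuple(np.linspace(x_lo, x_hi, n_rows))


# ---------------------------------------------------------------------------
# branch selection
# ---------------------------------------------------------------------------

def _settle_height(
    p: ProtrusionParams, h0: float, r_floor: float, h_scale: float
) -> float:
    """Integrate the height dynamics until the height stops moving."""
    h = h0
    # crude relaxation-time scale: tau ~ h / A near a root, bounded below
    t_chunk = 50.0 * max(h_scale / max(p.polym.a0, p.polym.a_max / 10.0, 1e-6), 1.0)
    for _ in range(60):
        traj = integrate_height(p, h, t_chunk, t_chunk / 50.0, r_floor=r_floor)
        h_new = float(traj.heights[-1])
        if abs(h_new - h) <= 1e-9 * max(h_new, 1e-12):
            rhs = height_rhs(p, h_new, r_floor=r_floor)
            if abs(rhs) * t_chunk <= 1e-6 * max(h_new, h_scale):
                return h_new
        h = h_new
    return h


def _select_developmental(
    p: ProtrusionParams,
    stable: Sequence[SteadyState],
    nucleation_radius: Optional[float],
) -> SteadyState:
    if len(stable) == 1:
        return stable[0]
    r_nuc = (
        nucleation_radius
        if nucleation_radius is not None
        else NUCLEATION_RADIUS_FRACTION * p.tip.r_ref
    )
    h_min = p.tip.h_min
    h0 = 0.1 * h_min if h_min > 0 else 1e-3 * stable[0].h
    h_scale = max(s.h for s in stable)
    h_end = _settle_height(p, h0, r_nuc, h_scale)
    # match the settled height to the nearest stable branch (log distance)
    def logdist(s: SteadyState) -> float:
        return abs(math.log(max(h_end, 1e-300) / s.h))

    chosen = min(stable, key=logdist)
    logger.debug(
        "developmental branch: settled at h=%.6g, matched to h=%.6g among %s",
        h_end, chosen.h, [f"{s.h:.6g}" for s in stable],
    )
    return chosen


# ---------------------------------------------------------------------------
# bundle assembly and classification
# ---------------------------------------------------------------------------

def build_bundle(
    f: ApicalField,
    template: ProtrusionParams,
    branch_rule: str = "developmental",
    nucleation_radius: Optional[float] = None,
    h_max: Optional[float] = None,
    n_scan: int = 2000,
) -> Bundle:
    """Solve every row of the bundle under the apical gradient.

    For each row position the gradient-target parameter of ``template`` is
    overridden by the local field value and the joint height-radius problem
    is solved; rows with no stable solution are absent.
    """
    if branch_rule not in BRANCH_RULES:
        raise ModelDomainError(
            f"unknown branch rule {branch_rule!r}; expected one of {BRANCH_RULES}"
        )
    rows: List[BundleRow] = []
    for i, x in enumerate(f.row_positions):
        value = field_value(f, x)
        p_row = with_param(template, f.target, value)
        try:
            sols = solve_joint(p_row, h_max=h_max, n_scan=n_scan)
        except (SolverError, IntegrationError, ModelDomainError) as exc:
            raise BundleBuildError(
                f"row {i} at x={x} ({f.target}={value}): {exc}"
            ) from exc
        stable = [s for s in sols if s.stable]
        if not stable:
            rows.append(BundleRow(index=i, x=x, status="absent", h=0.0, r=0.0))
            continue
        if branch_rule == "tallest":
            chosen = max(stable, key=lambda s: s.h)
        else:
            try:
                chosen = _select_developmental(p_row, stable, nucleation_radius)
            except (IntegrationError, ModelDomainError) as exc:
                raise BundleBuildError(
                    f"row {i} at x={x} ({f.target}={value}): {exc}"
                ) from exc
        rows.append(
            BundleRow(index=i, x=x, status="protrusion", h=chosen.h, r=chosen.r)
        )
    metrics = _classify_rows(rows)
    return Bundle(rows=tuple(rows), metrics=metrics)


def _classify_rows(rows: Sequence[BundleRow]) -> StaircaseMetrics:
    prot = [r for r in rows if r.status == "protrusion"]
    hs = np.array([r.h for r in prot], dtype=float)
    rs = np.array([r.r for r in prot], dtype=float)

    diffs: Tuple[float, ...] = ()
    second: Tuple[float, ...] = ()
    trend: Optional[str] = None
    jump: Optional[float] = None

    if len(prot) >= 2:
        diffs = tuple(np.diff(hs))
        rd = np.diff(rs)
        spread = (rs.max() - rs.min()) / rs.mean() if rs.mean() > 0 else 0.0
        if spread <= RADIUS_CONSTANT_RTOL:
            trend = "constant"
        elif np.all(rd < 0):
            trend = "decreasing"
        elif np.all(rd > 0):
            trend = "increasing"
        else:
            trend = "mixed"
    if len(prot) >= 3:
        second = tuple(np.diff(np.diff(hs)))
        top = np.sort(hs)[::-1][:3]
        denom = top[1] - top[2]
        jump = float((top[0] - top[1]) / denom) if denom != 0 else math.inf
    return StaircaseMetrics(
        diffs=diffs, second_diffs=second, radius_trend=trend, jump_ratio=jump
    )


def classify_staircase(b: Bundle) -> StaircaseMetrics:
    """Recompute the staircase metrics of a bundle from its rows."""
    return _classify_rows(b.rows)


def bundle_from_rows(rows: Sequence[BundleRow]) -> Bundle:
    """Assemble a Bundle (with metrics) from pre-computed rows."""
    rows = tuple(sorted(rows, key=lambda r: r.x))
    return Bundle(rows=rows, metrics=_classify_rows(rows))


# ---------------------------------------------------------------------------
# inter-row linker coupling
# ---------------------------------------------------------------------------

def apply_row_coupling(
    heights: Sequence[float], k: float, n_steps: int = 1
) -> List[float]:
    """Relax heights within a row toward their common mean.

    Tip linkers between same-row stereocilia pull heights together; each
    discrete step applies ``h_i <- h_i + k * (mean - h_i)`` with coupling
    strength k in [0, 1].  The mean is preserved and the variance is
    non-increasing at every step (contraction by (1-k)^2 per step).
    """
    if len(heights) == 0:
        raise ModelDomainError("heights must be non-empty")
    if not 0.0 <= k <= 1.0:
        raise ModelDomainError("coupling strength k must lie in [0, 1]")
    if n_steps < 0:
        raise ModelDomainError("n_steps must be >= 0")
    h = np.asarray(heights, dtype=float)
    mean = float(h.mean())
    if k == 1.0 and n_steps >= 1:
        return [mean] * len(h)
    for _ in range(n_steps):
        h = h + k * (mean - h)
    return [float(v) for v in h]
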