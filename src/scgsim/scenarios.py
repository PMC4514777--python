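"""Named wild-type regimes and mutant phenotypes.

Each scenario is a fully parameterized, deterministic configuration: an
apical gradient, a protrusion-parameter template, and a mutation (identity
for wild types).  The wild-type regimes correspond to the classic bundle
phenotypes:

``vestibular_wt``    constant polymerization rate + linear viscosity
                     gradient: a linear staircase with near-equal radii and
                     a microvilli-free region at low viscosity.
``cochlear_graded``  polymerization rate increasing with height (positive
                     feedback): a convex staircase whose taller rows are
                     thinner.
``inner_hair_cell``  sharply height-dependent polymerization rate: the
                     tallest row jumps far above the rest.

Mutations are parameter transformations:

``eps8_ko``    loss of the Eps8/whirlin/myosin-XV tip complex removes the
               height-polymerization feedback: A(h) is flattened to its
               basal value, giving short, thick stereocilia with only the
               shallow background gradient remaining.
``espin3_oe``  small espin-3 overexpression: polymerization rate x1.3 and
               severing rate halved, elongating the protrusions roughly
               threefold at fixed tip radius.
``jerker``     espin null: strongly thinned tip complexes (r_ref scaled
               down); stereocilia shorten and may lose stability.
``espin_oe``   espin overexpression: faster polymerization, slower
               severing and a wider tip complex - longer and thicker.
``triobp_ko``  loss of rootlet bundling raises the effective severing
               rate; heights drop and rows can degrade away entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Dict, Optional

import numpy as np
import pandas as pd

from .apical_bundle import ApicalField, Bundle, build_bundle, uniform_row_positions
from .core_model import (
    ModelDomainError,
    PolymerizationModel,
    Promoter,
    ProtrusionParams,
    TipRadiusModel,
    steady_state_height,
)


@dataclass(frozen=True)
class Mutation:
    """A multiplicative / replacement transformation of protrusion parameters."""

    name: str = "identity"
    a_factor: float = 1.0
    beta_factor: float = 1.0
    r_factor: float = 1.0
    flatten_a: bool = False
    a0_low: Optional[float] = None

    def __post_init__(self) -> None:
        for field_name in ("a_factor", "beta_factor", "r_factor"):
            if getattr(self, field_name) <= 0:
                raise ModelDomainError(f"{field_name} must be > 0")
        if self.flatten_a and self.a0_low is None:
            raise ModelDomainError("flatten_a requires a0_low")
        if self.a0_low is not None and self.a0_low < 0:
            raise ModelDomainError("a0_low must be >= 0")

    @property
    def is_identity(self) -> bool:
        return (
            self.a_factor == 1.0
            and self.beta_factor == 1.0
            and self.r_factor == 1.0
            and not self.flatten_a
        )


IDENTITY_MUTATION = Mutation()


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    field: ApicalField
    template: ProtrusionParams
    mutation: Mutation


def apply_mutation(p: ProtrusionParams, m: Mutation) -> ProtrusionParams:
    """Return a transformed copy of ``p``; the original is untouched.

    ``a_factor`` scales every amplitude of A(h) (basal rate, feedback
    amplitude, promoter amplitudes); ``beta_factor`` scales the severing
    rate; ``r_factor`` scales the reference tip radius.  ``flatten_a``
    replaces A(h) by the constant ``a0_low`` before scaling.
    """
    pm = p.polym
    if m.flatten_a:
        pm = PolymerizationModel(family="constant", a0=m.a0_low)
    pm = replace(
        pm,
        a0=pm.a0 * m.a_factor,
        a1=pm.a1 * m.a_factor,
        promoters=tuple(
            replace(pr, amplitude=pr.amplitude * m.a_factor) for pr in pm.promoters
        ),
    )
    tip = replace(p.tip, r_ref=p.tip.r_ref * m.r_factor)
    return replace(p, polym=pm, tip=tip, beta=p.beta * m.beta_factor)


# ---------------------------------------------------------------------------
# fixture parameter sets
# ---------------------------------------------------------------------------

def _base_kwargs() -> dict:
    # nondimensional baseline shared by all fixtures
    return dict(alpha=1.0, nu=1.0, mu=0.5, f_md0=0.0, c_s=1.0)


def _vestibular_template() -> ProtrusionParams:
    return ProtrusionParams(
        gamma_c=1.0,  # overridden row-by-row from the field
        beta=10.0,
        polym=PolymerizationModel(family="constant", a0=1.0),
        tip=TipRadiusModel(h_min=1e-3, r_ref=0.4, a_ref=1.0, s=0.5, q=0.5),
        **_base_kwargs(),
    )


def _vestibular_field() -> ApicalField:
    # gamma_c from 0.03 (below the existence threshold: microvilli-free)
    # to 150 at the kinocilium edge; 8 uniformly spaced rows
    return ApicalField(
        target="gamma_c",
        x_lo=0.0,
        x_hi=7.0,
        v_lo=0.03,
        slope=(150.0 - 0.03) / 7.0,
        row_positions=uniform_row_positions(8, 0.0, 7.0),
    )


def _cochlear_template() -> ProtrusionParams:
    return ProtrusionParams(
        gamma_c=1.0,
        beta=10.0,
        polym=PolymerizationModel(family="sigmoid", a0=0.6, a1=0.8, h_half=8.0, m=3.0),
        tip=TipRadiusModel(h_min=0.1, r_ref=0.4, a_ref=0.6, s=0.5, q=0.5),
        **_base_kwargs(),
    )


def _cochlear_field() -> ApicalField:
    return ApicalField(
        target="gamma_c",
        x_lo=0.0,
        x_hi=7.0,
        v_lo=139.0,
        slope=(260.0 - 139.0) / 7.0,
        row_positions=uniform_row_positions(8, 0.0, 7.0),
    )


def _inner_hair_cell_template() -> ProtrusionParams:
    return ProtrusionParams(
        gamma_c=1.0,
        beta=10.0,
        polym=PolymerizationModel(
            family="sharp_sigmoid", a0=0.5, a1=0.5, h_half=4.0, m=12.0
        ),
        tip=TipRadiusModel(h_min=0.2, r_ref=0.4, a_ref=0.5, s=0.5, q=0.5),
        **_base_kwargs(),
    )


def _inner_hair_cell_field() -> ApicalField:
    return ApicalField(
        target="gamma_c",
        x_lo=0.0,
        x_hi=7.0,
        v_lo=60.0,
        slope=(330.0 - 60.0) / 7.0,
        row_positions=uniform_row_positions(8, 0.0, 7.0),
    )


def two_promoter_params(gamma_c: float = 30.0) -> ProtrusionParams:
    """Uniform-cell fixture with two promoters saturating at different heights.

    At a fixed tip radius (use :func:`two_promoter_r_tip`) the pushing force
    is staircase-like in h and the linear restoring force crosses it several
    times, producing multiple stable steady-state heights.
    """
    return ProtrusionParams(
        gamma_c=gamma_c,
        beta=10.0,
        polym=PolymerizationModel(
            family="promoter_sum",
            a0=0.2,
            promoters=(
                Promoter(amplitude=0.8, h_sat=1.0, steepness=8.0),
                Promoter(amplitude=1.0, h_sat=5.0, steepness=16.0),
            ),
        ),
        tip=TipRadiusModel(h_min=0.2, r_ref=1.0, a_ref=1.0, s=0.5, q=0.5),
        **_base_kwargs(),
    )


def two_promoter_r_tip() -> float:
    """Fixed tip radius used with the two-promoter multi-stability fixture."""
    return 1.0


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

def _spec(name: str, field: ApicalField, template: ProtrusionParams,
          mutation: Mutation = IDENTITY_MUTATION) -> ScenarioSpec:
    return ScenarioSpec(name=name, field=field, template=template, mutation=mutation)


_REGISTRY: Dict[str, Callable[[], ScenarioSpec]] = {
    "vestibular_wt": lambda: _spec(
        "vestibular_wt", _vestibular_field(), _vestibular_template()
    ),
    "cochlear_graded": lambda: _spec(
        "cochlear_graded", _cochlear_field(), _cochlear_template()
    ),
    "inner_hair_cell": lambda: _spec(
        "inner_hair_cell", _inner_hair_cell_field(), _inner_hair_cell_template()
    ),
    "eps8_ko": lambda: _spec(
        "eps8_ko",
        _inner_hair_cell_field(),
        _inner_hair_cell_template(),
        Mutation(
            name="eps8_ko",
            flatten_a=True,
            a0_low=_inner_hair_cell_template().polym.a0,
        ),
    ),
    "espin3_oe": lambda: _spec(
        "espin3_oe",
        _vestibular_field(),
        _vestibular_template(),
        Mutation(name="espin3_oe", a_factor=1.3, beta_factor=0.5),
    ),
    "jerker": lambda: _spec(
        "jerker",
        _cochlear_field(),
        _cochlear_template(),
        Mutation(name="jerker", r_factor=0.3),
    ),
    "espin_oe": lambda: _spec(
        "espin_oe",
        _vestibular_field(),
        _vestibular_template(),
        Mutation(name="espin_oe", a_factor=1.3, beta_factor=0.5, r_factor=1.5),
    ),
    "triobp_ko": lambda: _spec(
        "triobp_ko",
        _cochlear_field(),
        _cochlear_template(),
        Mutation(name="triobp_ko", beta_factor=3.0),
    ),
}

SCENARIO_NAMES = tuple(sorted(_REGISTRY))


def make_scenario(name: str) -> ScenarioSpec:
    """Look up a registered scenario by name."""
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise ModelDomainError(
            f"unknown scenario {name!r}; registered scenarios: "
            + ", ".join(SCENARIO_NAMES)
        ) from None
    return factory()


def run_scenario(
    spec: ScenarioSpec, branch_rule: str = "developmental"
) -> "tuple[Bundle, Bundle]":
    """Build the wild-type bundle and the mutant bundle for a scenario."""
    wt = build_bundle(spec.field, spec.template, branch_rule=branch_rule)
    if spec.mutation.is_identity:
        return wt, wt
    mut_template = apply_mutation(spec.template, spec.mutation)
    mut = build_bundle(spec.field, mut_template, branch_rule=branch_rule)
    return wt, mut


def compare_bundles(wt: Bundle, mut: Bundle) -> pd.DataFrame:
    """Per-row mutant/wild-type height and radius ratios.

    Ratios and relative changes are NaN where either row is absent.
    Raises if the two bundles were not built on the same row positions.
    """
    if len(wt.rows) != len(mut.rows) or any(
        abs(a.x - b.x) > 1e-12 * max(1.0, abs(a.x)) for a, b in zip(wt.rows, mut.rows)
    ):
        raise ModelDomainError("bundles have mismatched row positions")
    records = []
    for a, b in zip(wt.rows, mut.rows):
        both = a.status == "protrusion" and b.status == "protrusion"
        h_ratio = b.h / a.h if both else np.nan
        r_ratio = b.r / a.r if both else np.nan
        records.append(
            dict(
                row_index=a.index,
                x=a.x,
                status_wt=a.status,
                status_mut=b.status,
                h_wt=a.h,
                h_mut=b.h,
                r_wt=a.r,
                r_mut=b.r,
                h_ratio=h_ratio,
                r_ratio=r_ratio,
                h_rel_change=h_ratio - 1.0 if both else np.nan,
                r_rel_change=r_ratio - 1.0 if both else np.nan,
            )
        )
    return pd.DataFrame.from_records(records)


def espin3_height_factor(beta_over_a: float = 10.0) -> float:
    """Fold-change in steady-state height under the espin-3 transformation.

    From a severing-dominated baseline (beta = ``beta_over_a`` * A, with
    beta_over_a >= 5) the polymerization rate is multiplied by 1.3 and the
    severing rate halved while the tip radius is held fixed; the ratio of
    the new to the old closed-form steady-state height is returned.
    """
    if beta_over_a < 5.0:
        raise ModelDomainError(
            "espin worked example assumes a severing-dominated baseline "
            "(beta >= 5*A)"
        )
    base = ProtrusionParams(
        gamma_c=1.0,
        beta=beta_over_a,
        polym=PolymerizationModel(family="constant", a0=1.0),
        tip=TipRadiusModel(h_min=1e-3, r_ref=1.0, a_ref=1.0, s=0.0, q=0.5),
        **_base_kwargs(),
    )
    mutant = apply_mutation(base, Mutation(name="espin3_oe", a_factor=1.3, beta_factor=0.5))
    r_tip = 1.0  # held fixed: the radius was not measured in the experiment
    return steady_state_height(mutant, r_tip) / steady_state_height(base, r_tip)
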