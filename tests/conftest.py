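import pytest

import scgsim as sg


@pytest.fixture(scope="session")
def const_params():
    """Constant polymerization rate, degenerate tip model (fixed-radius limit)."""
    return sg.ProtrusionParams(
        gamma_c=30.0,
        alpha=1.0,
        nu=1.0,
        mu=0.5,
        f_md0=0.0,
        beta=10.0,
        polym=sg.PolymerizationModel(family="constant", a0=1.0),
        tip=sg.TipRadiusModel(h_min=0.0, r_ref=1.0, a_ref=1.0, s=0.0, q=0.5),
    )


@pytest.fixture(scope="session")
def two_promoter():
    """Uniform-cell multi-stability fixture (params, fixed tip radius)."""
    return sg.two_promoter_params(), sg.two_promoter_r_tip()


@pytest.fixture(scope="session")
def vestibular_bundle():
    spec = sg.make_scenario("vestibular_wt")
    return spec, sg.build_bundle(spec.field, spec.template)


@pytest.fixture(scope="session")
def cochlear_bundle():
    spec = sg.make_scenario("cochlear_graded")
    return spec, sg.build_bundle(spec.field, spec.template)


@pytest.fixture(scope="session")
def inner_hair_cell_bundle():
    spec = sg.make_scenario("inner_hair_cell")
    return spec, sg.build_bundle(spec.field, spec.template)


@pytest.fixture(scope="session")
def eps8_comparison(inner_hair_cell_bundle):
    spec, wt = inner_hair_cell_bundle
    ko = sg.make_scenario("eps8_ko")
    mut = sg.build_bundle(ko.field, sg.apply_mutation(ko.template, ko.mutation))
    return wt, mut, sg.compare_bundles(wt, mut)
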