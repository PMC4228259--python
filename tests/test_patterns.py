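"""Flow-pattern taxonomy: vortex census, jet/impaction narrowness,
streamline tracing."""

import dataclasses

import numpy as np
import pytest

from aneuflow.fields import FlowField, box_tet_lattice
from aneuflow.patterns import (FlowPatternReport, NoInflowError,
                               classify_pattern, count_vortices,
                               measure_jet_and_impaction, trace_streamlines)
from aneuflow.synthetic import ConstructedFieldSpec, generate_constructed_field


# ----------------------------------------------------------------------
# streamlines
# ----------------------------------------------------------------------
@pytest.fixture(scope="module")
def box_field_factory():
    nodes, tets = box_tet_lattice(np.array([-5.0, -5.0, -1.0]), 0.5,
                                  (20, 20, 4))

    def make(u_fn):
        u = np.zeros((1, len(nodes), 3))
        u[0] = u_fn(nodes)
        return FlowField(nodes, tets, u, np.zeros((1, len(nodes))),
                         np.array([0.0]), 0)

    return make


def test_uniform_field_traces_straight_lines(box_field_factory):
    f = box_field_factory(lambda n: np.tile([100.0, 0, 0], (len(n), 1)))
    ln = trace_streamlines(f, 0, np.array([[-4.0, 0.3, 0.1]]))[0]
    assert len(ln) > 5
    assert np.allclose(ln[:, 1], 0.3) and np.allclose(ln[:, 2], 0.1)


def test_solid_body_rotation_traces_circles(box_field_factory):
    def swirl(n):
        u = np.zeros((len(n), 3))
        u[:, 0] = -50 * n[:, 1]
        u[:, 1] = 50 * n[:, 0]
        return u

    f = box_field_factory(swirl)
    ln = trace_streamlines(f, 0, np.array([[2.0, 0.0, 0.0]]),
                           max_length=30.0)[0]
    r = np.linalg.norm(ln[:, :2], axis=1)
    assert np.abs(r - 2.0).max() < 0.02  # 1% of the seed radius


def test_zero_field_gives_zero_length_lines(box_field_factory):
    f = box_field_factory(lambda n: np.zeros((len(n), 3)))
    ln = trace_streamlines(f, 0, np.array([[0.0, 0.0, 0.0]]))[0]
    assert len(ln) == 1


def test_seed_outside_lumen_rejected(box_field_factory):
    f = box_field_factory(lambda n: np.zeros((len(n), 3)))
    with pytest.raises(ValueError, match="seed"):
        trace_streamlines(f, 0, np.array([[50.0, 0.0, 0.0]]))


# ----------------------------------------------------------------------
# vortex census
# ----------------------------------------------------------------------
@pytest.mark.parametrize("count", [0, 1, 3])
def test_vortex_count_matches_construction(count):
    cf = generate_constructed_field(
        ConstructedFieldSpec(n_vortices_per_step=(count,),
                             jet_width_fraction=0.4))
    assert count_vortices(cf.field, cf.region, 0) == count


# ----------------------------------------------------------------------
# classification decision table
# ----------------------------------------------------------------------
@pytest.mark.parametrize("counts,changes,expected", [
    ((1, 1, 1, 1), False, "I"),
    ((2, 2, 2, 2), False, "II"),
    ((1, 1, 1, 1), True, "III"),
    ((1, 2, 2, 1), True, "IV"),
])
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_every_fixture_classifies_as_constructed(counts, changes, expected,
                                                 seed):
    spec = ConstructedFieldSpec(n_vortices_per_step=counts,
                                jet_direction_changes=changes,
                                jet_width_fraction=0.4, seed=seed)
    cf = generate_constructed_field(spec)
    rep = classify_pattern(cf.field, cf.region)
    assert rep.cebral_type == expected
    assert rep.vortex_count_per_step == list(counts)
    assert rep.jet_direction_changed == changes


# ----------------------------------------------------------------------
# jet and impaction narrowness
# ----------------------------------------------------------------------
def test_narrow_jet_width_recovered():
    cf = generate_constructed_field(
        ConstructedFieldSpec(n_vortices_per_step=(1,),
                             jet_width_fraction=0.3))
    jf, imf, _ = measure_jet_and_impaction(cf.field, cf.region)
    assert jf == pytest.approx(0.30, abs=0.05)
    assert 0.0 <= imf <= 1.0


def test_plug_inflow_spans_the_neck():
    cf = generate_constructed_field(
        ConstructedFieldSpec(n_vortices_per_step=(0,),
                             jet_width_fraction=1.0))
    jf, _, _ = measure_jet_and_impaction(cf.field, cf.region)
    assert jf == pytest.approx(1.0, abs=0.02)
    rep = classify_pattern(cf.field, cf.region)
    assert rep.narrowed_jet is False


def test_narrowness_rule_is_strictly_below_half():
    # the fraction-exactly-0.5 boundary: NOT narrowed (strict <)
    rep = FlowPatternReport(
        cebral_type="I", vortex_count_per_step=[1],
        jet_direction_changed=False, jet_width_fraction=0.5,
        impaction_zone_fraction=0.5, narrowed_jet=False,
        narrowed_impaction=False,
    )
    assert rep.narrowed_jet is False and rep.narrowed_impaction is False
    just_below = FlowPatternReport(
        cebral_type="I", vortex_count_per_step=[1],
        jet_direction_changed=False, jet_width_fraction=0.4999,
        impaction_zone_fraction=0.4999, narrowed_jet=True,
        narrowed_impaction=True,
    )
    assert just_below.narrowed_jet and just_below.narrowed_impaction


def test_report_flags_must_follow_the_rule():
    with pytest.raises(AssertionError):
        FlowPatternReport(
            cebral_type="I", vortex_count_per_step=[1],
            jet_direction_changed=False, jet_width_fraction=0.3,
            impaction_zone_fraction=0.3, narrowed_jet=False,
            narrowed_impaction=True,
        )


def test_reversed_flux_raises_no_inflow():
    cf = generate_constructed_field(
        ConstructedFieldSpec(n_vortices_per_step=(0,),
                             jet_width_fraction=0.5))
    reversed_field = dataclasses.replace(
        cf.field, velocities=-cf.field.velocities, _interp=None)
    with pytest.raises(NoInflowError):
        measure_jet_and_impaction(reversed_field, cf.region)


def test_fractions_always_in_unit_interval():
    for w in (0.2, 0.5, 0.9):
        cf = generate_constructed_field(
            ConstructedFieldSpec(n_vortices_per_step=(1,),
                                 jet_width_fraction=w))
        rep = classify_pattern(cf.field, cf.region)
        assert 0.0 <= rep.jet_width_fraction <= 1.0
        assert 0.0 <= rep.impaction_zone_fraction <= 1.0
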