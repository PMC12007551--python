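"""Morphology generation, SWC round trips, myelination and discretization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmsresponse.errors import ConfigurationError, GeometryError, SWCParseError, TopologyError
from tmsresponse.morphology import (
    MyelinationParams,
    Morphology,
    Section,
    SectionKind,
    apply_scaling,
    discretize,
    generate_ball_and_stick,
    generate_synthetic_population,
    load_swc,
    myelinate_axon,
    save_swc,
)


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def test_load_minimal_cable(tmp_path):
    """A 3-point single cable parses into one root section with 2 segments."""
    f = tmp_path / "cable.swc"
    f.write_text("1 2 0 0 0 0.5 -1\n2 2 0 0 -10 0.5 1\n3 2 0 0 -20 0.5 2\n")
    m = load_swc(f)
    assert len(m.sections) == 1
    s = m.sections[0]
    assert s.kind is SectionKind.AXON_UNMYELINATED
    assert len(s.points) == 3
    assert s.arc_length == pytest.approx(20.0)


def test_swc_round_trip_identity(tmp_path):
    """save∘load is the identity on generator output (coords, radii, topology)."""
    m = generate_synthetic_population(1, "pyramidal_like", 3)[0]
    f1, f2 = tmp_path / "a.swc", tmp_path / "b.swc"
    save_swc(m, f1)
    m2 = load_swc(f1)
    save_swc(m2, f2)
    assert f1.read_text() == f2.read_text()
    assert len(m2.sections) == len(m.sections)
    for a, b in zip(m.sections, m2.sections):
        assert a.kind is b.kind
        np.testing.assert_allclose(a.points, b.points, atol=1e-6)
        np.testing.assert_allclose(a.diameters, b.diameters, atol=1e-6)
        assert a.parent == b.parent


def test_swc_orphan_parent_is_topology_error(tmp_path):
    f = tmp_path / "bad.swc"
    f.write_text("1 1 0 0 0 5 -1\n2 2 0 0 -5 1 99\n")
    with pytest.raises(TopologyError):
        load_swc(f)


def test_swc_malformed_record_names_line(tmp_path):
    f = tmp_path / "bad.swc"
    f.write_text("1 1 0 0 0 5 -1\n2 2 oops 0 -5 1 1\n")
    with pytest.raises(SWCParseError, match="line 2"):
        load_swc(f)


# ---------------------------------------------------------------------------
# Ball-and-stick generator
# ---------------------------------------------------------------------------

def test_ball_and_stick_paper_geometry():
    """The 760 µm / 15 µm reference cell spans z in [0, -760] µm."""
    m = generate_ball_and_stick(760.0, 15.0)
    pts = np.vstack([s.points for s in m.sections])
    assert pts[:, 2].max() == pytest.approx(0.0)
    assert pts[:, 2].min() == pytest.approx(-760.0)
    assert all(np.allclose(s.points[:, :2], 0.0) for s in m.sections)


def test_ball_and_stick_partition_rule():
    """Hand-enumerated partition of a 100 µm, d=1 axon: node 1, internode 29, terminal 70."""
    m = generate_ball_and_stick(100.0, 1.0, MyelinationParams(), 10.0)
    kinds = [(s.kind, pytest.approx(s.arc_length)) for s in m.sections]
    assert kinds == [
        (SectionKind.SOMA, pytest.approx(0.0)),
        (SectionKind.NODE_OF_RANVIER, pytest.approx(1.0)),
        (SectionKind.MYELIN_INTERNODE, pytest.approx(29.0)),
        (SectionKind.AXON_TERMINAL, pytest.approx(70.0)),
    ]


def test_ball_and_stick_degenerate_axon():
    with pytest.raises(GeometryError):
        generate_ball_and_stick(0.0, 1.0)


# ---------------------------------------------------------------------------
# Synthetic population
# ---------------------------------------------------------------------------

def test_population_seeded_determinism():
    a = generate_synthetic_population(5, "pyramidal_like", 42)
    b = generate_synthetic_population(5, "pyramidal_like", 42)
    for ma, mb in zip(a, b):
        assert len(ma.sections) == len(mb.sections)
        for sa, sb in zip(ma.sections, mb.sections):
            np.testing.assert_array_equal(sa.points, sb.points)
            np.testing.assert_array_equal(sa.diameters, sb.diameters)


def test_population_aspect_ratio_ordering():
    """Pyramidal-like cells are taller than wide; basket-like near-isotropic."""
    pyr = generate_synthetic_population(6, "pyramidal_like", 1)
    bas = generate_synthetic_population(6, "basket_like", 1)
    ratios_p = [h / r for h, r in (c.bounding_extent() for c in pyr)]
    ratios_b = [h / r for h, r in (c.bounding_extent() for c in bas)]
    assert np.median(ratios_p) > 1.0
    # basket cells sit closer to isotropy than the pyramidal-like cells
    assert abs(np.median(ratios_b) - 1.0) < abs(np.median(ratios_p) - 1.0)


def test_population_errors():
    with pytest.raises(ConfigurationError):
        generate_synthetic_population(0, "pyramidal_like", 1)
    with pytest.raises(ConfigurationError):
        generate_synthetic_population(1, "stellate", 1)


# ---------------------------------------------------------------------------
# Myelination
# ---------------------------------------------------------------------------

def _straight_axon(length, diameter):
    sections = [
        Section(SectionKind.SOMA, np.zeros((1, 3)), np.array([20.0]), None),
        Section(SectionKind.AXON_UNMYELINATED,
                np.array([[0, 0, 0], [0, 0, -length]], dtype=float),
                np.full(2, diameter), 0),
    ]
    return Morphology(sections, identifier="axon")


def test_myelinate_1010um_pattern():
    """1010 µm, d=1: alternating internode(100)/node(1), remainder on the last
    internode, ending in a 70 µm terminal."""
    m = myelinate_axon(_straight_axon(1010.0, 1.0))
    segs = [(s.kind, round(s.arc_length, 6)) for s in m.sections[1:]]
    assert segs[0] == (SectionKind.NODE_OF_RANVIER, 1.0)
    assert segs[-1] == (SectionKind.AXON_TERMINAL, 70.0)
    internodes = [L for k, L in segs if k is SectionKind.MYELIN_INTERNODE]
    nodes = [L for k, L in segs if k is SectionKind.NODE_OF_RANVIER]
    assert internodes == [100.0] * 8 + [130.0]
    assert nodes == [1.0] * 10
    assert sum(L for _, L in segs) == pytest.approx(1010.0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(length=st.floats(5.0, 5000.0), diameter=st.floats(0.3, 16.0))
def test_myelination_conserves_arc_length(length, diameter):
    m0 = _straight_axon(length, diameter)
    m = myelinate_axon(m0)
    total = sum(s.arc_length for s in m.sections
                if s.kind is not SectionKind.SOMA and s.kind is not SectionKind.DENDRITE)
    assert total == pytest.approx(length, rel=1e-3)


def test_myelinate_dendrite_only_warns():
    sections = [
        Section(SectionKind.SOMA, np.zeros((1, 3)), np.array([20.0]), None),
        Section(SectionKind.DENDRITE, np.array([[0, 0, 0], [0, 0, 100.0]]),
                np.full(2, 2.0), 0),
    ]
    m = Morphology(sections, identifier="dend")
    with pytest.warns(UserWarning):
        out = myelinate_axon(m)
    assert out is m


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------

def test_scaling_identity_and_diameter(pyramidal_cells):
    m = pyramidal_cells[0]
    same = apply_scaling(m, None)
    for a, b in zip(m.sections, same.sections):
        np.testing.assert_allclose(a.points, b.points)
        np.testing.assert_allclose(a.diameters, b.diameters)

    doubled = apply_scaling(m, {"axon_diameter": 2.0})
    for a, b in zip(m.sections, doubled.sections):
        np.testing.assert_allclose(a.points, b.points)
        if a.kind in (SectionKind.SOMA, SectionKind.DENDRITE):
            np.testing.assert_allclose(b.diameters, a.diameters)
        else:
            np.testing.assert_allclose(b.diameters, 2.0 * a.diameters)


def test_scaling_negative_factor_rejected(pyramidal_cells):
    with pytest.raises(ConfigurationError):
        apply_scaling(pyramidal_cells[0], {"axon_diameter": -1.0})
    with pytest.raises(ConfigurationError):
        apply_scaling(pyramidal_cells[0], {"spine_density": 1.0})


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

def _single_section(length):
    sec = Section(SectionKind.DENDRITE,
                  np.array([[0, 0, 0], [0, 0, -length]], dtype=float),
                  np.full(2, 2.0), None)
    return Morphology([sec], identifier="cable")


@pytest.mark.parametrize("length,expected_n", [(100.0, 5), (101.0, 6)])
def test_discretize_splitting_rule(length, expected_n):
    cm = discretize(_single_section(length), 20.0)
    assert len(cm) == expected_n
    assert np.all(cm.lengths <= 20.0 + 1e-9)
    assert cm.lengths.sum() == pytest.approx(length, rel=1e-3)


def test_discretize_count_matches_recount(bas_cm):
    """Compartment count equals an independent per-section recount."""
    m = generate_ball_and_stick(760.0, 15.0)
    expected = sum(
        1 if s.kind is SectionKind.SOMA else math.ceil(s.arc_length / 20.0 - 1e-12)
        for s in m.sections
    )
    assert len(bas_cm) == expected


@settings(max_examples=20, deadline=None, derandomize=True)
@given(length=st.floats(1.0, 400.0), max_len=st.floats(3.0, 40.0))
def test_discretize_bounds_property(length, max_len):
    cm = discretize(_single_section(length), max_len)
    assert np.all(cm.lengths <= max_len * (1 + 1e-9))
    assert cm.lengths.sum() == pytest.approx(length, rel=1e-3)


def test_discretize_tree_ordering(branched_cm):
    """Parents precede children and the model forms a single connected tree."""
    adj = branched_cm.adjacency
    assert adj[0] == -1
    assert np.all(adj[1:] < np.arange(1, len(adj)))
    assert np.all(adj[1:] >= 0)
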