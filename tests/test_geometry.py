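"""Contact geometry: the <60 nm apposition rule against closed forms and
the dense-sampling oracle."""

import numpy as np
import pytest

from neuromast.geometry import (GeometryConfig, SegmentationDefectError,
                                apical_contact_area, brute_force_contact_area,
                                contact_area, contact_length_on_section)
from neuromast.model import ContourTrace, NeuromastConnectome, HairCell
from neuromast.synthetic import generate_traces, random_polygon_pair

from conftest import square_trace

CFG = GeometryConfig()


def test_parallel_edges_match_closed_form():
    # facing edges of height 1000 at gap 50: per section the qualifying arc
    # is 1000 + 2*(60-50) on each cell, so the area is exact
    traces, ledger = generate_traces([500, 500], [50.0], height=1000, n_sections=10)
    expected = ledger.expected_area("C1", "C2", CFG)
    assert expected == (1000 + 2 * 10) * 30 * 10
    got = contact_area("C1", "C2", traces, CFG)
    tol = CFG.arc_sampling_step * CFG.section_thickness * 10  # one step/section
    assert abs(got.area - expected) <= tol
    assert got.per_section_lengths[0][0] == 0 and len(got.per_section_lengths) == 10


def test_gap_at_threshold_is_not_contact():
    # the rule is a strict inequality: exactly 60 nm apart is no contact
    traces, ledger = generate_traces([500, 500], [60.0], n_sections=3)
    assert contact_area("C1", "C2", traces, CFG).area == 0.0
    assert ledger.expected_area("C1", "C2", CFG) == 0.0
    just_under, _ = generate_traces([500, 500], [59.0], n_sections=3)
    assert contact_area("C1", "C2", just_under, CFG).area > 0.0


def test_gap_beyond_threshold_zero_everywhere():
    traces, ledger = generate_traces([400, 400], [70.0], n_sections=4)
    assert contact_area("C1", "C2", traces, CFG).area == 0.0
    assert brute_force_contact_area("C1", "C2", traces, CFG) == 0.0


@pytest.mark.parametrize("mode", ["strict", "corridor"])
def test_full_occlusion_blocks_contact(mode):
    cfg = GeometryConfig(occlusion_mode=mode)
    traces, ledger = generate_traces([500, 500], [50.0], n_sections=3,
                                     occluded_gaps=[0])
    assert ledger.expected_area("C1", "C2", cfg) == 0.0
    assert contact_area("C1", "C2", traces, cfg).area == 0.0


def test_corridor_mode_agrees_without_occluders():
    traces, _ = generate_traces([500, 500], [40.0], n_sections=2)
    strict = contact_area("C1", "C2", traces, GeometryConfig()).area
    corridor = contact_area("C1", "C2", traces,
                            GeometryConfig(occlusion_mode="corridor")).area
    assert strict == corridor > 0


def test_overlapping_polygons_are_segmentation_defect():
    a = square_trace("a", 0, 1000)
    b = square_trace("b", 0, 1000, x0=500.0)   # overlaps a
    with pytest.raises(SegmentationDefectError):
        contact_length_on_section(a, b, [], CFG)


def test_concentric_squares_near_inner_perimeter():
    # nested contours are legitimate topology; at gap 30 both the main
    # algorithm and the oracle stay within 2% of perimeter x thickness
    inner = [square_trace("in", s, 2000, x0=30.0, y0=30.0) for s in range(3)]
    outer = [square_trace("out", s, 2060) for s in range(3)]
    traces = {"in": inner, "out": outer}
    closed_form = 4 * 2000 * 30 * 3
    main = contact_area("in", "out", traces, CFG).area
    brute = brute_force_contact_area("in", "out", traces, CFG)
    assert abs(main - closed_form) / closed_form < 0.02
    assert abs(brute - closed_form) / closed_form < 0.02


def test_no_shared_sections_is_zero():
    traces = {"a": [square_trace("a", 0, 500)],
              "b": [square_trace("b", 5, 500, x0=520.0)]}
    assert contact_area("a", "b", traces, CFG).area == 0.0


def test_zero_threshold_gives_zero():
    traces, _ = generate_traces([400, 400], [10.0], n_sections=2)
    cfg = GeometryConfig(contact_threshold=0.0, arc_sampling_step=6.0)
    assert contact_area("C1", "C2", traces, cfg).area == 0.0
    assert brute_force_contact_area("C1", "C2", traces, cfg) == 0.0


def test_area_monotone_in_threshold():
    rng = np.random.default_rng(3)
    traces = random_polygon_pair(rng, 45.0)
    areas = []
    for thr in (20.0, 40.0, 60.0, 90.0):
        cfg = GeometryConfig(contact_threshold=thr, arc_sampling_step=6.0)
        areas.append(contact_area("A", "B", traces, cfg).area)
    assert areas == sorted(areas)


def test_rigid_transform_invariance():
    rng = np.random.default_rng(4)
    traces = random_polygon_pair(rng, 35.0)
    base = contact_area("A", "B", traces, CFG).area
    theta = 0.7
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    moved = {cid: [ContourTrace(cid, t.section_index,
                                t.vertices @ rot.T + np.array([1e4, -3e3]))
                   for t in ts] for cid, ts in traces.items()}
    transformed = contact_area("A", "B", moved, CFG).area
    assert transformed == pytest.approx(base, rel=0.02)


def test_contact_is_symmetric_in_arguments():
    rng = np.random.default_rng(5)
    traces = random_polygon_pair(rng, 30.0)
    ab = contact_area("A", "B", traces, CFG)
    ba = contact_area("B", "A", traces, CFG)
    assert ab.area == pytest.approx(ba.area, rel=1e-12)


def test_directed_lengths_near_symmetric_on_parallel_edges():
    traces, _ = generate_traces([600, 600], [40.0], height=1500, n_sections=1)
    la = contact_length_on_section(traces["C1"][0], traces["C2"][0], [], CFG)
    lb = contact_length_on_section(traces["C2"][0], traces["C1"][0], [], CFG)
    assert abs(la - lb) / max(la, lb) < 0.01


def test_apical_area_closed_form_and_absent_cell():
    conn = NeuromastConnectome("S", "wild-type")
    conn.haircells["H1"] = HairCell("H1", mature=True, age_class=">15h")
    conn.traces["H1"] = [square_trace("H1", s, 500) for s in range(8)]
    conn.apical_sections = frozenset(range(3, 8))   # 5 apical sections
    assert apical_contact_area("H1", conn, CFG) == 2000 * 5 * 30
    conn.apical_sections = frozenset({100})
    assert apical_contact_area("H1", conn, CFG) == 0.0


def test_config_validation():
    with pytest.raises(ValueError):
        GeometryConfig(arc_sampling_step=40.0)     # > threshold/2
    with pytest.raises(ValueError):
        GeometryConfig(section_thickness=-1.0)
    with pytest.raises(ValueError):
        GeometryConfig(occlusion_mode="fuzzy")
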