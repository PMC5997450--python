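"""Membrane contact areas from serial-section contour traces.

Two membranes on a section are in contact where their traces lie less than
a threshold apart (default 60 nm, the precision of manual tracing) and no
other trace intervenes between them.  Contact length is measured along the
trace by arc sampling at the lateral pixel pitch (6 nm); areas integrate
per-section lengths over the 30 nm section thickness.  Directed lengths
(a toward b, and b toward a) are averaged so the reported contact is
symmetric in the two cells.

Two occlusion modes are provided because "no other trace intervened" admits
more than one geometric reading: in ``strict`` mode a boundary point is
occluded when the straight segment to its nearest point on the other trace
crosses a third trace; in ``corridor`` mode the quadrilateral spanned by
neighbouring matched arcs must stay clear of third polygons.

A deliberately naive brute-force sampler (pure numpy, ≤1 nm steps,
exhaustive segment-crossing checks) is included as an independent oracle
for tests; it shares no code with the main shapely-based path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely
from scipy.spatial.distance import cdist
from shapely.geometry import LineString, Polygon

from .model import ContourTrace, MembraneContact, NeuromastConnectome

log = logging.getLogger("neuromast.geometry")


class SegmentationDefectError(ValueError):
    """Two annotated membranes intersect, which traced cells must not do."""


@dataclass(frozen=True)
class GeometryConfig:
    contact_threshold: float = 60.0   # nm; strict '<'
    section_thickness: float = 30.0   # nm
    arc_sampling_step: float = 6.0    # nm, the lateral pixel pitch
    occlusion_mode: str = "strict"    # or "corridor"

    def __post_init__(self) -> None:
        if self.contact_threshold < 0:
            raise ValueError("contact_threshold must be >= 0")
        if self.section_thickness <= 0 or self.arc_sampling_step <= 0:
            raise ValueError("thickness and sampling step must be positive")
        if self.contact_threshold > 0 and self.arc_sampling_step > self.contact_threshold / 2:
            raise ValueError("arc_sampling_step must be <= contact_threshold / 2")
        if self.occlusion_mode not in ("strict", "corridor"):
            raise ValueError(f"unknown occlusion_mode {self.occlusion_mode!r}")


# ---------------------------------------------------------------------------
# main algorithm (shapely)
# ---------------------------------------------------------------------------

def _check_disjoint(pa: Polygon, pb: Polygon, ida: str, idb: str) -> None:
    # Containment (one contour nested in another) is legitimate topology on a
    # section; partial interior overlap or shared boundary crossings are not.
    if pa.equals(pb) or pa.overlaps(pb) or pa.boundary.crosses(pb.boundary):
        raise SegmentationDefectError(
            f"contours of {ida} and {idb} intersect — segmentation defect")


def _sample_arc(poly: Polygon, step: float) -> tuple[np.ndarray, float]:
    """Uniform arc-length samples of the exterior ring; returns (points, weight)."""
    coords = np.asarray(poly.exterior.coords)
    seg = np.diff(coords, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    total = seglen.sum()
    n = max(int(np.ceil(total / step)), 8)
    s = np.arange(n) * total / n
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seglen) - 1)
    frac = (s - cum[idx]) / np.where(seglen[idx] > 0, seglen[idx], 1.0)
    pts = coords[idx] + seg[idx] * frac[:, None]
    return pts, total / n


def _directed_length(poly_a: Polygon, poly_b: Polygon,
                     others: Sequence[Polygon], config: GeometryConfig) -> float:
    """Arc length of poly_a's boundary in unoccluded contact with poly_b."""
    if config.contact_threshold == 0:
        return 0.0
    pts, weight = _sample_arc(poly_a, config.arc_sampling_step)
    points = shapely.points(pts)
    boundary_b = poly_b.exterior
    dist = shapely.distance(points, boundary_b)
    near = dist < config.contact_threshold
    if not near.any():
        return 0.0

    if not others:
        return float(near.sum()) * weight

    segs = shapely.shortest_line(points[near], boundary_b)
    clear = np.ones(len(segs), dtype=bool)
    if config.occlusion_mode == "strict":
        for other in others:
            clear &= ~shapely.intersects(segs, other.exterior)
    else:  # corridor
        # quadrilateral hull between the matched arcs of consecutive samples
        n = len(pts)
        near_idx = np.flatnonzero(near)
        pos = {i: k for k, i in enumerate(near_idx)}
        q = shapely.get_coordinates(shapely.get_point(segs, -1))
        p = pts[near_idx]
        for k, i in enumerate(near_idx):
            j = (i + 1) % n
            neighbours = []
            if j in pos:
                neighbours.append(pos[j])
            jm = (i - 1) % n
            if jm in pos:
                neighbours.append(pos[jm])
            if not neighbours:
                seg = segs[k]
                if any(shapely.intersects(seg, o.exterior) for o in others):
                    clear[k] = False
                continue
            blocked = True
            for k2 in neighbours:
                quad = shapely.convex_hull(
                    shapely.multipoints(np.vstack([p[[k, k2]], q[[k, k2]]])))
                if not any(o.intersection(quad).area > 1e-9
                           or shapely.crosses(o.exterior, quad) for o in others):
                    blocked = False
                    break
            clear[k] = not blocked
    return float(clear.sum()) * weight


def contact_length_on_section(trace_a: ContourTrace, trace_b: ContourTrace,
                              other_traces: Iterable[ContourTrace],
                              config: GeometryConfig | None = None) -> float:
    """Directed contact length (nm) of trace_a's boundary toward trace_b."""
    config = config or GeometryConfig()
    pa, pb = trace_a.polygon, trace_b.polygon
    _check_disjoint(pa, pb, trace_a.cell_id, trace_b.cell_id)
    others = [t.polygon for t in other_traces]
    return _directed_length(pa, pb, others, config)


def _section_traces(traces_by_cell: Mapping[str, Sequence[ContourTrace]]
                    ) -> dict[int, dict[str, list[ContourTrace]]]:
    out: dict[int, dict[str, list[ContourTrace]]] = {}
    for cid, traces in traces_by_cell.items():
        for tr in traces:
            out.setdefault(tr.section_index, {}).setdefault(cid, []).append(tr)
    return out


def contact_area(cell_a: str, cell_b: str,
                 traces_by_cell: Mapping[str, Sequence[ContourTrace]],
                 config: GeometryConfig | None = None) -> MembraneContact:
    """Symmetric membrane contact between two cells over all shared sections.

    Per section, the two directed contact lengths are averaged; the area is
    the sum of mean lengths times the section thickness.
    """
    config = config or GeometryConfig()
    by_section = _section_traces(traces_by_cell)
    per_section: list[tuple[int, float]] = []
    for sect in sorted(by_section):
        cells = by_section[sect]
        if cell_a not in cells or cell_b not in cells:
            continue
        others = [tr.polygon for cid, trs in cells.items()
                  for tr in trs if cid not in (cell_a, cell_b)]
        len_ab = len_ba = 0.0
        polys_a = [tr.polygon for tr in cells[cell_a]]
        polys_b = [tr.polygon for tr in cells[cell_b]]
        for pa in polys_a:
            for pb in polys_b:
                _check_disjoint(pa, pb, cell_a, cell_b)
        for pa in polys_a:
            for pb in polys_b:
                len_ab += _directed_length(pa, pb, others, config)
                len_ba += _directed_length(pb, pa, others, config)
        mean_len = 0.5 * (len_ab + len_ba)
        if mean_len > 0:
            per_section.append((sect, mean_len))
    area = sum(l for _, l in per_section) * config.section_thickness
    return MembraneContact(cell_a, cell_b, area, per_section)


# ---------------------------------------------------------------------------
# brute-force oracle (pure numpy; tests only)
# ---------------------------------------------------------------------------

def _dense_boundary(vertices: np.ndarray, step: float) -> np.ndarray:
    ring = np.vstack([vertices, vertices[:1]])
    seg = np.diff(ring, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    total = seglen.sum()
    n = max(int(np.ceil(total / step)), 16)
    s = np.arange(n) * total / n
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seglen) - 1)
    frac = (s - cum[idx]) / np.where(seglen[idx] > 0, seglen[idx], 1.0)
    return ring[idx] + seg[idx] * frac[:, None]


def _segments_cross(p1: np.ndarray, p2: np.ndarray,
                    q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Proper/improper intersection test, vectorized over the first axis of p
    and the first axis of q (broadcast to (len(p), len(q)))."""
    def orient(a, b, c):
        return ((b[..., 0] - a[..., 0]) * (c[..., 1] - a[..., 1])
                - (b[..., 1] - a[..., 1]) * (c[..., 0] - a[..., 0]))

    p1 = p1[:, None, :]
    p2 = p2[:, None, :]
    q1 = q1[None, :, :]
    q2 = q2[None, :, :]
    d1 = orient(q1, q2, p1)
    d2 = orient(q1, q2, p2)
    d3 = orient(p1, p2, q1)
    d4 = orient(p1, p2, q2)
    return ((d1 * d2) < 0) & ((d3 * d4) < 0)


def _directed_length_brute(pts_a: np.ndarray, pts_b: np.ndarray, weight_a: float,
                           other_edges: tuple[np.ndarray, np.ndarray] | None,
                           threshold: float) -> float:
    if threshold == 0:
        return 0.0
    total = 0.0
    chunk = 512
    for start in range(0, len(pts_a), chunk):
        block = pts_a[start:start + chunk]
        d = cdist(block, pts_b)
        jmin = np.argmin(d, axis=1)
        dmin = d[np.arange(len(block)), jmin]
        near = dmin < threshold
        if not near.any():
            continue
        if other_edges is not None and len(other_edges[0]):
            p = block[near]
            q = pts_b[jmin[near]]
            e1, e2 = other_edges
            crossed = _segments_cross(p, q, e1, e2).any(axis=1)
            total += float((~crossed).sum()) * weight_a
        else:
            total += float(near.sum()) * weight_a
    return total


def brute_force_contact_area(cell_a: str, cell_b: str,
                             traces_by_cell: Mapping[str, Sequence[ContourTrace]],
                             config: GeometryConfig | None = None,
                             step: float = 1.0) -> float:
    """Dense-sampling oracle with the same contract as :func:`contact_area`.

    O(n^2) per section; intended for tests and verification only.
    """
    config = config or GeometryConfig()
    if step > 1.0:
        raise ValueError("oracle sampling step must be <= 1 nm")
    by_section = _section_traces(traces_by_cell)
    area = 0.0
    for sect, cells in by_section.items():
        if cell_a not in cells or cell_b not in cells:
            continue
        edges1, edges2 = [], []
        for cid, trs in cells.items():
            if cid in (cell_a, cell_b):
                continue
            for tr in trs:
                ring = np.vstack([tr.vertices, tr.vertices[:1]])
                edges1.append(ring[:-1])
                edges2.append(ring[1:])
        other = ((np.vstack(edges1), np.vstack(edges2)) if edges1 else None)
        for tr_a in cells[cell_a]:
            for tr_b in cells[cell_b]:
                pa = _dense_boundary(tr_a.vertices, step)
                pb = _dense_boundary(tr_b.vertices, step)
                wa = tr_a.perimeter / len(pa)
                wb = tr_b.perimeter / len(pb)
                lab = _directed_length_brute(pa, pb, wa, other, config.contact_threshold)
                lba = _directed_length_brute(pb, pa, wb, other, config.contact_threshold)
                area += 0.5 * (lab + lba) * config.section_thickness
    return area


# ---------------------------------------------------------------------------
# apical surface
# ---------------------------------------------------------------------------

def apical_contact_area(cell_id: str, conn: NeuromastConnectome,
                        config: GeometryConfig | None = None) -> float:
    """Surface area a cell exposes at the epithelial apex.

    Sums the cell's trace perimeters over the connectome's annotated apical
    sections, times the section thickness.  Nascent cells that have not yet
    reached the surface return 0 (with a warning).
    """
    config = config or GeometryConfig()
    traces = conn.traces.get(cell_id, [])
    apical = conn.apical_sections
    total = 0.0
    for tr in traces:
        if tr.section_index in apical:
            total += tr.perimeter * config.section_thickness
    if total == 0.0:
        log.warning("cell %s absent from apical sections of %s",
                    cell_id, conn.specimen_id)
    return total


def compute_all_contacts(conn: NeuromastConnectome,
                         config: GeometryConfig | None = None,
                         pairs: Iterable[tuple[str, str]] | None = None) -> None:
    """Populate ``conn.contacts`` for hair-cell x terminal pairs from traces."""
    config = config or GeometryConfig()
    if pairs is None:
        pairs = [(h, t) for h in conn.haircells for t in conn.terminals]
    conn.contacts = {}
    for a, b in pairs:
        if a not in conn.traces or b not in conn.traces:
            continue
        c = contact_area(a, b, conn.traces, config)
        if c.area > 0:
            conn.add_contact(c)
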