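"""Domain model for lateral-line neuromast connectomes.

A neuromast is a discrete sense organ of the fish lateral line containing
mechanosensory hair cells of two opposing directional sensitivities
(rostrad / caudad), innervated by afferent axonal terminals and usually one
efferent terminal.  This module defines the in-memory representation of one
reconstructed specimen — hair cells, terminals, ribbon synapses, membrane
contacts and perisynaptic associations — together with validation, the
tab-separated annotation-table schema, and GraphML export of the bipartite
wiring diagram.

Coordinate conventions: all lengths in nanometres; x increases caudad
(anterior of the animal to the left); sections are indexed from 0 and each
section is 30 nm thick by default.  "rostrad"/"caudad" always name the
direction of mechanical sensitivity, never a cell's position; a cell's
anteroposterior position relative to its sibling is the separate
``ap_position`` field.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import networkx as nx
from shapely.geometry import Polygon

log = logging.getLogger("neuromast.model")

SECTION_THICKNESS_NM = 30.0
PIXEL_PITCH_NM = 6.0

POLARITIES = ("rostrad", "caudad", "undetermined")
AP_POSITIONS = ("anterior", "posterior", "unresolved")
AGE_CLASSES = ("0-5h", "5-15h", ">15h", "unknown")
AGE_SOURCES = ("preimaged", "classified")
TERMINAL_KINDS = ("afferent", "efferent", "unclassified")
STRUCTURAL_FLAGS = ("vesicle-filled bouton", "postsynaptic cistern")
GENOTYPES = ("wild-type", "trilobite", "notch-overexpression")

TABLE_FILES = ("cells.tsv", "traces.tsv", "ribbons.tsv", "associations.tsv")


class LoadError(ValueError):
    """Raised when annotation tables are malformed; carries the offending context."""

    def __init__(self, message: str, *, table: str | None = None,
                 row: object | None = None, entity: str | None = None):
        parts = [message]
        if table:
            parts.append(f"table={table}")
        if row is not None:
            parts.append(f"row={row}")
        if entity is not None:
            parts.append(f"entity={entity}")
        super().__init__(" | ".join(parts))
        self.table = table
        self.row = row
        self.entity = entity


class AnnotationStateError(RuntimeError):
    """An operation required a stage (contacts, classification) that has not run."""


@dataclass
class Violation:
    entity: str
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.rule}] {self.entity}: {self.message}"


def _normalize_ring(vertices: np.ndarray) -> np.ndarray:
    """Drop a duplicated closing vertex and orient the ring counter-clockwise."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2:
        raise ValueError("vertices must be an (n, 2) array")
    if len(v) >= 2 and np.allclose(v[0], v[-1]):
        v = v[:-1]
    if len(v) < 3:
        raise ValueError("a contour needs at least 3 distinct vertices")
    # signed area (shoelace); CCW is positive
    x, y = v[:, 0], v[:, 1]
    area2 = np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))
    if area2 < 0:
        v = v[::-1]
    return v


@dataclass
class ContourTrace:
    """Closed membrane outline of one cell on one section (vertices in nm)."""

    cell_id: str
    section_index: int
    vertices: np.ndarray
    section_thickness: float = SECTION_THICKNESS_NM

    def __post_init__(self) -> None:
        if self.section_index < 0:
            raise ValueError(f"negative section index for {self.cell_id}")
        self.vertices = _normalize_ring(self.vertices)
        poly = Polygon(self.vertices)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError(
                f"contour of {self.cell_id} on section {self.section_index} "
                "is not a simple polygon"
            )

    @property
    def z(self) -> float:
        return self.section_index * self.section_thickness

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.vertices, self.vertices[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    @property
    def area(self) -> float:
        return float(self.polygon.area)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ContourTrace):
            return NotImplemented
        return (self.cell_id == other.cell_id
                and self.section_index == other.section_index
                and np.array_equal(self.vertices, other.vertices)
                and self.section_thickness == other.section_thickness)


@dataclass
class HairCell:
    cell_id: str
    polarity: str = "undetermined"
    ap_position: str = "unresolved"
    sibling_id: str | None = None
    age_class: str = "unknown"
    age_source: str = "preimaged"
    mature: bool = False

    def __post_init__(self) -> None:
        if self.polarity not in POLARITIES:
            raise ValueError(f"{self.cell_id}: unknown polarity {self.polarity!r}")
        if self.ap_position not in AP_POSITIONS:
            raise ValueError(f"{self.cell_id}: unknown ap_position {self.ap_position!r}")
        if self.age_class not in AGE_CLASSES:
            raise ValueError(f"{self.cell_id}: unknown age_class {self.age_class!r}")
        if self.age_source not in AGE_SOURCES:
            raise ValueError(f"{self.cell_id}: unknown age_source {self.age_source!r}")


@dataclass
class Terminal:
    terminal_id: str
    kind: str = "unclassified"
    enters_neuromast: bool = True
    structural_flags: frozenset[str] = frozenset()
    polarity_preference: str = "unassigned"

    def __post_init__(self) -> None:
        if self.kind not in TERMINAL_KINDS:
            raise ValueError(f"{self.terminal_id}: unknown kind {self.kind!r}")
        self.structural_flags = frozenset(self.structural_flags)
        unknown = self.structural_flags - set(STRUCTURAL_FLAGS)
        if unknown:
            raise ValueError(f"{self.terminal_id}: unknown structural flags {sorted(unknown)}")


@dataclass
class RibbonSynapse:
    """One presynaptic active zone with its apposed terminals.

    ``appositions`` maps each candidate terminal to its apposed membrane
    area (an input annotation); ``assignments`` is the derived partner list
    with weights summing to 1 (a whole ribbon, or two halves when two
    terminals occupy the apposed area equally).
    """

    ribbon_id: str
    haircell_id: str
    appositions: dict[str, float] = field(default_factory=dict)
    assignments: list[tuple[str, float]] = field(default_factory=list)
    volume_nm3: float = 0.0
    unpartnered: bool = False

    def weight_for(self, terminal_id: str) -> float:
        return sum(w for t, w in self.assignments if t == terminal_id)

    @property
    def total_weight(self) -> float:
        return sum(w for _, w in self.assignments)


@dataclass
class MembraneContact:
    cell_a: str
    cell_b: str
    area: float
    per_section_lengths: list[tuple[int, float]] = field(default_factory=list)

    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.cell_a, self.cell_b)))  # type: ignore[return-value]


@dataclass
class NeuromastConnectome:
    """One reconstructed specimen: the unit every statistic consumes."""

    specimen_id: str
    genotype: str = "wild-type"
    haircells: dict[str, HairCell] = field(default_factory=dict)
    terminals: dict[str, Terminal] = field(default_factory=dict)
    ribbons: dict[str, RibbonSynapse] = field(default_factory=dict)
    contacts: dict[tuple[str, str], MembraneContact] | None = None
    perisynaptic: set[tuple[str, str]] = field(default_factory=set)
    traces: dict[str, list[ContourTrace]] = field(default_factory=dict)
    apical_sections: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        self.apical_sections = frozenset(self.apical_sections)

    # -- convenience accessors -------------------------------------------------

    def mature_haircells(self) -> list[HairCell]:
        return [hc for hc in self.haircells.values() if hc.mature]

    def entering_terminals(self) -> list[Terminal]:
        return [t for t in self.terminals.values() if t.enters_neuromast]

    def contact_area(self, a: str, b: str) -> float:
        if self.contacts is None:
            return 0.0
        c = self.contacts.get(tuple(sorted((a, b))))
        return c.area if c else 0.0

    def contacts_of(self, entity_id: str) -> dict[str, float]:
        """Map partner id -> contact area for one cell or terminal."""
        out: dict[str, float] = {}
        if self.contacts is None:
            return out
        for (a, b), c in self.contacts.items():
            if a == entity_id:
                out[b] = out.get(b, 0.0) + c.area
            elif b == entity_id:
                out[a] = out.get(a, 0.0) + c.area
        return out

    def ribbons_of_cell(self, cell_id: str) -> list[RibbonSynapse]:
        return [r for r in self.ribbons.values() if r.haircell_id == cell_id]

    def add_contact(self, contact: MembraneContact) -> None:
        if self.contacts is None:
            self.contacts = {}
        key = contact.key()
        if (contact.cell_a, contact.cell_b) != key:
            contact = MembraneContact(key[0], key[1], contact.area,
                                      contact.per_section_lengths)
        prev = self.contacts.get(key)
        if prev is None:
            self.contacts[key] = contact
        else:
            prev.area += contact.area
            prev.per_section_lengths.extend(contact.per_section_lengths)

    def sibling_pairs(self) -> list[tuple[str, str]]:
        seen: set[tuple[str, str]] = set()
        for hc in self.haircells.values():
            if hc.sibling_id:
                seen.add(tuple(sorted((hc.cell_id, hc.sibling_id))))  # type: ignore[arg-type]
        return sorted(seen)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate(conn: NeuromastConnectome) -> list[Violation]:
    """Check every type invariant; violations are returned, never raised."""
    out: list[Violation] = []

    for hc in conn.haircells.values():
        if hc.sibling_id is not None:
            if hc.sibling_id == hc.cell_id:
                out.append(Violation(hc.cell_id, "sibling-irreflexive",
                                     "cell is its own sibling"))
            else:
                sib = conn.haircells.get(hc.sibling_id)
                if sib is None:
                    out.append(Violation(hc.cell_id, "sibling-exists",
                                         f"sibling {hc.sibling_id} not in connectome"))
                elif sib.sibling_id != hc.cell_id:
                    out.append(Violation(hc.cell_id, "sibling-symmetric",
                                         f"{hc.sibling_id} does not link back"))

    for rib in conn.ribbons.values():
        if rib.haircell_id not in conn.haircells:
            out.append(Violation(rib.ribbon_id, "ribbon-haircell-exists",
                                 f"hair cell {rib.haircell_id} unknown"))
        for tid in rib.appositions:
            if tid not in conn.terminals:
                out.append(Violation(rib.ribbon_id, "ribbon-terminal-exists",
                                     f"apposed terminal {tid} unknown"))
        if rib.assignments:
            total = sum(w for _, w in rib.assignments)
            if abs(total - 1.0) > 1e-9:
                out.append(Violation(rib.ribbon_id, "ribbon-weights-sum",
                                     f"weights sum to {total}, not 1"))
            if len(rib.assignments) > 2:
                out.append(Violation(rib.ribbon_id, "ribbon-max-two-partners",
                                     f"{len(rib.assignments)} assignees"))
            for tid, w in rib.assignments:
                if w not in (1.0, 0.5):
                    out.append(Violation(rib.ribbon_id, "ribbon-weight-values",
                                         f"weight {w} not in {{1.0, 0.5}}"))
                term = conn.terminals.get(tid)
                if term is None:
                    out.append(Violation(rib.ribbon_id, "ribbon-terminal-exists",
                                         f"assigned terminal {tid} unknown"))
                elif term.kind == "efferent":
                    out.append(Violation(rib.ribbon_id, "ribbon-not-efferent",
                                         f"assigned to efferent terminal {tid}"))
        if rib.volume_nm3 < 0:
            out.append(Violation(rib.ribbon_id, "ribbon-volume-nonneg",
                                 f"volume {rib.volume_nm3}"))

    if conn.contacts is not None:
        for key, c in conn.contacts.items():
            for cid in key:
                if cid not in conn.haircells and cid not in conn.terminals:
                    out.append(Violation(f"{key[0]}~{key[1]}", "contact-ids-exist",
                                         f"{cid} unknown"))
            if c.area < 0:
                out.append(Violation(f"{key[0]}~{key[1]}", "contact-area-nonneg",
                                     f"area {c.area}"))
            if c.per_section_lengths:
                thick = SECTION_THICKNESS_NM
                expect = sum(l for _, l in c.per_section_lengths) * thick
                if not np.isclose(expect, c.area, rtol=1e-6, atol=1e-6):
                    out.append(Violation(f"{key[0]}~{key[1]}", "contact-area-consistent",
                                         f"area {c.area} != sum lengths x thickness {expect}"))

    for hc_id, t_id in conn.perisynaptic:
        if hc_id not in conn.haircells:
            out.append(Violation(f"{hc_id}~{t_id}", "perisynaptic-haircell-exists",
                                 f"{hc_id} unknown"))
        if t_id not in conn.terminals:
            out.append(Violation(f"{hc_id}~{t_id}", "perisynaptic-terminal-exists",
                                 f"{t_id} unknown"))

    for cid in conn.traces:
        if cid not in conn.haircells and cid not in conn.terminals:
            out.append(Violation(cid, "trace-owner-exists", "traced id unknown"))

    return out


# ---------------------------------------------------------------------------
# TSV annotation-table I/O
# ---------------------------------------------------------------------------

_CELL_COLUMNS = ["specimen_id", "genotype", "apical_sections", "entity_id",
                 "entity_class", "polarity", "ap_position", "sibling_id",
                 "age_class", "age_source", "mature", "kind",
                 "enters_neuromast", "structural_flags", "polarity_preference"]
_TRACE_COLUMNS = ["cell_id", "section_index", "vertex_index", "x_nm", "y_nm"]
_RIBBON_COLUMNS = ["ribbon_id", "haircell_id", "terminal_id",
                   "apposition_area_nm2", "weight", "ribbon_volume_nm3"]
_ASSOC_COLUMNS = ["cell_a", "cell_b", "assoc_type", "area_nm2", "per_section"]


def _resolve_paths(paths: str | Path | Mapping[str, Path]) -> dict[str, Path]:
    if isinstance(paths, (str, Path)):
        base = Path(paths)
        return {name.split(".")[0]: base / name for name in TABLE_FILES}
    return {k: Path(v) for k, v in paths.items()}


def _require_columns(df: pd.DataFrame, cols: Sequence[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise LoadError(f"missing columns {missing}", table=table)


def _opt(value: object) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return str(value)


def _parse_bool(value: object, table: str, row: object) -> bool:
    s = str(value).strip().lower()
    if s in ("true", "1"):
        return True
    if s in ("false", "0"):
        return False
    raise LoadError(f"cannot parse boolean {value!r}", table=table, row=row)


def load_annotation_tables(paths: str | Path | Mapping[str, Path],
                           config: Mapping | None = None) -> NeuromastConnectome:
    """Load the four-file TSV schema into a validated connectome.

    ``paths`` is a directory containing cells.tsv / traces.tsv / ribbons.tsv /
    associations.tsv, or a mapping of those stem names to file paths.
    Referential integrity and contour simplicity are enforced here; derived
    fields that annotation or geometry stages produce are loaded verbatim if
    present (so generator round-trips are exact) and otherwise left unset.
    """
    files = _resolve_paths(paths)
    frames: dict[str, pd.DataFrame] = {}
    for stem in ("cells", "traces", "ribbons", "associations"):
        path = files.get(stem)
        if path is None or not Path(path).exists():
            raise LoadError("table file missing", table=stem)
        frames[stem] = pd.read_csv(path, sep="\t", dtype=str,
                                   keep_default_na=False, na_values=[""])

    cells = frames["cells"]
    _require_columns(cells, _CELL_COLUMNS, "cells")
    if cells.empty:
        raise LoadError("cells.tsv has no rows", table="cells")

    specimen_id = str(cells["specimen_id"].iloc[0])
    genotype = str(cells["genotype"].iloc[0])
    apical_raw = _opt(cells["apical_sections"].iloc[0])
    apical = frozenset(int(s) for s in apical_raw.split(";")) if apical_raw else frozenset()

    conn = NeuromastConnectome(specimen_id=specimen_id, genotype=genotype,
                               apical_sections=apical)

    for idx, row in cells.iterrows():
        eid = str(row["entity_id"])
        cls = str(row["entity_class"])
        try:
            if cls == "haircell":
                conn.haircells[eid] = HairCell(
                    cell_id=eid,
                    polarity=_opt(row["polarity"]) or "undetermined",
                    ap_position=_opt(row["ap_position"]) or "unresolved",
                    sibling_id=_opt(row["sibling_id"]),
                    age_class=_opt(row["age_class"]) or "unknown",
                    age_source=_opt(row["age_source"]) or "preimaged",
                    mature=_parse_bool(row["mature"], "cells", idx),
                )
            elif cls == "terminal":
                flags_raw = _opt(row["structural_flags"])
                flags = frozenset(f for f in flags_raw.split(";") if f) if flags_raw else frozenset()
                conn.terminals[eid] = Terminal(
                    terminal_id=eid,
                    kind=_opt(row["kind"]) or "unclassified",
                    enters_neuromast=_parse_bool(row["enters_neuromast"], "cells", idx),
                    structural_flags=flags,
                    polarity_preference=_opt(row["polarity_preference"]) or "unassigned",
                )
            else:
                raise LoadError(f"unknown entity_class {cls!r}", table="cells",
                                row=idx, entity=eid)
        except ValueError as exc:
            if isinstance(exc, LoadError):
                raise
            raise LoadError(str(exc), table="cells", row=idx, entity=eid) from exc

    traces = frames["traces"]
    _require_columns(traces, _TRACE_COLUMNS, "traces")
    if not traces.empty:
        traces = traces.astype({"section_index": int, "vertex_index": int,
                                "x_nm": float, "y_nm": float})
        for (cid, sect), grp in traces.groupby(["cell_id", "section_index"], sort=True):
            grp = grp.sort_values("vertex_index")
            verts = grp[["x_nm", "y_nm"]].to_numpy()
            if cid not in conn.haircells and cid not in conn.terminals:
                raise LoadError("trace references unknown cell", table="traces",
                                entity=f"{cid}@{sect}")
            try:
                trace = ContourTrace(str(cid), int(sect), verts)
            except ValueError as exc:
                raise LoadError(str(exc), table="traces",
                                entity=f"{cid}@{sect}") from exc
            conn.traces.setdefault(str(cid), []).append(trace)
        for lst in conn.traces.values():
            lst.sort(key=lambda t: t.section_index)

    ribbons = frames["ribbons"]
    _require_columns(ribbons, _RIBBON_COLUMNS, "ribbons")
    if not ribbons.empty:
        for rid, grp in ribbons.groupby("ribbon_id", sort=True):
            hc_ids = set(grp["haircell_id"])
            if len(hc_ids) != 1:
                raise LoadError("ribbon rows disagree on hair cell", table="ribbons",
                                entity=str(rid))
            hc_id = hc_ids.pop()
            if hc_id not in conn.haircells:
                raise LoadError(f"ribbon references unknown hair cell {hc_id}",
                                table="ribbons", entity=str(rid))
            vol = float(grp["ribbon_volume_nm3"].iloc[0]) if _opt(grp["ribbon_volume_nm3"].iloc[0]) else 0.0
            rib = RibbonSynapse(ribbon_id=str(rid), haircell_id=str(hc_id),
                                volume_nm3=vol)
            for idx, row in grp.iterrows():
                tid = _opt(row["terminal_id"])
                if tid is None:
                    rib.unpartnered = True
                    continue
                if tid not in conn.terminals:
                    raise LoadError(f"ribbon references unknown terminal {tid}",
                                    table="ribbons", row=idx, entity=str(rid))
                area = _opt(row["apposition_area_nm2"])
                if area is not None:
                    rib.appositions[tid] = float(area)
                w = _opt(row["weight"])
                if w is not None:
                    rib.assignments.append((tid, float(w)))
            if not rib.appositions and not rib.assignments:
                rib.unpartnered = True
            conn.ribbons[str(rid)] = rib

    assoc = frames["associations"]
    _require_columns(assoc, _ASSOC_COLUMNS, "associations")
    if not assoc.empty:
        for idx, row in assoc.iterrows():
            a, b = str(row["cell_a"]), str(row["cell_b"])
            for cid in (a, b):
                if cid not in conn.haircells and cid not in conn.terminals:
                    raise LoadError(f"association references unknown id {cid}",
                                    table="associations", row=idx, entity=f"{a}~{b}")
            kind = str(row["assoc_type"])
            if kind == "perisynaptic":
                conn.perisynaptic.add((a, b))
            elif kind == "contact":
                per_section: list[tuple[int, float]] = []
                raw = _opt(row["per_section"])
                if raw:
                    for item in raw.split(";"):
                        s, l = item.split(":")
                        per_section.append((int(s), float(l)))
                area = float(row["area_nm2"])
                conn.add_contact(MembraneContact(a, b, area, per_section))
            else:
                raise LoadError(f"unknown assoc_type {kind!r}", table="associations",
                                row=idx)

    return conn


def write_connectome_tables(conn: NeuromastConnectome, outdir: str | Path) -> dict[str, Path]:
    """Write the four-file TSV schema; inverse of :func:`load_annotation_tables`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    apical = ";".join(str(s) for s in sorted(conn.apical_sections))

    cell_rows = []
    for hc in sorted(conn.haircells.values(), key=lambda c: c.cell_id):
        cell_rows.append(dict(specimen_id=conn.specimen_id, genotype=conn.genotype,
                              apical_sections=apical, entity_id=hc.cell_id,
                              entity_class="haircell", polarity=hc.polarity,
                              ap_position=hc.ap_position,
                              sibling_id=hc.sibling_id or "",
                              age_class=hc.age_class, age_source=hc.age_source,
                              mature=str(hc.mature).lower(), kind="",
                              enters_neuromast="", structural_flags="",
                              polarity_preference=""))
    for t in sorted(conn.terminals.values(), key=lambda t: t.terminal_id):
        cell_rows.append(dict(specimen_id=conn.specimen_id, genotype=conn.genotype,
                              apical_sections=apical, entity_id=t.terminal_id,
                              entity_class="terminal", polarity="", ap_position="",
                              sibling_id="", age_class="", age_source="",
                              mature="", kind=t.kind,
                              enters_neuromast=str(t.enters_neuromast).lower(),
                              structural_flags=";".join(sorted(t.structural_flags)),
                              polarity_preference=t.polarity_preference))
    cells_df = pd.DataFrame(cell_rows, columns=_CELL_COLUMNS)

    trace_rows = []
    for cid in sorted(conn.traces):
        for tr in conn.traces[cid]:
            for vi, (x, y) in enumerate(tr.vertices):
                trace_rows.append(dict(cell_id=cid, section_index=tr.section_index,
                                       vertex_index=vi, x_nm=repr(float(x)),
                                       y_nm=repr(float(y))))
    traces_df = pd.DataFrame(trace_rows, columns=_TRACE_COLUMNS)

    ribbon_rows = []
    for rid in sorted(conn.ribbons):
        rib = conn.ribbons[rid]
        weights = dict(rib.assignments)
        tids = sorted(set(rib.appositions) | set(weights))
        if not tids:
            ribbon_rows.append(dict(ribbon_id=rid, haircell_id=rib.haircell_id,
                                    terminal_id="", apposition_area_nm2="",
                                    weight="", ribbon_volume_nm3=repr(rib.volume_nm3)))
        for tid in tids:
            area = rib.appositions.get(tid)
            w = weights.get(tid)
            ribbon_rows.append(dict(ribbon_id=rid, haircell_id=rib.haircell_id,
                                    terminal_id=tid,
                                    apposition_area_nm2="" if area is None else repr(area),
                                    weight="" if w is None else repr(w),
                                    ribbon_volume_nm3=repr(rib.volume_nm3)))
    ribbons_df = pd.DataFrame(ribbon_rows, columns=_RIBBON_COLUMNS)

    assoc_rows = []
    if conn.contacts:
        for key in sorted(conn.contacts):
            c = conn.contacts[key]
            per = ";".join(f"{s}:{repr(l)}" for s, l in c.per_section_lengths)
            assoc_rows.append(dict(cell_a=key[0], cell_b=key[1], assoc_type="contact",
                                   area_nm2=repr(c.area), per_section=per))
    for a, b in sorted(conn.perisynaptic):
        assoc_rows.append(dict(cell_a=a, cell_b=b, assoc_type="perisynaptic",
                               area_nm2="", per_section=""))
    assoc_df = pd.DataFrame(assoc_rows, columns=_ASSOC_COLUMNS)

    paths = {}
    for stem, df in (("cells", cells_df), ("traces", traces_df),
                     ("ribbons", ribbons_df), ("associations", assoc_df)):
        path = outdir / f"{stem}.tsv"
        df.to_csv(path, sep="\t", index=False)
        paths[stem] = path
    return paths


# ---------------------------------------------------------------------------
# GraphML export
# ---------------------------------------------------------------------------

def to_graph(conn: NeuromastConnectome) -> nx.MultiGraph:
    """Bipartite multigraph of hair cells vs terminals with typed edges."""
    unclassified = [t.terminal_id for t in conn.terminals.values()
                    if t.kind == "unclassified"]
    if unclassified:
        raise AnnotationStateError(
            f"connectome not annotated: unclassified terminals {unclassified[:5]}")
    g = nx.MultiGraph(specimen_id=conn.specimen_id, genotype=conn.genotype)
    for hc in conn.haircells.values():
        g.add_node(hc.cell_id, bipartite="haircell", polarity=hc.polarity,
                   ap_position=hc.ap_position, age_class=hc.age_class,
                   mature=hc.mature, sibling_id=hc.sibling_id or "")
    for t in conn.terminals.values():
        g.add_node(t.terminal_id, bipartite="terminal", kind=t.kind,
                   enters_neuromast=t.enters_neuromast,
                   polarity_preference=t.polarity_preference)
    for rib in conn.ribbons.values():
        for tid, w in rib.assignments:
            g.add_edge(rib.haircell_id, tid, edge_type="ribbon", weight=float(w),
                       ribbon_id=rib.ribbon_id)
    if conn.contacts:
        for key in sorted(conn.contacts):
            c = conn.contacts[key]
            g.add_edge(key[0], key[1], edge_type="contact", area_nm2=float(c.area))
    for a, b in sorted(conn.perisynaptic):
        g.add_edge(a, b, edge_type="perisynaptic")
    return g


def write_connectome_graph(conn: NeuromastConnectome, path: str | Path) -> Path:
    """Serialize the Fig-3-style wiring diagram as GraphML."""
    g = to_graph(conn)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(g, path)
    return path
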