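"""Synthetic neuromast connectomes and contour fixtures with planted truth.

Every pipeline stage can be exercised without the original EM volumes:
the generator emits the same annotation-table schema the loaders consume,
and a ground-truth ledger records every random draw (planted terminal
identities, per-ribbon match flags, dominance weights, sibling identities,
closed-form contact areas for trace fixtures) so recovery can be asserted
exactly or within sampling error.

Genotype wiring rules
---------------------
wild-type
    Sibling hair cells adopt opposite polarities; the more anterior cell is
    caudad-sensitive, the posterior one rostrad-sensitive; innervation
    identity follows polarity (and hence position).
trilobite (vangl2 inactivated)
    Hair bundles orient randomly; the two innervation identities are still
    allocated uniquely within each sibling pair but land on the
    anterior/posterior positions at random.
notch-overexpression (NICD)
    All mature hair cells are rostrad-polarized; both siblings of a pair
    carry the *same* innervation identity, and every ribbon-partner
    terminal of a cell also contacts the sibling, so sibling pairs always
    share innervation.

Within a polarity pool, each ribbon chooses its terminal independently
according to a dominance simplex (default 0.55/0.30/0.10/0.05, padded with
zeros for larger pools), flattened for 5-15 h cells whose innervation is
still diffuse.  With probability ``specificity_error`` a ribbon is flipped
to the opposite pool (the default is the observed rate, 4 of 344).  After the
allocation the generator tops up each active terminal with matched ribbons
until its matched weight strictly exceeds any flipped weight, so that the
derived polarity preference of every active terminal equals its planted
identity by construction and planted mismatch counts are recovered exactly
by the statistics stage; the forced draws are recorded in the ledger.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely
from shapely import affinity
from shapely.geometry import Polygon

from .annotation import AnnotationConfig, annotate
from .geometry import GeometryConfig
from .model import (ContourTrace, HairCell, MembraneContact,
                    NeuromastConnectome, RibbonSynapse, STRUCTURAL_FLAGS,
                    Terminal)

IDENTITIES = ("caudad", "rostrad")


@dataclass
class GenotypeModel:
    """Wiring-statistics model for one genotype.

    Defaults are the printed study conditions: 8-20 hair cells per organ
    (5-7 sibling pairs), ~9 afferent branches plus one efferent, a
    specificity error of 4/344 ribbons, 8 % off-polarity contact area, a
    0.55/0.30/0.10/0.05 dominance profile, and roughly one synaptic partner
    per 5-15 h cell growing to two after 15 h.
    """

    genotype: str = "wild-type"
    n_haircell_pairs: int | None = None       # None -> draw 5-7 per organ
    n_afferents: int = 9
    specificity_error: float = 4.0 / 344.0
    contact_area_error: float = 0.08
    dominance_weights: tuple[float, ...] = (0.55, 0.30, 0.10, 0.05)
    partners_per_cell: Mapping[str, float] = field(
        default_factory=lambda: {"5-15h": 1.0, ">15h": 2.0})
    ribbons_per_cell: Mapping[str, tuple[int, float]] = field(
        default_factory=lambda: {"5-15h": (1, 1.0), ">15h": (2, 2.0)})
    age_mix: tuple[float, float, float] = (0.20, 0.35, 0.45)  # 0-5h, 5-15h, >15h
    allocation: str = "dominance"             # or "poisson-partners"
    perisynaptic_rate: float = 0.5
    split_ribbon_rate: float = 0.10
    extra_apposition_rate: float = 0.15
    young_dominance_flatten: float = 0.4      # exponent on weights for 5-15 h cells
    n_nonentering: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.specificity_error <= 1.0):
            raise ValueError("specificity_error must lie in [0, 1]")
        if not (0.0 <= self.contact_area_error < 1.0):
            raise ValueError("contact_area_error must lie in [0, 1)")
        w = np.asarray(self.dominance_weights, dtype=float)
        if (w < 0).any() or not math.isclose(w.sum(), 1.0, rel_tol=1e-9):
            raise ValueError("dominance_weights must be a simplex")
        n_nonzero = int((w > 0).sum())
        if n_nonzero > 1 and self.n_afferents < 4:
            raise ValueError("need at least 2 afferents per identity for a "
                             "multi-terminal dominance profile")
        if abs(sum(self.age_mix) - 1.0) > 1e-9:
            raise ValueError("age_mix must sum to 1")
        if self.allocation not in ("dominance", "poisson-partners"):
            raise ValueError(f"unknown allocation {self.allocation!r}")


@dataclass
class GroundTruthLedger:
    """Record of every planted quantity in one generated connectome."""

    seed: int
    genotype: str
    cell_identity: dict[str, str | None] = field(default_factory=dict)
    terminal_identity: dict[str, str] = field(default_factory=dict)
    terminal_weight: dict[str, float] = field(default_factory=dict)
    terminal_rank: dict[str, int] = field(default_factory=dict)
    dominance_weights: dict[str, list[float]] = field(default_factory=dict)
    ribbon_match: dict[str, bool] = field(default_factory=dict)
    ribbon_forced: dict[str, bool] = field(default_factory=dict)
    planted_partner_counts: dict[str, int] = field(default_factory=dict)
    sibling_identity: dict[str, str] = field(default_factory=dict)
    efferent_id: str | None = None
    bundle_angles: dict[str, float] = field(default_factory=dict)

    @property
    def n_flipped(self) -> int:
        return sum(1 for ok in self.ribbon_match.values() if not ok)

    @property
    def mismatch_weight(self) -> float:
        # each flipped ribbon carries its full unit weight into the
        # opposite pool, split or not
        return float(self.n_flipped)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {k: v for k, v in self.__dict__.items()}
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _pool_weights(model: GenotypeModel, pool_size: int) -> np.ndarray:
    w = np.zeros(pool_size)
    base = np.asarray(model.dominance_weights, dtype=float)
    k = min(pool_size, len(base))
    w[:k] = base[:k]
    if w.sum() == 0:
        raise ValueError("dominance weights vanish for this pool size")
    return w / w.sum()


def _flatten(w: np.ndarray, exponent: float) -> np.ndarray:
    out = np.where(w > 0, w ** exponent, 0.0)
    return out / out.sum()


def generate_connectome(model: GenotypeModel, seed: int
                        ) -> tuple[NeuromastConnectome, GroundTruthLedger]:
    """Generate one annotated connectome and its ground-truth ledger.

    Identical (model, seed) pairs give identical output.  The emitted
    connectome is fully annotated (ribbon weights, terminal kinds) and
    passes validation.
    """
    rng = np.random.default_rng(seed)
    ledger = GroundTruthLedger(seed=seed, genotype=model.genotype)
    conn = NeuromastConnectome(specimen_id=f"SYN-{model.genotype}-{seed}",
                               genotype=model.genotype)

    n_pairs = model.n_haircell_pairs or int(rng.integers(5, 8))

    # --- terminals -------------------------------------------------------
    pool_sizes = {"caudad": (model.n_afferents + 1) // 2,
                  "rostrad": model.n_afferents // 2}
    pools: dict[str, list[str]] = {}
    i = 0
    for identity in IDENTITIES:
        ids = []
        for rank in range(pool_sizes[identity]):
            i += 1
            tid = f"A{i:02d}"
            conn.terminals[tid] = Terminal(tid, kind="afferent")
            ledger.terminal_identity[tid] = identity
            ledger.terminal_rank[tid] = rank
            ids.append(tid)
        pools[identity] = ids
        w = _pool_weights(model, len(ids))
        ledger.dominance_weights[identity] = w.tolist()
        for tid, weight in zip(ids, w):
            ledger.terminal_weight[tid] = float(weight)
    eff_id = "EFF"
    conn.terminals[eff_id] = Terminal(eff_id, kind="efferent",
                                      structural_flags=frozenset(STRUCTURAL_FLAGS))
    ledger.terminal_identity[eff_id] = "efferent"
    ledger.efferent_id = eff_id
    for j in range(model.n_nonentering):
        tid = f"NE{j + 1:02d}"
        conn.terminals[tid] = Terminal(tid, kind="afferent", enters_neuromast=False)
        ledger.terminal_identity[tid] = "non-entering"

    # --- hair cells in sibling pairs ------------------------------------
    age_labels = ("0-5h", "5-15h", ">15h")
    for p in range(n_pairs):
        age = age_labels[int(rng.choice(3, p=model.age_mix))]
        mature = age != "0-5h"
        ids = (f"HC{2 * p + 1:02d}", f"HC{2 * p + 2:02d}")
        positions = ("anterior", "posterior") if mature else ("unresolved", "unresolved")
        if model.genotype == "wild-type":
            identities = ("caudad", "rostrad")      # identity follows position
            polarities = ("caudad", "rostrad") if mature else ("undetermined",) * 2
        elif model.genotype == "trilobite":
            order = rng.permutation(2)
            identities = tuple(IDENTITIES[k] for k in order)
            polarities = tuple(
                rng.choice(IDENTITIES) if mature else "undetermined" for _ in range(2))
            for cid in ids:
                ledger.bundle_angles[cid] = float(rng.uniform(0, 2 * math.pi))
        else:  # notch-overexpression: shared identity, all rostrad bundles
            shared = str(rng.choice(IDENTITIES))
            identities = (shared, shared)
            polarities = ("rostrad", "rostrad") if mature else ("undetermined",) * 2
        for cid, sib, pos, pol, ident in zip(ids, ids[::-1], positions,
                                             polarities, identities):
            conn.haircells[cid] = HairCell(cid, polarity=pol, ap_position=pos,
                                           sibling_id=sib, age_class=age,
                                           age_source="preimaged", mature=mature)
            ledger.cell_identity[cid] = ident if mature else None
            ledger.sibling_identity[cid] = ident

    # --- ribbon allocation ----------------------------------------------
    contact_plan: dict[tuple[str, str], float] = {}

    def plant_contact(cell: str, term: str, area: float) -> None:
        key = (cell, term)
        contact_plan[key] = contact_plan.get(key, 0.0) + area

    def draw_area(mean_log: float, sigma: float) -> float:
        return float(rng.lognormal(mean_log, sigma))

    rib_counter = 0

    def new_ribbon(cell: str, terminal: str, matched: bool, age: str,
                   forced: bool = False, split_with: str | None = None) -> None:
        nonlocal rib_counter
        rib_counter += 1
        rid = f"R{rib_counter:03d}"
        area = draw_area(math.log(1.0e5), 0.4)
        appositions = {terminal: area}
        if split_with is not None:
            appositions[split_with] = area          # equal -> half each
        elif rng.random() < model.extra_apposition_rate:
            pool = ledger.terminal_identity[terminal]
            others = [t for t in pools.get(pool, []) if t != terminal]
            if others:
                wts = np.array([ledger.terminal_weight[t] for t in others])
                if wts.sum() > 0:
                    extra = str(rng.choice(others, p=wts / wts.sum()))
                    appositions[extra] = area * 0.5  # clearly unequal -> no split
        vol = draw_area(math.log(4.0e6 if age == ">15h" else 1.5e6), 0.5)
        conn.ribbons[rid] = RibbonSynapse(rid, cell, appositions=appositions,
                                          volume_nm3=vol)
        ledger.ribbon_match[rid] = matched
        ledger.ribbon_forced[rid] = forced

    pending_flips: list[tuple[str, str, str]] = []   # ribbon, cell, age

    def new_flip_placeholder(cell: str, age: str) -> None:
        # opposite-pool terminal chosen later, once sibling partners are known
        nonlocal rib_counter
        rib_counter += 1
        rid = f"R{rib_counter:03d}"
        vol = draw_area(math.log(4.0e6 if age == ">15h" else 1.5e6), 0.5)
        conn.ribbons[rid] = RibbonSynapse(rid, cell, appositions={}, volume_nm3=vol)
        ledger.ribbon_match[rid] = False
        ledger.ribbon_forced[rid] = False
        pending_flips.append((rid, cell, age))

    def pick(pool_ids: list[str], weights: np.ndarray, exclude: str | None = None
             ) -> str:
        if exclude is not None:
            keep = [k for k, t in enumerate(pool_ids) if t != exclude]
            ids = [pool_ids[k] for k in keep]
            w = weights[keep]
        else:
            ids, w = pool_ids, weights
        w = np.asarray(w, dtype=float)
        if w.sum() <= 0:
            w = np.ones(len(ids))
        return str(rng.choice(ids, p=w / w.sum()))

    mature_by_identity: dict[str, list[str]] = {k: [] for k in IDENTITIES}
    for cid, hc in conn.haircells.items():
        if hc.mature and ledger.cell_identity[cid]:
            mature_by_identity[ledger.cell_identity[cid]].append(cid)

    for cid, hc in conn.haircells.items():
        if not hc.mature:
            # nascent cells touch a terminal but make no synapses yet
            pool = str(rng.choice(IDENTITIES))
            w = np.array([ledger.terminal_weight[t] for t in pools[pool]])
            tid = pick(pools[pool], w)
            plant_contact(cid, tid, draw_area(math.log(1.5e5), 0.4))
            conn.perisynaptic.add((cid, tid))
            continue
        identity = ledger.cell_identity[cid]
        age = hc.age_class
        base, lam = model.ribbons_per_cell[age]
        n_rib = base + int(rng.poisson(lam))
        own_ids = pools[identity]
        own_w = np.array([ledger.terminal_weight[t] for t in own_ids])
        opp = IDENTITIES[1 - IDENTITIES.index(identity)]
        opp_ids = pools[opp]
        opp_w = np.array([ledger.terminal_weight[t] for t in opp_ids])
        if age == "5-15h":
            own_w = _flatten(own_w, model.young_dominance_flatten)
            opp_w_eff = _flatten(opp_w, model.young_dominance_flatten)
        else:
            opp_w_eff = opp_w

        if model.allocation == "poisson-partners":
            lam_partners = max(model.partners_per_cell.get(age, 1.0) - 1.0, 0.0)
            k = 1 + int(rng.poisson(lam_partners))
            nonzero = [t for t, w in zip(own_ids, own_w) if w > 0]
            k = min(k, len(nonzero))
            chosen = list(rng.choice(
                nonzero, size=k, replace=False,
                p=np.array([own_w[own_ids.index(t)] for t in nonzero])
                / sum(own_w[own_ids.index(t)] for t in nonzero)))
            ledger.planted_partner_counts[cid] = k
            n_rib = max(n_rib, k)
            targets = chosen + [pick(chosen, np.ones(len(chosen)))
                                for _ in range(n_rib - k)]
            for tid in targets:
                new_ribbon(cid, tid, matched=True, age=age)
        else:
            for _ in range(n_rib):
                if rng.random() < model.specificity_error:
                    new_flip_placeholder(cid, age)
                    continue
                tid = pick(own_ids, own_w)
                split_with = None
                if rng.random() < model.split_ribbon_rate:
                    if len(own_ids) > 1 and (np.asarray(own_w) > 0).sum() > 1:
                        split_with = pick(own_ids, np.asarray(own_w), exclude=tid)
                new_ribbon(cid, tid, matched=True, age=age, split_with=split_with)

    # resolve flipped ribbons: opposite-pool terminal, avoiding the sibling's
    # synaptic partners where possible — the unique sibling identity that
    # guides innervation remains allocated even when polarity errs
    if pending_flips:
        winners_by_cell: dict[str, set[str]] = {}
        for rib in conn.ribbons.values():
            if not rib.appositions:
                continue
            amax = max(rib.appositions.values())
            winners_by_cell.setdefault(rib.haircell_id, set()).update(
                t for t, a in rib.appositions.items() if a == amax)
        for rid, cell, age in pending_flips:
            identity = ledger.cell_identity[cell]
            opp = IDENTITIES[1 - IDENTITIES.index(identity)]
            sib = conn.haircells[cell].sibling_id
            sib_partners = winners_by_cell.get(sib or "", set())
            cand = [t for t in pools[opp]
                    if ledger.terminal_weight[t] > 0 and t not in sib_partners]
            if not cand:
                cand = [t for t in pools[opp] if ledger.terminal_weight[t] > 0]
            w = np.array([ledger.terminal_weight[t] for t in cand])
            if age == "5-15h":
                w = _flatten(w, model.young_dominance_flatten)
            tid = pick(cand, w)
            area = draw_area(math.log(1.0e5), 0.4)
            rib = conn.ribbons[rid]
            rib.appositions = {tid: area}
            if rng.random() < model.split_ribbon_rate and len(cand) > 1:
                rib.appositions[pick(cand, w, exclude=tid)] = area

    # top-up: every active terminal's matched weight must beat its flipped
    # weight so derived preference equals planted identity by construction
    if model.allocation == "dominance":
        matched_w: dict[str, float] = {}
        flipped_w: dict[str, float] = {}
        for rid, rib in conn.ribbons.items():
            amax = max(rib.appositions.values())
            winners = [t for t, a in rib.appositions.items() if a == amax]
            share = 1.0 / len(winners)
            for tid in winners:
                if ledger.ribbon_match[rid]:
                    matched_w[tid] = matched_w.get(tid, 0.0) + share
                else:
                    flipped_w[tid] = flipped_w.get(tid, 0.0) + share
        for identity in IDENTITIES:
            cells = mature_by_identity[identity]
            if not cells:
                continue
            for tid in pools[identity]:
                if ledger.terminal_weight[tid] <= 0:
                    continue
                while (matched_w.get(tid, 0.0) <= flipped_w.get(tid, 0.0)
                       or matched_w.get(tid, 0.0) == 0.0):
                    cell = str(rng.choice(cells))
                    age = conn.haircells[cell].age_class
                    new_ribbon(cell, tid, matched=True, age=age, forced=True)
                    matched_w[tid] = matched_w.get(tid, 0.0) + 1.0

    # --- contacts: synaptic partners, efferent, off-polarity, Notch -----
    for rib in conn.ribbons.values():
        for tid in rib.appositions:
            plant_contact(rib.haircell_id, tid, draw_area(math.log(4.0e5), 0.4))
    for cid, hc in conn.haircells.items():
        if hc.mature:
            plant_contact(cid, eff_id, draw_area(math.log(3.0e5), 0.4))

    if model.genotype == "notch-overexpression":
        for rib in conn.ribbons.values():
            hc = conn.haircells[rib.haircell_id]
            sib = hc.sibling_id
            if sib is None:
                continue
            for tid in rib.appositions:
                if (sib, tid) not in contact_plan:
                    plant_contact(sib, tid, draw_area(math.log(3.0e5), 0.4))

    if model.contact_area_error > 0:
        c = model.contact_area_error
        assignees: dict[str, set[str]] = {}
        for rib in conn.ribbons.values():
            amax = max(rib.appositions.values())
            assignees.setdefault(rib.haircell_id, set()).update(
                t for t, a in rib.appositions.items() if a == amax)
        for cid, hc in conn.haircells.items():
            if not hc.mature or ledger.cell_identity[cid] is None:
                continue
            identity = ledger.cell_identity[cid]
            matched_total = sum(a for (cc, t), a in contact_plan.items()
                                if cc == cid and
                                ledger.terminal_identity.get(t) == identity)
            opp = IDENTITIES[1 - IDENTITIES.index(identity)]
            # off-polarity contact avoids the sibling's synaptic partners:
            # sibling exclusivity holds even where polarity specificity fails
            sib_partners = assignees.get(hc.sibling_id or "", set())
            cand = [t for t in pools[opp]
                    if ledger.terminal_weight[t] > 0 and t not in sib_partners]
            if not cand:
                cand = [t for t in pools[opp] if ledger.terminal_weight[t] > 0]
            w = np.array([ledger.terminal_weight[t] for t in cand])
            tid = pick(cand, w)
            plant_contact(cid, tid, matched_total * c / (1.0 - c))

    # canonical key order so table round-trips accumulate floats identically
    for cid, tid in sorted(contact_plan, key=lambda k: tuple(sorted(k))):
        conn.add_contact(MembraneContact(cid, tid, contact_plan[(cid, tid)]))

    # --- perisynaptic occupancy: both identities, independent of polarity
    entering_afferents = [t for t in conn.terminals.values()
                          if t.kind == "afferent" and t.enters_neuromast]
    for cid, hc in conn.haircells.items():
        if not hc.mature:
            continue
        for rib in conn.ribbons_of_cell(cid):
            for tid in rib.appositions:
                conn.perisynaptic.add((cid, tid))
        for term in entering_afferents:
            if rng.random() < model.perisynaptic_rate:
                conn.perisynaptic.add((cid, term.terminal_id))

    annotate(conn, AnnotationConfig())
    return conn, ledger


# ---------------------------------------------------------------------------
# contour-trace fixtures with closed-form contact areas
# ---------------------------------------------------------------------------

@dataclass
class TraceLedger:
    """Closed-form contact geometry of a generated rectangle layout."""

    cell_ids: list[str]
    widths: list[float]
    gaps: list[float]
    height: float
    n_sections: int
    occluded_gaps: list[int]

    def expected_area(self, cell_a: str, cell_b: str,
                      config: GeometryConfig | None = None) -> float:
        """Exact contact area the 60 nm rule yields for a pair of cells.

        Facing edges of height h at gap g contribute h + 2*(threshold - g)
        of contact length per section (the wrap onto the receding
        perpendicular edges), provided g < threshold and the corridor is
        unobstructed.
        """
        config = config or GeometryConfig()
        ia = self.cell_ids.index(cell_a)
        ib = self.cell_ids.index(cell_b)
        if abs(ia - ib) != 1:
            lo, hi = min(ia, ib), max(ia, ib)
            span = sum(self.gaps[lo:hi]) + sum(self.widths[lo + 1:hi])
            if span >= config.contact_threshold:
                return 0.0
            raise NotImplementedError("non-adjacent cells closer than threshold")
        gap_index = min(ia, ib)
        gap = self.gaps[gap_index]
        if gap >= config.contact_threshold or gap_index in self.occluded_gaps:
            return 0.0
        length = self.height + 2.0 * (config.contact_threshold - gap)
        return length * config.section_thickness * self.n_sections


def generate_traces(cell_widths: Sequence[float], gaps: Sequence[float],
                    height: float = 1000.0, n_sections: int = 10,
                    occluded_gaps: Iterable[int] = (), seed: int = 0,
                    apical_sections: Iterable[int] = ()
                    ) -> tuple[dict[str, list[ContourTrace]], TraceLedger]:
    """Rectangular cell profiles side by side with specified inter-cell gaps.

    Occluded gaps receive a thin third trace spanning the full corridor
    (taller than the cells), which blocks all contact across that gap.
    Returns per-cell trace stacks plus the closed-form ledger.
    """
    if len(gaps) != len(cell_widths) - 1:
        raise ValueError("need one gap per adjacent cell pair")
    if any(g < 0 for g in gaps):
        raise ValueError("gaps must be non-negative")
    occluded = sorted(set(int(g) for g in occluded_gaps))
    for g in occluded:
        if not (0 <= g < len(gaps)):
            raise ValueError(f"occluded gap index {g} out of range")
        if gaps[g] < 3.0:
            raise ValueError("an occluded gap must be at least 3 nm wide")

    cell_ids = [f"C{i + 1}" for i in range(len(cell_widths))]
    traces: dict[str, list[ContourTrace]] = {cid: [] for cid in cell_ids}
    x = 0.0
    rects: list[tuple[float, float]] = []
    for w, cid in zip(cell_widths, cell_ids):
        rects.append((x, x + w))
        x += w
        if len(rects) <= len(gaps):
            x += gaps[len(rects) - 1]
    occ_rects: list[tuple[str, float, float]] = []
    for g in occluded:
        x0 = rects[g][1]
        margin = min(1.0, gaps[g] / 4.0)
        occ_rects.append((f"OCC{g + 1}", x0 + margin, x0 + gaps[g] - margin))
        traces[f"OCC{g + 1}"] = []

    for s in range(n_sections):
        for (x0, x1), cid in zip(rects, cell_ids):
            verts = np.array([[x0, 0.0], [x1, 0.0], [x1, height], [x0, height]])
            traces[cid].append(ContourTrace(cid, s, verts))
        for oid, x0, x1 in occ_rects:
            verts = np.array([[x0, -200.0], [x1, -200.0],
                              [x1, height + 200.0], [x0, height + 200.0]])
            traces[oid].append(ContourTrace(oid, s, verts))

    ledger = TraceLedger(cell_ids=cell_ids, widths=list(map(float, cell_widths)),
                         gaps=list(map(float, gaps)), height=float(height),
                         n_sections=n_sections, occluded_gaps=occluded)
    return traces, ledger


def random_polygon_pair(rng: np.random.Generator, target_gap: float,
                        radius_range: tuple[float, float] = (700.0, 1100.0),
                        n_vertices: tuple[int, int] = (10, 18),
                        flatten: float = 0.2,
                        with_occluder: bool = False
                        ) -> dict[str, list[ContourTrace]]:
    """A pair of random convex polygons separated by ``target_gap`` (nm).

    The hulls are flattened in y and stacked vertically, so the facing
    boundaries are long and gently curved — the regime in which membrane
    appositions occur — and optionally a small occluding polygon sits at
    the midpoint of the closest approach.  Used for oracle-equivalence
    fixtures.
    """
    def convex(center: np.ndarray) -> np.ndarray:
        n = int(rng.integers(*n_vertices))
        ang = np.sort(rng.uniform(0, 2 * math.pi, n))
        rad = rng.uniform(*radius_range, n)
        pts = np.c_[rad * np.cos(ang), flatten * rad * np.sin(ang)]
        hull = shapely.convex_hull(shapely.multipoints(pts))
        return center + shapely.get_coordinates(hull)[:-1]

    va = convex(np.zeros(2))
    pa = Polygon(va)
    offset = 2 * flatten * radius_range[1] + target_gap + 100.0
    vb0 = convex(np.array([rng.uniform(-100, 100), offset]))
    pb0 = Polygon(vb0)

    lo, hi = 0.0, offset  # shift of b toward a along -y
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        d = pa.distance(affinity.translate(pb0, yoff=-mid))
        if d > target_gap:
            lo = mid
        else:
            hi = mid
    shift = lo
    vb = vb0 - np.array([0.0, shift])
    pb = Polygon(vb)

    out = {"A": [ContourTrace("A", 0, va)], "B": [ContourTrace("B", 0, vb)]}
    if with_occluder:
        seg = shapely.shortest_line(pa, pb)
        (x0, y0), (x1, y1) = np.asarray(seg.coords)
        mid = np.array([(x0 + x1) / 2, (y0 + y1) / 2])
        r = max(min(target_gap * 0.35, 25.0), 2.0)
        ang = np.linspace(0, 2 * math.pi, 9)[:-1]
        verts = mid + np.c_[r * np.cos(ang), r * np.sin(ang)]
        occ = Polygon(verts)
        if not (occ.intersects(pa) or occ.intersects(pb)):
            out["OCC"] = [ContourTrace("OCC", 0, verts)]
    return out


# ---------------------------------------------------------------------------
# age-classifier cohorts
# ---------------------------------------------------------------------------

def generate_age_cohort(n_cells: int = 149,
                        class_proportions: Sequence[float] = (0.20, 0.35, 0.45),
                        separation: float = 2.0,
                        n_labeled: int | None = None,
                        seed: int = 0
                        ) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Class-conditional morphometric features for an age-classifier cohort.

    Volumes are log-normal and increase with age; nascent (0-5 h) cells
    have zero ribbon volume and small apical areas.  ``separation`` scales
    every class-conditional difference in units of the log-scale spread
    (0 makes the three classes identically distributed, including the
    ribbon-volume zeroing, so accuracy cannot beat chance).  Returns
    (features (n, 4), labels, labeled_mask); when ``n_labeled`` is given,
    only that many cells (chosen at random) are marked labeled, mimicking
    cohorts in which some specimens lack preimaging.
    """
    if abs(sum(class_proportions) - 1.0) > 1e-9:
        raise ValueError("class proportions must sum to 1")
    rng = np.random.default_rng(seed)
    classes = ("0-5h", "5-15h", ">15h")
    y_idx = rng.choice(3, size=n_cells, p=np.asarray(class_proportions))
    counts = np.bincount(y_idx, minlength=3)
    if (counts < 3).any():
        raise ValueError("need at least 3 cells per class; increase n_cells")

    sigma = 0.35
    log_vol = math.log(1.0e11) + y_idx * separation * sigma \
        + rng.normal(0, sigma, n_cells)
    volume = np.exp(log_vol)
    area = volume ** (2.0 / 3.0) * 6.0 * np.exp(rng.normal(0, 0.15, n_cells))
    log_apical = math.log(2.0e5) + y_idx * separation * 0.4 \
        + rng.normal(0, 0.4, n_cells)
    apical = np.exp(log_apical)
    log_rib = math.log(5.0e6) + (y_idx - 1) * separation * 0.5 \
        + rng.normal(0, 0.5, n_cells)
    ribbon = np.exp(log_rib)
    if separation > 0:
        ribbon[y_idx == 0] = 0.0

    X = np.c_[area, volume, ribbon, apical]
    labels = [classes[k] for k in y_idx]
    mask = np.ones(n_cells, dtype=bool)
    if n_labeled is not None:
        if n_labeled > n_cells:
            raise ValueError("n_labeled exceeds n_cells")
        mask = np.zeros(n_cells, dtype=bool)
        mask[rng.choice(n_cells, size=n_labeled, replace=False)] = True
    return X, labels, mask
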