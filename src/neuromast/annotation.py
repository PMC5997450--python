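"""Classification rules applied to a loaded connectome.

Efferent identification: a terminal that directly contacts every mature
hair cell yet is apposed to no synaptic ribbon — and, by default, carries
both diagnostic structures (vesicle-filled bouton, postsynaptic cistern) —
is the neuromast's efferent; all other terminals are afferent.

Ribbon partnership: the terminal occupying the largest membrane area
opposite a ribbon receives the whole active zone; when the top two areas
are equal within a relative tolerance, each receives half.

Terminal polarity preference: the majority polarity of a terminal's
ribbon-synapse partners, weighted by ribbon share; terminals without
informative synapses fall back to the majority of their membrane contact
area with polarized hair cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .model import (AnnotationStateError, NeuromastConnectome, RibbonSynapse,
                    STRUCTURAL_FLAGS, Terminal)

log = logging.getLogger("neuromast.annotation")


@dataclass(frozen=True)
class AnnotationConfig:
    efferent_requires_flags: bool = True
    tie_area_tolerance: float = 0.10   # relative; "occupied equally"

    def __post_init__(self) -> None:
        if not (0.0 <= self.tie_area_tolerance < 0.5):
            raise ValueError("tie_area_tolerance must be in [0, 0.5)")


def identify_entering_terminals(conn: NeuromastConnectome) -> set[str]:
    """Terminals scored as entering the neuromast (crossing the basal lamina).

    The crossing itself is an input annotation carried on each terminal;
    this returns the flagged set.  Non-entering fibers are excluded from all
    downstream statistics.
    """
    return {t.terminal_id for t in conn.terminals.values() if t.enters_neuromast}


def classify_terminals(conn: NeuromastConnectome,
                       config: AnnotationConfig | None = None) -> NeuromastConnectome:
    """Set ``Terminal.kind`` for every terminal; idempotent.

    Requires contacts to have been computed (or planted).  More than one
    efferent candidate triggers a warning, not an error: most neuromasts
    carry exactly one.
    """
    config = config or AnnotationConfig()
    if conn.contacts is None:
        raise AnnotationStateError(
            f"{conn.specimen_id}: contacts must be computed before terminal "
            "classification")
    mature = [hc.cell_id for hc in conn.mature_haircells()]
    apposed: set[str] = set()
    for rib in conn.ribbons.values():
        apposed.update(rib.appositions)
        apposed.update(t for t, _ in rib.assignments)

    n_eff = 0
    for term in conn.terminals.values():
        contacts = conn.contacts_of(term.terminal_id)
        contacts_all_mature = bool(mature) and all(
            contacts.get(cid, 0.0) > 0 for cid in mature)
        no_ribbons = term.terminal_id not in apposed
        has_flags = set(STRUCTURAL_FLAGS) <= term.structural_flags
        is_eff = contacts_all_mature and no_ribbons and (
            has_flags or not config.efferent_requires_flags)
        term.kind = "efferent" if is_eff else "afferent"
        n_eff += int(is_eff)
    if n_eff > 1:
        log.warning("%s: %d efferent candidates (expected at most one)",
                    conn.specimen_id, n_eff)
    return conn


def assign_ribbon_partners(ribbon: RibbonSynapse,
                           apposed_areas: dict[str, float] | None = None,
                           config: AnnotationConfig | None = None) -> RibbonSynapse:
    """Assign a ribbon to its partner terminal(s) from apposed membrane areas.

    Largest area wins the whole ribbon; if the top two areas agree within
    ``tie_area_tolerance`` (relative), each terminal is assigned half.  A
    ribbon with no apposed terminal is flagged unpartnered, not dropped.
    """
    config = config or AnnotationConfig()
    areas = dict(apposed_areas if apposed_areas is not None else ribbon.appositions)
    ribbon.assignments = []
    if not areas:
        ribbon.unpartnered = True
        return ribbon
    ribbon.unpartnered = False
    ranked = sorted(areas.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) >= 2:
        (t1, a1), (t2, a2) = ranked[0], ranked[1]
        if a1 > 0 and (a1 - a2) / a1 <= config.tie_area_tolerance:
            ribbon.assignments = [(t1, 0.5), (t2, 0.5)]
            return ribbon
    ribbon.assignments = [(ranked[0][0], 1.0)]
    return ribbon


def assign_all_ribbons(conn: NeuromastConnectome,
                       config: AnnotationConfig | None = None) -> NeuromastConnectome:
    config = config or AnnotationConfig()
    for rib in conn.ribbons.values():
        assign_ribbon_partners(rib, None, config)
    return conn


def group_preference(terminal_id: str, conn: NeuromastConnectome,
                     grouping: str = "polarity") -> str | None:
    """Majority group (polarity or ap_position) a terminal serves.

    Votes are ribbon weights over mature hair cells with an informative
    group label; ties or absent synapses fall back to the majority of
    membrane contact area with labelled cells; a residual tie gives None.
    Immature (0-5 h) cells never vote.
    """
    def label(hc) -> str | None:
        if not hc.mature or hc.age_class == "0-5h":
            return None
        if grouping == "polarity":
            return hc.polarity if hc.polarity != "undetermined" else None
        if grouping == "ap_position":
            return hc.ap_position if hc.ap_position != "unresolved" else None
        raise ValueError(f"unknown grouping {grouping!r}")

    votes: dict[str, float] = {}
    for rib in conn.ribbons.values():
        w = rib.weight_for(terminal_id)
        if w <= 0:
            continue
        lab = label(conn.haircells[rib.haircell_id])
        if lab is not None:
            votes[lab] = votes.get(lab, 0.0) + w
    winner = _majority(votes)
    if winner is not None:
        return winner
    # fall back to contact area with labelled cells
    votes = {}
    for cid, area in conn.contacts_of(terminal_id).items():
        hc = conn.haircells.get(cid)
        if hc is None:
            continue
        lab = label(hc)
        if lab is not None:
            votes[lab] = votes.get(lab, 0.0) + area
    return _majority(votes)


def _majority(votes: dict[str, float]) -> str | None:
    if not votes:
        return None
    ranked = sorted(votes.items(), key=lambda kv: -kv[1])
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return None
    return ranked[0][0]


def terminal_polarity_preference(terminal: Terminal | str,
                                 conn: NeuromastConnectome) -> str:
    tid = terminal if isinstance(terminal, str) else terminal.terminal_id
    pref = group_preference(tid, conn, grouping="polarity")
    return pref if pref is not None else "unassigned"


def annotate_preferences(conn: NeuromastConnectome) -> NeuromastConnectome:
    for term in conn.terminals.values():
        if term.kind == "efferent":
            term.polarity_preference = "unassigned"
        else:
            term.polarity_preference = terminal_polarity_preference(term, conn)
    return conn


def annotate(conn: NeuromastConnectome,
             config: AnnotationConfig | None = None) -> NeuromastConnectome:
    """Full annotation pass: partners, kinds, preferences."""
    config = config or AnnotationConfig()
    assign_all_ribbons(conn, config)
    classify_terminals(conn, config)
    annotate_preferences(conn)
    return conn
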