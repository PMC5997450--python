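"""Wiring statistics of neuromast connectomes.

Covers polarity (or position) specificity of ribbon synapses, membrane
contacts and perisynaptic associations; redundancy (partners per hair
cell); dominance of individual afferent arbors; sibling-pair innervation
exclusivity; the mixed-terminal fraction used to score mutants by
anteroposterior position; entering-branch counts; and the pooled-variance
two-tailed t test used for group comparisons.

Counting conventions: a ribbon split between two terminals contributes
half its weight to each in all weighted tallies; integer "active zone"
counts, in which every ribbon counts once regardless of splitting, are
reported alongside.  Hair cells 0-5 h post-mitosis have neither a settled
polarity nor a stable anteroposterior position and are excluded from
specificity and mixed-fraction statistics; they are retained in redundancy
and dominance tallies.  Pooled ("micro") statistics sum counts over
specimens; per-specimen ("macro") means are reported as well.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .annotation import group_preference
from .model import NeuromastConnectome

log = logging.getLogger("neuromast.stats")

ASSOCIATION_TYPES = ("ribbon", "contact", "perisynaptic")
SPECIFICITY_AGES = ("5-15h", ">15h")
ALL_AGES = ("0-5h", "5-15h", ">15h")


def mean_sem(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        return float("nan"), float("nan")
    if arr.size == 1:
        return float(arr[0]), float("nan")
    return float(arr.mean()), float(arr.std(ddof=1) / math.sqrt(arr.size))


def _cell_group(hc, grouping: str) -> str | None:
    if not hc.mature or hc.age_class == "0-5h":
        return None
    if grouping == "polarity":
        return hc.polarity if hc.polarity != "undetermined" else None
    if grouping == "ap_position":
        return hc.ap_position if hc.ap_position != "unresolved" else None
    raise ValueError(f"unknown grouping {grouping!r}")


def _afferent_ids(conn: NeuromastConnectome) -> set[str]:
    return {t.terminal_id for t in conn.terminals.values()
            if t.kind == "afferent" and t.enters_neuromast}


def _preferences(conn: NeuromastConnectome, grouping: str) -> dict[str, str | None]:
    return {tid: group_preference(tid, conn, grouping)
            for tid in _afferent_ids(conn)}


# ---------------------------------------------------------------------------
# specificity
# ---------------------------------------------------------------------------

@dataclass
class SpecificityReport:
    grouping: str
    by_age: dict[str, dict[str, float]]          # age -> assoc type -> fraction
    total_ribbons: int = 0                        # integer active zones (labelled cells)
    opposite_ribbons: int = 0
    weighted_total: float = 0.0
    weighted_opposite: float = 0.0
    ribbon_specificity: float = float("nan")
    contact_specificity_all: float = float("nan")      # pooled over all labelled ages
    contact_specificity_mature: float = float("nan")   # >15 h only
    perisynaptic_specificity: float = float("nan")
    per_specimen: dict[str, dict[str, float]] = field(default_factory=dict)
    macro: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "grouping": self.grouping,
            "by_age": self.by_age,
            "total_ribbons": self.total_ribbons,
            "opposite_ribbons": self.opposite_ribbons,
            "weighted_total": self.weighted_total,
            "weighted_opposite": self.weighted_opposite,
            "ribbon_specificity": self.ribbon_specificity,
            "contact_specificity_all": self.contact_specificity_all,
            "contact_specificity_mature": self.contact_specificity_mature,
            "perisynaptic_specificity": self.perisynaptic_specificity,
            "per_specimen": self.per_specimen,
            "macro": self.macro,
        }


def specificity_stats(connectomes: Sequence[NeuromastConnectome],
                      grouping: str = "polarity") -> SpecificityReport:
    """Fraction of associations formed with terminals of the appropriate group.

    A ribbon is appropriate iff every assignee's derived preference matches
    its hair cell's group; split ribbons contribute their weight to the
    mismatch tally.  Contact specificity is the fraction of hair-cell to
    afferent contact area whose terminal preference matches the cell.
    ``grouping`` is "polarity" for wild type and "ap_position" for mutants
    whose bundle polarity is uninformative.
    """
    if not connectomes:
        raise ValueError("specificity_stats needs at least one connectome")

    num = {a: {t: 0.0 for t in ASSOCIATION_TYPES} for a in SPECIFICITY_AGES}
    den = {a: {t: 0.0 for t in ASSOCIATION_TYPES} for a in SPECIFICITY_AGES}
    rep = SpecificityReport(grouping=grouping,
                            by_age={a: {} for a in SPECIFICITY_AGES})
    contact_num_all = contact_den_all = 0.0
    contact_num_mat = contact_den_mat = 0.0
    peri_num = peri_den = 0.0
    per_specimen: dict[str, dict[str, float]] = {}

    for conn in connectomes:
        prefs = _preferences(conn, grouping)
        afferents = _afferent_ids(conn)
        sp_w_match = sp_w_total = 0.0
        sp_c_match = sp_c_total = 0.0

        for rib in conn.ribbons.values():
            hc = conn.haircells[rib.haircell_id]
            lab = _cell_group(hc, grouping)
            if lab is None or not rib.assignments:
                continue
            age = hc.age_class if hc.age_class in SPECIFICITY_AGES else None
            match_w = sum(w for t, w in rib.assignments if prefs.get(t) == lab)
            total_w = rib.total_weight
            rep.weighted_total += total_w
            rep.weighted_opposite += total_w - match_w
            rep.total_ribbons += 1
            any_mismatch = any(prefs.get(t) != lab for t, _ in rib.assignments)
            rep.opposite_ribbons += int(any_mismatch)
            sp_w_total += total_w
            sp_w_match += match_w
            if age:
                den[age]["ribbon"] += total_w
                num[age]["ribbon"] += match_w

        if conn.contacts is not None:
            for (a, b), c in conn.contacts.items():
                hc_id, t_id = (a, b) if a in conn.haircells else (b, a)
                if hc_id not in conn.haircells or t_id not in afferents:
                    continue
                hc = conn.haircells[hc_id]
                lab = _cell_group(hc, grouping)
                if lab is None:
                    continue
                match = prefs.get(t_id) == lab
                contact_den_all += c.area
                contact_num_all += c.area if match else 0.0
                sp_c_total += c.area
                sp_c_match += c.area if match else 0.0
                if hc.age_class == ">15h":
                    contact_den_mat += c.area
                    contact_num_mat += c.area if match else 0.0
                if hc.age_class in SPECIFICITY_AGES:
                    den[hc.age_class]["contact"] += c.area
                    num[hc.age_class]["contact"] += c.area if match else 0.0

        for hc_id, t_id in conn.perisynaptic:
            if t_id not in afferents:
                continue
            hc = conn.haircells[hc_id]
            lab = _cell_group(hc, grouping)
            if lab is None:
                continue
            match = prefs.get(t_id) == lab
            peri_den += 1
            peri_num += 1 if match else 0
            if hc.age_class in SPECIFICITY_AGES:
                den[hc.age_class]["perisynaptic"] += 1
                num[hc.age_class]["perisynaptic"] += 1 if match else 0

        per_specimen[conn.specimen_id] = {
            "ribbon_specificity": sp_w_match / sp_w_total if sp_w_total else float("nan"),
            "contact_specificity": sp_c_match / sp_c_total if sp_c_total else float("nan"),
        }

    for age in SPECIFICITY_AGES:
        for assoc in ASSOCIATION_TYPES:
            d = den[age][assoc]
            rep.by_age[age][assoc] = num[age][assoc] / d if d else float("nan")

    rep.ribbon_specificity = (1.0 - rep.weighted_opposite / rep.weighted_total
                              if rep.weighted_total else float("nan"))
    rep.contact_specificity_all = (contact_num_all / contact_den_all
                                   if contact_den_all else float("nan"))
    rep.contact_specificity_mature = (contact_num_mat / contact_den_mat
                                      if contact_den_mat else float("nan"))
    rep.perisynaptic_specificity = (peri_num / peri_den if peri_den else float("nan"))
    rep.per_specimen = per_specimen
    for metric in ("ribbon_specificity", "contact_specificity"):
        vals = [m[metric] for m in per_specimen.values() if not math.isnan(m[metric])]
        rep.macro[metric] = float(np.mean(vals)) if vals else float("nan")
    return rep


# ---------------------------------------------------------------------------
# redundancy
# ---------------------------------------------------------------------------

def redundancy_stats(connectomes: Sequence[NeuromastConnectome]) -> dict:
    """Per age class, mean +/- SEM of distinct afferent partners per hair cell.

    Partner sets are counted separately for ribbon synapses, membrane
    contacts, and perisynaptic associations; half-ribbon assignees count as
    full partners.
    """
    counts = {a: {t: [] for t in ASSOCIATION_TYPES} for a in ALL_AGES}
    per_cell: list[dict] = []
    for conn in connectomes:
        afferents = _afferent_ids(conn)
        for hc in conn.haircells.values():
            if hc.age_class not in ALL_AGES:
                continue
            rib_partners = {t for rib in conn.ribbons_of_cell(hc.cell_id)
                            for t, w in rib.assignments if w > 0 and t in afferents}
            contact_partners = {t for t, area in conn.contacts_of(hc.cell_id).items()
                                if area > 0 and t in afferents}
            peri_partners = {t for (c, t) in conn.perisynaptic
                             if c == hc.cell_id and t in afferents}
            tallies = {"ribbon": len(rib_partners), "contact": len(contact_partners),
                       "perisynaptic": len(peri_partners)}
            for assoc, n in tallies.items():
                counts[hc.age_class][assoc].append(n)
            per_cell.append(dict(specimen=conn.specimen_id, cell=hc.cell_id,
                                 age_class=hc.age_class, **tallies))
    out = {"by_age": {}, "per_cell": per_cell}
    for age in ALL_AGES:
        out["by_age"][age] = {}
        for assoc in ASSOCIATION_TYPES:
            m, s = mean_sem(counts[age][assoc])
            out["by_age"][age][assoc] = {"mean": m, "sem": s,
                                         "n": len(counts[age][assoc])}
    return out


# ---------------------------------------------------------------------------
# dominance
# ---------------------------------------------------------------------------

@dataclass
class DominanceReport:
    per_cell: list[dict]
    by_age: dict[str, dict[str, float]]           # age -> mean dominant shares
    ranked: dict[str, dict[str, list]]            # specimen -> group -> ranked shares
    mean_ranked_ribbon: list[float]               # 1st, 2nd, 3rd
    mean_ranked_contact: list[float]

    def to_dict(self) -> dict:
        return {"per_cell": self.per_cell, "by_age": self.by_age,
                "ranked": self.ranked,
                "mean_ranked_ribbon": self.mean_ranked_ribbon,
                "mean_ranked_contact": self.mean_ranked_contact}


def dominance_stats(connectomes: Sequence[NeuromastConnectome],
                    grouping: str = "polarity") -> DominanceReport:
    """Dominant-arbor shares per hair cell and ranked arbor shares per organ.

    Per cell, the dominant terminal is the argmax over (summed ribbon
    weight, contact area) taken lexicographically; cells without ribbons
    are excluded (logged).  Per specimen and group, afferent arbors are
    ranked by their share of the group's polarity-specific ribbon weight;
    shares over a group's terminals sum to 1.
    """
    per_cell: list[dict] = []
    by_age_shares = {a: {"ribbon": [], "contact": []} for a in ALL_AGES}
    ranked: dict[str, dict[str, list]] = {}
    firsts_r: list[list[float]] = [[], [], []]
    firsts_c: list[list[float]] = [[], [], []]

    for conn in connectomes:
        afferents = _afferent_ids(conn)
        for hc in conn.haircells.values():
            weights: dict[str, float] = {}
            for rib in conn.ribbons_of_cell(hc.cell_id):
                for t, w in rib.assignments:
                    if t in afferents:
                        weights[t] = weights.get(t, 0.0) + w
            if not weights:
                log.info("%s: cell %s has no assigned ribbons; excluded from "
                         "per-cell dominance", conn.specimen_id, hc.cell_id)
                continue
            areas = conn.contacts_of(hc.cell_id)
            dom = max(weights, key=lambda t: (weights[t], areas.get(t, 0.0), t))
            total_w = sum(weights.values())
            total_a = sum(a for t, a in areas.items() if t in afferents)
            rib_share = weights[dom] / total_w
            c_share = (areas.get(dom, 0.0) / total_a) if total_a else float("nan")
            rec = dict(specimen=conn.specimen_id, cell=hc.cell_id,
                       age_class=hc.age_class, dominant_terminal=dom,
                       ribbon_share=rib_share, contact_share=c_share)
            per_cell.append(rec)
            if hc.age_class in ALL_AGES:
                by_age_shares[hc.age_class]["ribbon"].append(rib_share)
                if not math.isnan(c_share):
                    by_age_shares[hc.age_class]["contact"].append(c_share)

        # per-organ ranked arbors within each group
        prefs = _preferences(conn, grouping)
        ranked[conn.specimen_id] = {}
        groups = sorted({p for p in prefs.values() if p is not None})
        for grp in groups:
            grp_terms = [t for t, p in prefs.items() if p == grp]
            rib_w = {t: 0.0 for t in grp_terms}
            con_a = {t: 0.0 for t in grp_terms}
            for rib in conn.ribbons.values():
                hc = conn.haircells[rib.haircell_id]
                if _cell_group(hc, grouping) != grp:
                    continue
                for t, w in rib.assignments:
                    if t in rib_w:
                        rib_w[t] += w
            if conn.contacts is not None:
                for (a, b), c in conn.contacts.items():
                    hc_id, t_id = (a, b) if a in conn.haircells else (b, a)
                    if t_id in con_a and hc_id in conn.haircells:
                        if _cell_group(conn.haircells[hc_id], grouping) == grp:
                            con_a[t_id] += c.area
            tot_w = sum(rib_w.values())
            tot_a = sum(con_a.values())
            if tot_w <= 0:
                continue
            order = sorted(grp_terms, key=lambda t: (-rib_w[t], t))
            shares = [(t, rib_w[t] / tot_w,
                       (con_a[t] / tot_a) if tot_a else float("nan"))
                      for t in order]
            ranked[conn.specimen_id][grp] = shares
            for i in range(min(3, len(shares))):
                firsts_r[i].append(shares[i][1])
                if not math.isnan(shares[i][2]):
                    firsts_c[i].append(shares[i][2])

    by_age = {}
    for age in ALL_AGES:
        by_age[age] = {
            "ribbon_share_mean": mean_sem(by_age_shares[age]["ribbon"])[0],
            "ribbon_share_sem": mean_sem(by_age_shares[age]["ribbon"])[1],
            "contact_share_mean": mean_sem(by_age_shares[age]["contact"])[0],
            "contact_share_sem": mean_sem(by_age_shares[age]["contact"])[1],
            "n": len(by_age_shares[age]["ribbon"]),
        }
    return DominanceReport(
        per_cell=per_cell, by_age=by_age, ranked=ranked,
        mean_ranked_ribbon=[float(np.mean(v)) if v else float("nan") for v in firsts_r],
        mean_ranked_contact=[float(np.mean(v)) if v else float("nan") for v in firsts_c],
    )


# ---------------------------------------------------------------------------
# sibling exclusivity and mixed innervation
# ---------------------------------------------------------------------------

def sibling_exclusivity(connectomes: Sequence[NeuromastConnectome]) -> dict:
    """Weighted count of ribbons whose terminal also contacts the sibling cell.

    A ribbon is "shared" if any assignee terminal has a membrane contact
    with the hair cell's sibling.  Cells without a sibling annotation are
    skipped (logged).  Returns pooled weighted counts and per-pair flags.
    """
    shared_w = total_w = 0.0
    shared_n = total_n = 0
    pair_flags: dict[str, dict[str, bool]] = {}
    for conn in connectomes:
        flags: dict[str, bool] = {}
        for rib in conn.ribbons.values():
            hc = conn.haircells[rib.haircell_id]
            if hc.sibling_id is None:
                log.info("%s: cell %s unpaired; skipped in sibling exclusivity",
                         conn.specimen_id, hc.cell_id)
                continue
            if not rib.assignments:
                continue
            sib_contacts = conn.contacts_of(hc.sibling_id)
            w = rib.total_weight
            is_shared = any(sib_contacts.get(t, 0.0) > 0 for t, _ in rib.assignments)
            total_w += w
            total_n += 1
            if is_shared:
                shared_w += w
                shared_n += 1
            pair = "~".join(sorted((hc.cell_id, hc.sibling_id)))
            flags[pair] = flags.get(pair, False) or is_shared
        pair_flags[conn.specimen_id] = flags
    return {
        "shared_ribbons_weighted": shared_w,
        "total_ribbons_weighted": total_w,
        "shared_ribbons": shared_n,
        "total_ribbons": total_n,
        "shared_fraction": shared_w / total_w if total_w else float("nan"),
        "per_pair": pair_flags,
    }


def mixed_terminal_fraction(connectomes: Sequence[NeuromastConnectome]) -> dict:
    """Fraction of ribbon weight on terminals innervated from both positions.

    A terminal is "mixed" when it receives ribbon synapses both from
    anteriorly and posteriorly positioned hair cells; 0-5 h cells, which
    have no stable position, are excluded entirely.
    """
    mixed_w = total_w = 0.0
    per_specimen: dict[str, float] = {}
    for conn in connectomes:
        positions: dict[str, set[str]] = {}
        for rib in conn.ribbons.values():
            hc = conn.haircells[rib.haircell_id]
            lab = _cell_group(hc, "ap_position")
            if lab is None:
                continue
            for t, w in rib.assignments:
                if w > 0:
                    positions.setdefault(t, set()).add(lab)
        sp_mixed = sp_total = 0.0
        for rib in conn.ribbons.values():
            hc = conn.haircells[rib.haircell_id]
            if _cell_group(hc, "ap_position") is None:
                continue
            for t, w in rib.assignments:
                sp_total += w
                if len(positions.get(t, set())) > 1:
                    sp_mixed += w
        mixed_w += sp_mixed
        total_w += sp_total
        per_specimen[conn.specimen_id] = (sp_mixed / sp_total if sp_total
                                          else float("nan"))
    return {
        "mixed_weight": mixed_w,
        "total_weight": total_w,
        "mixed_fraction": mixed_w / total_w if total_w else float("nan"),
        "per_specimen": per_specimen,
    }


# ---------------------------------------------------------------------------
# branch counts and t tests
# ---------------------------------------------------------------------------

def branch_count_stats(connectomes: Sequence[NeuromastConnectome]) -> dict:
    """Mean +/- SEM of entering terminals (afferent + efferent) per organ."""
    counts = []
    for conn in connectomes:
        n = sum(1 for t in conn.terminals.values()
                if t.enters_neuromast and t.kind in ("afferent", "efferent"))
        counts.append(n)
    m, s = mean_sem(counts)
    return {"counts": counts, "mean": m, "sem": s, "n": len(counts)}


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def two_tailed_t(sample_a: Sequence[float], sample_b: Sequence[float]
                 ) -> tuple[float, float, tuple[float, float]]:
    """Pooled-variance two-sample Student t test (two-tailed).

    Returns (t, p, (SEM_a, SEM_b)).  Two zero-variance samples with equal
    means give t = 0, p = 1 rather than NaN.
    """
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    sem_a = float(a.std(ddof=1) / math.sqrt(a.size))
    sem_b = float(b.std(ddof=1) / math.sqrt(b.size))
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, (sem_a, sem_b)
        return float("inf"), 0.0, (sem_a, sem_b)
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p), (sem_a, sem_b)
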