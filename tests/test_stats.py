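"""Connectome statistics: specificity, redundancy, dominance, sibling
exclusivity, mixed innervation, branch counts, and the t test."""

import math

import numpy as np
import pytest

from neuromast.model import (HairCell, MembraneContact, NeuromastConnectome,
                             RibbonSynapse, Terminal)
from neuromast.stats import (branch_count_stats, dominance_stats, mean_sem,
                             mixed_terminal_fraction, redundancy_stats,
                             sibling_exclusivity, significance_stars,
                             specificity_stats, two_tailed_t)
from neuromast.synthetic import GenotypeModel, generate_connectome


def _bare_connectome(n_afferent, specimen="S"):
    conn = NeuromastConnectome(specimen, "wild-type")
    for i in range(n_afferent):
        conn.terminals[f"A{i}"] = Terminal(f"A{i}", kind="afferent")
    conn.contacts = {}
    return conn


def test_specificity_conservation():
    conn, _ = generate_connectome(GenotypeModel(specificity_error=0.1), 9)
    rep = specificity_stats([conn])
    matched = rep.weighted_total - rep.weighted_opposite
    assert matched + rep.weighted_opposite == pytest.approx(rep.weighted_total)
    assert 0 <= rep.ribbon_specificity <= 1
    assert rep.opposite_ribbons <= rep.total_ribbons


def test_specificity_invariant_to_order_and_relabeling():
    model = GenotypeModel()
    conns = [generate_connectome(model, s)[0] for s in (1, 2, 3)]
    a = specificity_stats(conns)
    b = specificity_stats(conns[::-1])
    assert a.ribbon_specificity == b.ribbon_specificity
    assert a.contact_specificity_all == pytest.approx(b.contact_specificity_all,
                                                      rel=1e-12)
    for c, new in zip(conns, ("X", "Y", "Z")):
        c.specimen_id = new
    c2 = specificity_stats(conns)
    assert c2.ribbon_specificity == a.ribbon_specificity


def test_specificity_empty_input_errors():
    with pytest.raises(ValueError):
        specificity_stats([])


def test_redundancy_counts_distinct_partners():
    conn = _bare_connectome(3)
    conn.haircells["H"] = HairCell("H", polarity="caudad", age_class=">15h",
                                   mature=True)
    for i in range(3):   # three ribbons, all with A0
        conn.ribbons[f"R{i}"] = RibbonSynapse(f"R{i}", "H",
                                              assignments=[("A0", 1.0)])
    conn.haircells["H2"] = HairCell("H2", polarity="rostrad", age_class="5-15h",
                                    mature=True)   # no associations at all
    rep = redundancy_stats([conn])
    old = {r["cell"]: r for r in rep["per_cell"]}
    assert old["H"]["ribbon"] == 1
    assert old["H2"]["ribbon"] == old["H2"]["contact"] == old["H2"]["perisynaptic"] == 0
    # a half-ribbon assignee counts as a full partner
    conn.ribbons["R0"].assignments = [("A0", 0.5), ("A1", 0.5)]
    rep = redundancy_stats([conn])
    assert {r["cell"]: r for r in rep["per_cell"]}["H"]["ribbon"] == 2


def test_dominance_share_arithmetic():
    conn = _bare_connectome(2)
    conn.haircells["H"] = HairCell("H", polarity="caudad", age_class=">15h",
                                   mature=True)
    for i, tid in enumerate(["A0"] * 3 + ["A1"]):
        conn.ribbons[f"R{i}"] = RibbonSynapse(f"R{i}", "H",
                                              assignments=[(tid, 1.0)])
    rep = dominance_stats([conn])
    rec = rep.per_cell[0]
    assert rec["dominant_terminal"] == "A0"
    assert rec["ribbon_share"] == 0.75


def test_dominance_tie_broken_by_contact_area():
    conn = _bare_connectome(2)
    conn.haircells["H"] = HairCell("H", polarity="caudad", age_class=">15h",
                                   mature=True)
    for i, tid in enumerate(["A0", "A0", "A1", "A1"]):
        conn.ribbons[f"R{i}"] = RibbonSynapse(f"R{i}", "H",
                                              assignments=[(tid, 1.0)])
    conn.add_contact(MembraneContact("H", "A1", 9e5))
    conn.add_contact(MembraneContact("H", "A0", 1e5))
    rep = dominance_stats([conn])
    assert rep.per_cell[0]["dominant_terminal"] == "A1"


def test_dominance_more_ribbons_never_lowers_rank():
    conn, ledger = generate_connectome(GenotypeModel(), 11)
    rep = dominance_stats([conn])
    ranked = rep.ranked[conn.specimen_id]
    for shares in ranked.values():
        vals = [s for _, s, _ in shares]
        assert vals == sorted(vals, reverse=True)
        assert sum(vals) == pytest.approx(1.0)


def test_ranked_shares_sum_to_one_per_group():
    conns = [generate_connectome(GenotypeModel(), s)[0] for s in range(3)]
    rep = dominance_stats(conns)
    for spec in rep.ranked.values():
        for shares in spec.values():
            assert sum(s for _, s, _ in shares) == pytest.approx(1.0)


def test_mixed_fraction_single_terminal_toy():
    conn = _bare_connectome(1)
    conn.haircells["H1"] = HairCell("H1", polarity="caudad",
                                    ap_position="anterior", age_class=">15h",
                                    mature=True)
    conn.haircells["H2"] = HairCell("H2", polarity="rostrad",
                                    ap_position="posterior", age_class=">15h",
                                    mature=True)
    conn.ribbons["R1"] = RibbonSynapse("R1", "H1", assignments=[("A0", 1.0)])
    conn.ribbons["R2"] = RibbonSynapse("R2", "H2", assignments=[("A0", 1.0)])
    assert mixed_terminal_fraction([conn])["mixed_fraction"] == 1.0


def test_sibling_exclusivity_toy():
    conn = _bare_connectome(2)
    conn.haircells["H1"] = HairCell("H1", polarity="caudad", sibling_id="H2",
                                    age_class=">15h", mature=True)
    conn.haircells["H2"] = HairCell("H2", polarity="rostrad", sibling_id="H1",
                                    age_class=">15h", mature=True)
    conn.ribbons["R1"] = RibbonSynapse("R1", "H1", assignments=[("A0", 1.0)])
    rep = sibling_exclusivity([conn])
    assert rep["shared_ribbons"] == 0 and rep["total_ribbons"] == 1
    conn.add_contact(MembraneContact("H2", "A0", 1e5))   # A0 now touches sibling
    rep = sibling_exclusivity([conn])
    assert rep["shared_ribbons"] == 1 and rep["shared_fraction"] == 1.0


def test_branch_count_mean():
    counts = [10, 9, 9, 10, 9, 9, 10, 8]
    conns = []
    for k, n in enumerate(counts):
        conn = _bare_connectome(n - 1, specimen=f"S{k}")
        conn.terminals["E"] = Terminal("E", kind="efferent")
        conn.terminals["NE"] = Terminal("NE", kind="afferent",
                                        enters_neuromast=False)
        conns.append(conn)
    rep = branch_count_stats(conns)
    assert rep["counts"] == counts
    assert rep["mean"] == pytest.approx(9.25)


def test_two_tailed_t_basic():
    t, p, _ = two_tailed_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert (t, p) == (0.0, 1.0)
    t, p, _ = two_tailed_t([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
    assert p < 0.001 and significance_stars(p) == "***"
    t, p, _ = two_tailed_t([2.0, 2.0], [2.0, 2.0])
    assert p == 1.0
    with pytest.raises(ValueError):
        two_tailed_t([1.0], [1.0, 2.0])


def test_mean_sem():
    m, s = mean_sem([1.0, 2.0, 3.0])
    assert m == 2.0
    assert s == pytest.approx(1.0 / math.sqrt(3))
    assert math.isnan(mean_sem([])[0])
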