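"""Classification rules: efferent identification, ribbon partnership,
polarity preference."""

import logging

import pytest
from hypothesis import given, settings, strategies as st

from neuromast.annotation import (AnnotationConfig, annotate,
                                  assign_ribbon_partners, classify_terminals,
                                  identify_entering_terminals,
                                  terminal_polarity_preference)
from neuromast.model import (AnnotationStateError, MembraneContact,
                             RibbonSynapse, Terminal)
from neuromast.synthetic import GenotypeModel, generate_connectome


def test_efferent_rule(tiny_connectome):
    conn = tiny_connectome
    for t in conn.terminals.values():
        t.kind = "unclassified"
    classify_terminals(conn)
    assert conn.terminals["E"].kind == "efferent"
    assert conn.terminals["A1"].kind == "afferent"
    assert conn.terminals["A2"].kind == "afferent"


def test_ribbon_apposition_disqualifies_efferent(tiny_connectome):
    conn = tiny_connectome
    conn.ribbons["R3"] = RibbonSynapse("R3", "H1", appositions={"E": 1e4})
    classify_terminals(conn)
    assert conn.terminals["E"].kind == "afferent"


def test_efferent_needs_full_coverage_and_flags(tiny_connectome):
    conn = tiny_connectome
    # drop one of the efferent's contacts: no longer contacts every mature cell
    del conn.contacts[("E", "H2")]
    classify_terminals(conn)
    assert conn.terminals["E"].kind == "afferent"
    conn.add_contact(MembraneContact("H2", "E", 3e5))
    conn.terminals["E"].structural_flags = frozenset({"vesicle-filled bouton"})
    classify_terminals(conn)
    assert conn.terminals["E"].kind == "afferent"
    classify_terminals(conn, AnnotationConfig(efferent_requires_flags=False))
    assert conn.terminals["E"].kind == "efferent"


def test_two_efferent_candidates_warn_not_error(tiny_connectome, caplog):
    conn = tiny_connectome
    conn.terminals["E2"] = Terminal(
        "E2", structural_flags=frozenset({"vesicle-filled bouton",
                                          "postsynaptic cistern"}))
    conn.add_contact(MembraneContact("H1", "E2", 1e5))
    conn.add_contact(MembraneContact("H2", "E2", 1e5))
    with caplog.at_level(logging.WARNING, logger="neuromast.annotation"):
        classify_terminals(conn)
    assert conn.terminals["E2"].kind == "efferent"
    assert any("efferent candidates" in r.message for r in caplog.records)


def test_classification_requires_contacts(tiny_connectome):
    tiny_connectome.contacts = None
    with pytest.raises(AnnotationStateError):
        classify_terminals(tiny_connectome)


def test_classify_is_idempotent():
    conn, ledger = generate_connectome(GenotypeModel(), 3)
    first = {t.terminal_id: t.kind for t in conn.terminals.values()}
    classify_terminals(conn)
    classify_terminals(conn)
    assert {t.terminal_id: t.kind for t in conn.terminals.values()} == first
    assert first[ledger.efferent_id] == "efferent"


def test_entering_flags():
    conn, _ = generate_connectome(GenotypeModel(n_nonentering=2), 1)
    entering = identify_entering_terminals(conn)
    assert "NE01" not in entering and "NE02" not in entering
    assert all(t in entering for t in conn.terminals if t.startswith("A"))


@pytest.mark.parametrize("areas,tol,expected", [
    ({"A1": 1e5}, 0.10, [("A1", 1.0)]),
    ({"A1": 1e5, "A2": 1e5}, 0.10, [("A1", 0.5), ("A2", 0.5)]),
    ({"A1": 1e5, "A2": 9.5e4}, 0.10, [("A1", 0.5), ("A2", 0.5)]),
    ({"A1": 1e5, "A2": 9.5e4}, 0.01, [("A1", 1.0)]),
    ({"A1": 5e4, "A2": 1e5, "A3": 2e4}, 0.10, [("A2", 1.0)]),
])
def test_ribbon_partner_assignment(areas, tol, expected):
    rib = RibbonSynapse("R", "H", appositions=areas)
    assign_ribbon_partners(rib, config=AnnotationConfig(tie_area_tolerance=tol))
    assert sorted(rib.assignments) == sorted(expected)
    assert not rib.unpartnered


def test_unpartnered_ribbon_flagged_not_dropped():
    rib = RibbonSynapse("R", "H", appositions={})
    assign_ribbon_partners(rib)
    assert rib.unpartnered and rib.assignments == []


@settings(derandomize=True, max_examples=60)
@given(st.dictionaries(st.sampled_from(["A1", "A2", "A3", "A4"]),
                       st.floats(1.0, 1e6), min_size=1, max_size=4))
def test_assignment_weights_always_sum_to_one(areas):
    rib = RibbonSynapse("R", "H", appositions=areas)
    assign_ribbon_partners(rib)
    assert sum(w for _, w in rib.assignments) == pytest.approx(1.0)
    assert 1 <= len(rib.assignments) <= 2


def test_polarity_preference_majority(tiny_connectome):
    conn = tiny_connectome
    assert terminal_polarity_preference("A1", conn) == "caudad"
    assert terminal_polarity_preference("A2", conn) == "rostrad"


def test_preference_contact_fallback_on_tie(tiny_connectome):
    conn = tiny_connectome
    # equal ribbon weight from both polarities, contact area 2:1 caudad
    conn.ribbons["R3"] = RibbonSynapse("R3", "H2", appositions={"A1": 1e5},
                                       assignments=[("A1", 1.0)])
    conn.add_contact(MembraneContact("H2", "A1", 2.5e5))   # caudad H1 has 5e5
    assert terminal_polarity_preference("A1", conn) == "caudad"


def test_preference_unassigned_without_evidence(tiny_connectome):
    conn = tiny_connectome
    conn.terminals["A3"] = Terminal("A3", kind="afferent")
    assert terminal_polarity_preference("A3", conn) == "unassigned"


def test_immature_cells_do_not_vote(tiny_connectome):
    conn = tiny_connectome
    conn.haircells["H1"].age_class = "0-5h"
    conn.haircells["H1"].mature = False
    conn.haircells["H1"].polarity = "undetermined"
    # A1's only synapse is on the nascent cell: falls back to contacts,
    # which also exclude it, so the preference is unassigned
    del conn.contacts[("A1", "H1")]
    assert terminal_polarity_preference("A1", conn) == "unassigned"


def test_annotate_recovers_planted_preferences():
    model = GenotypeModel(specificity_error=0.0, contact_area_error=0.0)
    for seed in range(10):
        conn, ledger = generate_connectome(model, seed)
        annotate(conn)
        for tid, term in conn.terminals.items():
            if term.kind != "afferent" or not term.enters_neuromast:
                continue
            if ledger.terminal_weight.get(tid, 0.0) > 0:
                assert term.polarity_preference == ledger.terminal_identity[tid]
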