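"""Synthetic generator: reproducibility, validity, and planted ground truth."""

import numpy as np
import pytest

from neuromast.model import validate, write_connectome_tables
from neuromast.stats import (mixed_terminal_fraction, redundancy_stats,
                             sibling_exclusivity, specificity_stats)
from neuromast.synthetic import (GenotypeModel, generate_age_cohort,
                                 generate_connectome, generate_traces)


def test_identical_seed_identical_tables(tmp_path):
    model = GenotypeModel(genotype="trilobite")
    for label in ("x", "y"):
        conn, _ = generate_connectome(model, 17)
        write_connectome_tables(conn, tmp_path / label)
    for name in ("cells.tsv", "traces.tsv", "ribbons.tsv", "associations.tsv"):
        assert (tmp_path / "x" / name).read_bytes() == \
            (tmp_path / "y" / name).read_bytes()


@pytest.mark.parametrize("genotype", ["wild-type", "trilobite",
                                      "notch-overexpression"])
def test_generator_output_always_validates(genotype):
    model = GenotypeModel(genotype=genotype, n_haircell_pairs=5)
    for seed in range(100):
        conn, _ = generate_connectome(model, seed)
        assert validate(conn) == []


def test_cell_and_branch_counts_in_study_range():
    for seed in range(20):
        conn, _ = generate_connectome(GenotypeModel(), seed)
        assert 8 <= len(conn.haircells) <= 20
        entering = [t for t in conn.terminals.values() if t.enters_neuromast]
        assert len(entering) == 10   # 9 afferent branches + 1 efferent


def test_wildtype_siblings_opposite():
    for seed in range(20):
        conn, ledger = generate_connectome(GenotypeModel(), seed)
        for hc in conn.haircells.values():
            if not hc.mature:
                continue
            sib = conn.haircells[hc.sibling_id]
            assert {hc.polarity, sib.polarity} == {"caudad", "rostrad"}
            assert {hc.ap_position, sib.ap_position} == {"anterior", "posterior"}
            assert hc.polarity == ("caudad" if hc.ap_position == "anterior"
                                   else "rostrad")


def test_notch_uniform_rostrad_and_shared_identity():
    model = GenotypeModel(genotype="notch-overexpression")
    for seed in range(10):
        conn, ledger = generate_connectome(model, seed)
        for hc in conn.haircells.values():
            if hc.mature:
                assert hc.polarity == "rostrad"
            assert ledger.sibling_identity[hc.cell_id] == \
                ledger.sibling_identity[hc.sibling_id]


def test_trilobite_unique_identity_per_pair():
    model = GenotypeModel(genotype="trilobite")
    for seed in range(10):
        _, ledger = generate_connectome(model, seed)
        for cid, ident in ledger.sibling_identity.items():
            sib = [c for c in ledger.sibling_identity
                   if c != cid and abs(int(c[2:]) - int(cid[2:])) == 1
                   and (int(cid[2:]) - 1) // 2 == (int(c[2:]) - 1) // 2]
            assert len(sib) == 1
            assert ledger.sibling_identity[sib[0]] != ident


def test_ledger_covers_every_entity():
    conn, ledger = generate_connectome(GenotypeModel(), 12)
    assert set(ledger.ribbon_match) == set(conn.ribbons)
    assert set(ledger.terminal_identity) == set(conn.terminals)
    assert set(ledger.cell_identity) == set(conn.haircells)


def test_ledger_mismatch_recovered_exactly():
    model = GenotypeModel(specificity_error=0.06)
    for seed in range(15):
        conn, ledger = generate_connectome(model, seed)
        rep = specificity_stats([conn])
        assert rep.weighted_opposite == pytest.approx(ledger.mismatch_weight)


def test_partner_count_planting_recovers_poisson_mean():
    model = GenotypeModel(allocation="poisson-partners", n_afferents=16,
                          age_mix=(0.0, 0.0, 1.0),
                          partners_per_cell={"5-15h": 1.0, ">15h": 3.0})
    ns = []
    seed = 0
    while len(ns) < 200:
        conn, ledger = generate_connectome(model, seed)
        rep = redundancy_stats([conn])
        ns.extend(r["ribbon"] for r in rep["per_cell"]
                  if r["age_class"] == ">15h")
        for rec in rep["per_cell"]:
            assert rec["ribbon"] == ledger.planted_partner_counts[rec["cell"]]
        seed += 1
    ns = np.asarray(ns, float)
    se = ns.std(ddof=1) / np.sqrt(len(ns))
    assert abs(ns.mean() - 3.0) < 3 * se + 0.15   # small clip bias at pool edge


def test_trace_fixture_ledger_closed_forms():
    _, ledger = generate_traces([500, 500], [50.0], height=1000, n_sections=10)
    assert ledger.expected_area("C1", "C2") == (1000 + 20) * 30 * 10
    _, ledger = generate_traces([500, 500], [70.0], n_sections=10)
    assert ledger.expected_area("C1", "C2") == 0.0
    _, ledger = generate_traces([500, 500], [50.0], n_sections=10,
                                occluded_gaps=[0])
    assert ledger.expected_area("C1", "C2") == 0.0


def test_trace_generator_input_validation():
    with pytest.raises(ValueError):
        generate_traces([500, 500], [-1.0])
    with pytest.raises(ValueError):
        generate_traces([500, 500], [50.0], occluded_gaps=[3])


def test_model_validation():
    with pytest.raises(ValueError):
        GenotypeModel(specificity_error=1.5)
    with pytest.raises(ValueError):
        GenotypeModel(dominance_weights=(0.9, 0.9))
    with pytest.raises(ValueError):
        GenotypeModel(n_afferents=3)
    with pytest.raises(ValueError):
        GenotypeModel(age_mix=(0.5, 0.5, 0.5))


def test_age_cohort_validation_and_masking():
    with pytest.raises(ValueError):
        generate_age_cohort(9, class_proportions=(0.98, 0.01, 0.01), seed=0)
    X, y, mask = generate_age_cohort(60, seed=0)
    assert X.shape == (60, 4) and mask.all()
    assert set(y) == {"0-5h", "5-15h", ">15h"}
    assert all(X[i, 2] == 0.0 for i in range(60) if y[i] == "0-5h")


def test_nonentering_fiber_excluded_from_branch_count():
    from neuromast.stats import branch_count_stats
    conn, _ = generate_connectome(GenotypeModel(n_nonentering=1), 4)
    assert branch_count_stats([conn])["counts"] == [10]


def test_mixed_fraction_zero_for_error_free_wildtype():
    model = GenotypeModel(specificity_error=0.0, contact_area_error=0.0)
    conns = [generate_connectome(model, s)[0] for s in range(10)]
    assert mixed_terminal_fraction(conns)["mixed_fraction"] == 0.0


def test_notch_every_pair_shares_a_terminal():
    model = GenotypeModel(genotype="notch-overexpression")
    for seed in range(5):
        conn, _ = generate_connectome(model, seed)
        rep = sibling_exclusivity([conn])
        flags = rep["per_pair"][conn.specimen_id]
        assert flags and all(flags.values())
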