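import numpy as np
import pytest

from neuromast.model import (HairCell, MembraneContact, NeuromastConnectome,
                             RibbonSynapse, Terminal)
from neuromast.synthetic import GenotypeModel, generate_connectome


@pytest.fixture(scope="session")
def wt_connectome():
    conn, ledger = generate_connectome(GenotypeModel(), seed=42)
    return conn, ledger


@pytest.fixture()
def tiny_connectome():
    """Two mature opposite-polarity cells, two afferents, one efferent."""
    conn = NeuromastConnectome("toy", "wild-type")
    conn.haircells["H1"] = HairCell("H1", polarity="caudad", ap_position="anterior",
                                    sibling_id="H2", age_class=">15h", mature=True)
    conn.haircells["H2"] = HairCell("H2", polarity="rostrad", ap_position="posterior",
                                    sibling_id="H1", age_class=">15h", mature=True)
    conn.terminals["A1"] = Terminal("A1", kind="afferent")
    conn.terminals["A2"] = Terminal("A2", kind="afferent")
    conn.terminals["E"] = Terminal(
        "E", kind="efferent",
        structural_flags=frozenset({"vesicle-filled bouton", "postsynaptic cistern"}))
    conn.ribbons["R1"] = RibbonSynapse("R1", "H1", appositions={"A1": 1e5},
                                       assignments=[("A1", 1.0)])
    conn.ribbons["R2"] = RibbonSynapse("R2", "H2", appositions={"A2": 1e5},
                                       assignments=[("A2", 1.0)])
    conn.contacts = {}
    conn.add_contact(MembraneContact("H1", "A1", 5e5))
    conn.add_contact(MembraneContact("H2", "A2", 5e5))
    conn.add_contact(MembraneContact("H1", "E", 3e5))
    conn.add_contact(MembraneContact("H2", "E", 3e5))
    conn.perisynaptic = {("H1", "A1"), ("H2", "A2")}
    return conn


def square_trace(cell_id, section, side, x0=0.0, y0=0.0):
    from neuromast.model import ContourTrace
    verts = np.array([[x0, y0], [x0 + side, y0],
                      [x0 + side, y0 + side], [x0, y0 + side]])
    return ContourTrace(cell_id, section, verts)
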