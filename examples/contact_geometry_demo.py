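"""Membrane contact areas under the 60 nm rule.

Two rectangular cell profiles, 50 nm apart over ten 30 nm sections, have a
closed-form contact area; the arc-sampling algorithm and the dense
brute-force oracle both reproduce it, and an occluding trace in the
corridor abolishes the contact.
"""

from neuromast.geometry import (GeometryConfig, brute_force_contact_area,
                                contact_area)
from neuromast.synthetic import generate_traces

cfg = GeometryConfig()   # 60 nm threshold, 30 nm sections, 6 nm sampling

traces, ledger = generate_traces([500, 500], [50.0], height=1000, n_sections=10)
closed = ledger.expected_area("C1", "C2", cfg)
main = contact_area("C1", "C2", traces, cfg).area
oracle = brute_force_contact_area("C1", "C2", traces, cfg)
print(f"closed form : {closed:,.0f} nm^2")
print(f"algorithm   : {main:,.0f} nm^2")
print(f"oracle      : {oracle:,.0f} nm^2")

at_limit, _ = generate_traces([500, 500], [60.0], n_sections=10)
print(f"gap = 60 nm : {contact_area('C1', 'C2', at_limit, cfg).area:,.0f} nm^2 "
      "(strictly less than 60 nm is required)")

occluded, _ = generate_traces([500, 500], [50.0], n_sections=10,
                              occluded_gaps=[0])
print(f"occluded    : {contact_area('C1', 'C2', occluded, cfg).area:,.0f} nm^2 "
      "(a third trace intervenes)")

# The closed form includes the wrap of the <60 nm zone around the facing
# corners: (1000 + 2*(60-50)) nm of contact per section.
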