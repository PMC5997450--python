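"""Generate one wild-type neuromast and summarize its wiring.

Builds a synthetic organ at the study's default scale (5-7 sibling pairs
of hair cells, 9 afferent branches, 1 efferent), runs the annotation
rules, and prints the headline wiring statistics.
"""

from neuromast.annotation import annotate
from neuromast.stats import branch_count_stats, redundancy_stats, specificity_stats
from neuromast.synthetic import GenotypeModel, generate_connectome

conn, ledger = generate_connectome(GenotypeModel(), seed=42)
annotate(conn)

print(f"specimen {conn.specimen_id}: {len(conn.haircells)} hair cells, "
      f"{len(conn.terminals)} terminals, {len(conn.ribbons)} ribbon synapses")

spec = specificity_stats([conn])
print(f"ribbon specificity      : {100 * spec.ribbon_specificity:.1f}% "
      f"({spec.opposite_ribbons} of {spec.total_ribbons} active zones opposite)")
print(f"contact-area specificity: {100 * spec.contact_specificity_all:.1f}%")

branches = branch_count_stats([conn])
print(f"entering branches       : {branches['counts'][0]}")

red = redundancy_stats([conn])
young = red["by_age"]["5-15h"]["ribbon"]["mean"]
old = red["by_age"][">15h"]["ribbon"]["mean"]
print(f"synaptic partners per cell: {young:.1f} at 5-15 h -> {old:.1f} after 15 h")

# The specificity numbers say how much of the wiring respects hair-bundle
# polarity; partners-per-cell shows the redundancy that accrues with age.
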