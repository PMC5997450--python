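# neuromast-connectomics

Quantitative analysis of the wiring diagram of the zebrafish lateral-line
neuromast, for researchers working with serial-blockface EM reconstructions
of sensory microcircuits.

A neuromast contains 8–20 mechanosensory hair cells split into two
subpopulations of opposing directional sensitivity (*rostrad*, toward the
head, and *caudad*, toward the tail), innervated by roughly nine afferent
axonal branches and one efferent terminal. This package turns per-section
membrane contour annotations and ribbon-synapse records into the statistics
that characterize such a microcircuit — polarity **specificity**,
innervation **redundancy**, and afferent-arbor **dominance** — and ships a
synthetic-data generator with planted ground truth for wild-type,
*trilobite* (vangl2-deficient), and Notch-overexpression wiring so that
every stage is testable without EM volumes.

## What it computes

**Membrane contact areas.** Two membranes on a section are in contact where
their traces are separated by less than ϑ = 60 nm (the tracing precision)
and no other trace intervenes. The per-section contact length of cells
*a, b* is the arc length

L(a,b) = |{ s ∈ ∂a : d(s, ∂b) < ϑ, segment to nearest point unoccluded }|

sampled at the 6 nm pixel pitch, symmetrized by averaging the two directed
lengths, and integrated over 30 nm sections: A = Σ L̄ · Δz. A brute-force
1 nm sampler serves as an independent oracle in the tests.

**Circuit annotation.** A terminal is *efferent* iff it contacts every
mature hair cell, is apposed to no synaptic ribbon, and shows the
diagnostic vesicle-filled bouton and postsynaptic cistern; all others are
afferent. Each ribbon (presynaptic active zone) is assigned to the terminal
occupying the largest apposed area, or split half-and-half when the top two
areas agree within 10 %. A terminal's polarity preference is the majority
polarity of its ribbon partners, weighted by ribbon share.

**Wiring statistics.** Specificity (fraction of ribbons / contact area /
perisynaptic occupancy on polarity-appropriate terminals, stratified by
hair-cell age), redundancy (distinct partners per cell), dominance
(per-cell dominant-arbor share and per-organ ranked arbor shares), sibling
exclusivity, the mixed-terminal fraction used to score mutants by
anteroposterior position, branch counts, and two-tailed pooled-variance
Student t tests for group comparisons.

**Age classification.** Hair cells lacking time-lapse preimaging are
assigned to the 0–5 h / 5–15 h / >15 h post-mitotic classes by a
from-scratch CART (Gini impurity, axis-aligned splits, JSON-serializable)
trained on four morphometric features with a 70/30 split.

## Worked example

```
$ python examples/wildtype_connectome.py
specimen SYN-wild-type-42: 10 hair cells, 10 terminals, 29 ribbon synapses
ribbon specificity      : 100.0% (0 of 29 active zones opposite)
contact-area specificity: 92.0%
entering branches       : 10
synaptic partners per cell: 2.0 at 5-15 h -> 2.3 after 15 h
```

All 29 active zones of this organ sit on polarity-appropriate terminals,
92 % of the hair-cell–afferent membrane contact area is polarity-specific,
ten neuronal branches enter the organ, and cells accumulate synaptic
partners as they mature. `examples/` contains similar narrated scripts for
contact geometry, mutant-versus-wild-type comparison, and age
classification; the `neuromast` command-line entry point runs the whole
pipeline (`neuromast run --seed 1 --n-specimens 8 --out out/`) and writes
GraphML wiring diagrams, JSON/text reports, and a manifest that reproduces
every output byte-for-byte.

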