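# Methods

## Data model and conventions

One `NeuromastConnectome` holds a single reconstructed specimen: hair cells
(polarity, anteroposterior position relative to the sibling, sibling link,
post-mitotic age class, maturity), axonal terminals (afferent/efferent,
basal-lamina crossing flag, annotator-supplied structural flags), ribbon
synapses (apposed terminals with areas, derived weighted assignments,
ribbon volume), membrane contacts, and perisynaptic memberships. All
lengths are nanometres; x increases toward the tail; sections are indexed
from 0 at 30 nm pitch. *Rostrad*/*caudad* always denote the direction of
mechanical sensitivity, never a cell's position — an anteriorly positioned
wild-type cell is caudad-sensitive — and `ap_position` is deliberately a
separate field so the two vocabularies cannot be conflated.

Annotation tables use four TSV files (`cells.tsv`, `traces.tsv`,
`ribbons.tsv`, `associations.tsv`); hair cells and terminals share
`cells.tsv` under an `entity_class` column, and planted contacts and
perisynaptic pairs share `associations.tsv` under `assoc_type`.
Perisynaptic membership is an input annotation: the compartment is bounded
by supporting cells, which are not traced, so it cannot be derived from
hair-cell and terminal contours alone. Writing and re-loading a connectome
is exact (floats serialize via `repr`), which the round-trip tests assert
field-for-field.

## Contact geometry

Two traces are in contact where they are separated by **strictly less
than** 60 nm — the precision of manual membrane tracing — with no
intervening trace. The directed contact length of trace *a* toward *b*
samples ∂a at uniform arc steps (default 6 nm, the lateral pixel pitch, so
discretization matches the source-data resolution), keeps samples whose
distance to ∂b is below threshold, and discards samples whose
nearest-point segment is occluded. Directed lengths are averaged
(the annotation literature does not say whether the original measurement
was directed, and averaging makes A(a,b) ≡ A(b,a) exactly); areas
integrate mean lengths over the section thickness.

"No other trace intervened" admits more than one geometric reading, so two
occlusion modes are provided: **strict** (default; the straight segment
from a sample to its nearest point on the other trace crosses a third
polygon's boundary) and **corridor** (the quadrilateral hull between
neighbouring matched arcs intersects a third polygon). Both agree on
unobstructed and fully occluded fixtures; partial occlusion differs only
at arc-step resolution.

Intersecting contours of the two measured cells raise a segmentation-defect
error; *nested* contours are accepted (a cell enclosing another on a
section is legitimate topology, exercised by the concentric-square tests).
For parallel facing edges of length h at gap g the qualifying arc per
section is exactly h + 2·(ϑ − g): the sub-threshold zone wraps around the
facing corners onto the receding perpendicular edges. This closed form —
not the bare h — is what both the algorithm and the trace-generator ledger
use.

The brute-force oracle re-implements the same contract in plain numpy:
boundaries densely sampled at ≤ 1 nm, nearest neighbours by exhaustive
distance matrices (chunked), occlusion by segment–edge crossing tests. It
shares no code with the shapely-based path. Oracle-equivalence tests
compare the two within 2 % — or within a few sampling quanta
(step × thickness) where contact areas are near zero, the same absolute
slack the closed-form cases use, since a relative bound is ill-posed as the
area vanishes. Equivalence fixtures are flattened random convex hulls whose
facing boundaries are long and gently curved, the regime in which membrane
appositions actually occur; gap values concentrate below 50 nm or above
threshold because gaps within a few nanometres of ϑ yield arcs of a few
tens of nanometres where any finite sampling dominates.

## Annotation rules

* **Efferent identification**: contacts every mature hair cell, zero ribbon
  appositions, and (by default) both diagnostic structures. More than one
  candidate logs a warning rather than failing — most organs have exactly
  one efferent, but not all.
* **Ribbon partnership**: largest apposed area wins the ribbon; a relative
  area difference ≤ 10 % (configurable `tie_area_tolerance`) counts as
  "occupied equally" and splits the ribbon 0.5/0.5. No ribbon is ever split
  more than two ways. Ribbons with no apposed terminal are flagged
  unpartnered and counted separately, not dropped.
* **Polarity preference**: weighted ribbon majority over mature, polarized
  cells; ties and synapse-free terminals fall back to the majority of
  membrane contact area with polarized cells (mirroring the inference used
  for terminals known only from contacts with neighbouring mature cells);
  a residual tie leaves the terminal unassigned. Cells 0–5 h post-mitosis
  never vote: they have neither settled polarity nor stable position.

## Statistics

Half-ribbons contribute fractional weight to all weighted tallies; integer
active-zone counts (each ribbon once) are reported alongside and used where
whole-ribbon counts are quoted. 0–5 h cells are excluded from specificity
and mixed-fraction statistics but retained in redundancy and dominance.
Pooling across specimens is by summed counts (micro-average), with
per-specimen macro-averages also reported; contact specificity is reported
both pooled over all labelled ages and restricted to >15 h cells. Group
comparisons use the pooled-variance two-tailed Student t test with
n₁+n₂−2 degrees of freedom and the conventional star coding
(0.05/0.01/0.001); two zero-variance samples with equal means return p = 1.
Specimens whose bundle polarity is uninformative (*trilobite*, Notch) are
grouped by anteroposterior position instead of polarity.

## Age classifier

A binary CART with axis-aligned thresholds minimizing Gini impurity,
written directly so the model is fully inspectable and serializes to JSON
(feature index, threshold, children, leaf class). Features: traced
membrane area (perimeter × thickness), cell volume (polygon area ×
thickness), total ribbon volume, and apical surface area over the
annotated apical sections. Defaults `max_depth=3`, `min_leaf=3` suit an
~90-sample training regime; the 70/30 train/test split is the only
randomized step, and training is bit-deterministic given data, seed, and
hyperparameters. Features are not standardized — axis-aligned splits are
scale-equivariant, and the tests assert prediction invariance under a
consistent nm→µm unit change. Splits must strictly reduce impurity;
tie-breaks prefer the lowest feature index, then the lowest threshold.
Gradient boosting, which performed comparably in the motivating setting,
is out of scope.

## Synthetic generator

The generator emits annotated connectomes in the same table schema the
loaders consume, with a ledger recording every planted quantity. Defaults
are the printed study conditions: 5–7 sibling pairs (8–20 cells including
nascent ones), 9 afferent branches plus 1 efferent, specificity error
ε = 4/344 ≈ 0.012, 8 % off-polarity contact area, dominance simplex
(0.55, 0.30, 0.10, 0.05) padded with zeros for larger pools (the padding
reproduces the minority of branches that enter but make no associations),
and ~1 synaptic partner per 5–15 h cell growing toward ~2 after 15 h.
Age mix defaults to 20/35/45 % across the three classes — a chosen-once
stand-in, as no class census is printed. Ribbon counts per cell are
1+Poisson(1) (5–15 h) and 2+Poisson(2) (>15 h), matching ~40 active zones
per organ. One explicit PCG64 stream drives everything; identical
(model, seed) pairs are bit-identical at the table level.

Genotype rules: wild-type siblings take opposite polarities with identity
following position (anterior ⇒ caudad-sensitive); *trilobite* allocates
the two identities uniquely within each pair but places them on positions
at random, with random bundle orientations; Notch overexpression gives
both siblings the same identity and uniformly rostrad bundles, and plants
a membrane contact between every ribbon partner and the sibling, so
sibling sharing is universal by construction.

Two allocation modes exist. In the default **dominance** mode each ribbon
draws its terminal independently from the identity pool's dominance
simplex (flattened by an exponent of 0.4 for 5–15 h cells, whose
innervation is still diffuse), and with probability ε is flipped to the
opposite pool. Flips are resolved after matched wiring is laid down and
avoid the sibling's partner terminals where possible — sibling exclusivity
is empirically intact even where polarity specificity fails, and the
off-polarity contact area obeys the same avoidance. After allocation, each
active terminal is topped up with matched ribbons until its matched weight
strictly exceeds any flipped weight; this guarantees, by construction,
that the derived preference of every active terminal equals its planted
identity, so planted mismatch counts are recovered *exactly* by the
statistics stage. Forced draws are ledgered and excluded from
parameter-recovery estimates. The **poisson-partners** mode instead plants
the distinct-partner count per cell as 1+Poisson(λ−1) for distributional
checks of the redundancy statistic; ε is not applied there.

Trace fixtures are a separate path: rectangular cell profiles at
prescribed gaps (optionally with corridor-spanning occluders) whose exact
contact areas the ledger computes in closed form, plus random flattened
convex-hull pairs for oracle equivalence. Age-cohort features are
class-conditional log-normals whose separation parameter scales every
class difference (at separation 0 the classes are identically distributed,
including the zero ribbon volume of nascent cells).

**What the generator does not emulate.** Contact-area error is
age-independent, so the growth of contact specificity with maturation is
not reproduced. Per-cell dominant-arbor shares emerge from small synapse
counts: a 5–15 h cell with one or two ribbons cannot have a dominant share
below one half, so the low dominant share of young cells in real organs —
where dominance is also diluted across many weak contacts — appears here
only at the pool level (the flattened young simplex), not per cell.
Spatial structure (soma positions, basal projections, cupula) is absent;
wiring is generated at the table level and volumetric emulation of a whole
organ is out of scope. Passing tests therefore certify the measurement
pipeline and the wiring statistics, not a generative model of neuromast
development.

## Pipeline and reproducibility

`RunConfig` selects tables or synthetic input (a seed is mandatory for the
latter), geometry and annotation configs, and an output directory. A run
writes per-specimen annotation tables and ledgers (synthetic mode),
GraphML bipartite wiring diagrams, one JSON+text report per analysis, and
a manifest (config, seed, package versions) sufficient to reproduce every
report byte-for-byte; reports from tables mode on a generator's own output
are byte-identical to the synthetic run that produced them. Problem sizes
throughout the tests and the acceptance script — eight wild-type, four
trilobite, and two Notch organs; 50-organ recovery cohorts; 200 oracle
pairs; 1000 null t tests; 200 permutation refits — are the study's own
specimen counts or sizes at which the sampling error of the checked
quantity is a few percent.
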