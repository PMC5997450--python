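"""Train the CART age classifier on a synthetic morphometric cohort.

Mimics a cohort in which 88 of 149 hair cells carry preimaged age labels:
the tree is trained on a random 70% of the labeled cells, scored on the
remaining 30%, then used to classify the unlabeled cells.
"""

import collections

from neuromast.age import train_tree
from neuromast.synthetic import generate_age_cohort

X, labels, mask = generate_age_cohort(n_cells=149, n_labeled=88, seed=9)
labeled = [l for l, m in zip(labels, mask) if m]

model = train_tree(X[mask], labeled, split_fraction=0.7, seed=9)
print(f"trained on {int(0.7 * mask.sum())} cells; "
      f"held-out accuracy {model.test_accuracy:.2f}")

predicted = model.predict(X[~mask])
print("predicted classes for the 61 unlabeled cells:",
      dict(collections.Counter(predicted)))
print("model serializes to JSON:", len(model.to_json()), "characters")

# Features: traced membrane area, cell volume, total ribbon volume, and
# apical surface area - all of which grow as a hair cell matures.
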