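"""Inspect the tree audit file: one line per leaf, with the leaf's candidate
count, its mean label (the calling score) and the root-to-leaf decisions.

"Name> t" marks the branch where the feature exceeded the threshold,
"Name<= t" the other branch.
"""

from pathlib import Path

from leafcall import SimConfig, TrainConfig, call_variants, parse_tree_file, simulate_dataset
from leafcall.cart import Leaf, predict_leaf
import numpy as np

res = simulate_dataset(SimConfig(seed=7, genome_length=60_000, n_snv=60, n_ins=12, n_del=12), "example_tree")
call_variants(res["alignments"], res["known_vcf"], res["reference_dir"], "example_tree/sample",
              train_config=TrainConfig(min_leaf=10, min_split=20))

text = Path("example_tree/sample.tree").read_text()
print("tree file:")
for line in text.splitlines():
    print("  " + line)

# the file is self-describing: parsing it back gives an equivalent predictor
tree = parse_tree_file("example_tree/sample.tree")
leaf = predict_leaf(tree, np.zeros(12))
print(f"\nan all-zero feature vector falls into a leaf with mean qual {leaf.mean_qual:.3f}")
print("(low score: zero depth and ratio look nothing like a real variant)")
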