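"""Build charge-difference scoring matrices from a molecule corpus.

All absolute Gasteiger-charge differences in the corpus are binned in 0.1
steps over [0, 3); each bin scores the log2 survival probability of seeing
that difference or larger, shifted so the bin holding the mean difference
scores 0.  Paired matrices do the same per element pair.
"""

from smilesalign import build_all_vs_all, build_paired
from smilesalign.fixtures import combined_corpus, corpus_blueprints

blueprints = corpus_blueprints(combined_corpus())
matrix = build_all_vs_all(blueprints)

print(f"corpus: {len(blueprints)} molecules, "
      f"{matrix.n_observations} charge differences")
print(f"mean |dq| = {matrix.mean_diff:.3f}  ->  zero-score bin "
      f"{int(matrix.mean_diff / 0.1)}")
print(f"score(|dq|=0.0) = {matrix.score(0.0):+.3f}   (best reward)")
print(f"score(|dq|=0.5) = {matrix.score(0.5):+.3f}")
print(f"floor           = {matrix.floor:+.3f}   (largest penalty)")

paired = build_paired(blueprints, min_pair_observations=100)
print("\npaired matrices for:", ", ".join("-".join(k) for k in sorted(paired.matrices)))
cc = paired.matrix_for("C", "C")
co = paired.matrix_for("C", "O")
print(f"C-C score at |dq|=0.3: {cc.score(0.3):+.3f}")
print(f"C-O score at |dq|=0.3: {co.score(0.3):+.3f}")
# C-O charge differences are typically larger than C-C ones, so the same
# numeric difference is less surprising (less penalized) for C-O.
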