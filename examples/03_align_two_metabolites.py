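"""Globally align two Krebs-cycle metabolites.

The affine-gap Needleman-Wunsch DP aligns the charge blueprints; the
stripped SMILES characters are reinserted afterwards, with '-' marking
gap columns (a display string, since '-' is also a SMILES bond symbol).
"""

from smilesalign import GapPenalties, align, build_all_vs_all
from smilesalign.fixtures import combined_corpus, corpus_blueprints

matrix = build_all_vs_all(corpus_blueprints(combined_corpus()))

citrate = "OC(=O)CC(O)(CC(=O)O)C(=O)O"
succinate = "OC(=O)CCC(=O)O"
res = align(citrate, succinate, matrix, GapPenalties(g_open=1.0, g_extend=0.5))

ga, gb = res.gapped_token_strings
print("citrate   :", res.aligned_smiles_a)
print("succinate :", res.aligned_smiles_b)
print("tokens    :", ga)
print("           ", gb)
print(f"score = {res.score:.3f}  (mode={res.mode}, "
      f"g_open={res.penalties.g_open}, g_extend={res.penalties.g_extend})")
# Positive column scores mean the paired atoms' charges differ less than the
# corpus average; the five extra citrate atoms sit in gap columns.
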