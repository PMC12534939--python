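"""From a raw SMILES to a charge blueprint.

A molecule is canonicalized, split into atom tokens and a skeleton of
non-atomic characters, and given one Gasteiger partial charge per heavy
atom.  The charge list is what the aligner actually sees.
"""

from smilesalign import compute_blueprint

bp = compute_blueprint("OC(=O)CC(=O)C(=O)O", molecule_id="oxaloacetate")

print("canonical SMILES :", bp.canonical_smiles)
print("token string     :", bp.token_string)
print("charges          :", [round(q, 3) for q in bp.charges])
print("round trip OK    :", bp.reconstruct() == bp.canonical_smiles)

# The token string is the molecule with bonds/rings/parentheses stripped;
# the charges mirror electronegativity: carboxyl carbons are strongly
# positive, oxygens negative.  The skeleton lets us put the stripped
# characters back after alignment.
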