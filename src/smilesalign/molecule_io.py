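"""Reading, canonicalizing and decomposing SMILES into charge blueprints.

A molecule enters the aligner as a *charge blueprint*: the ordered list of
heavy-atom tokens of its canonical SMILES, one Gasteiger partial charge per
token, and a *skeleton* — the canonical SMILES with every atom token replaced
by a placeholder slot so the original characters can be reinserted after
alignment.  Bonds, ring closures, parentheses and bracket punctuation stay in
the skeleton; they carry no partial charge and would only add noise to the
alignment.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

logger = logging.getLogger(__name__)

__all__ = [
    "AtomToken",
    "ChargeBlueprint",
    "CanonizationStabilityReport",
    "SmilesParseError",
    "MalformedSmilesError",
    "ChargeComputationError",
    "EmptyBlueprintError",
    "InconsistentAlignmentError",
    "canonicalize",
    "tokenize_atoms",
    "compute_blueprint",
    "gasteiger_charges",
    "reinsert",
    "oxygen_to_sulfur_variants",
    "canonization_stability",
    "read_smiles_file",
    "GAP",
    "PLACEHOLDER",
]

#: Sentinel marking a gap column in a gapped token sequence.
GAP = None

#: Placeholder character standing in for one atom token in a skeleton string.
#: NUL cannot occur in a SMILES string, so substitution is unambiguous.
PLACEHOLDER = "\x00"

# Atom tokens of the SMILES grammar: a bracket atom is one token (isotope,
# charge and H-count travel with the atom); two-letter organic-subset halogens
# before single letters; aromatic lowercase atoms are tokens too.
_ATOM_TOKEN_RE = re.compile(r"\[[^\[\]]+\]|Br|Cl|[BCNOPSFI]|[bcnops]")
_BRACKET_ELEMENT_RE = re.compile(r"\[(?:\d+)?(?:([A-Z][a-z]?)|([a-z]{1,2}))")


class SmilesParseError(ValueError):
    """A SMILES string could not be parsed into a molecule."""


class MalformedSmilesError(SmilesParseError):
    """Unbalanced brackets/parentheses or otherwise broken SMILES syntax."""


class ChargeComputationError(RuntimeError):
    """The charge provider failed for a molecule."""


class EmptyBlueprintError(ValueError):
    """All atoms of a molecule were filtered out (non-finite charges)."""


class InconsistentAlignmentError(ValueError):
    """Gapped tokens do not match the blueprint they claim to come from."""


@dataclass(frozen=True)
class AtomToken:
    """One atom of a canonical SMILES string.

    ``symbol`` is the token exactly as written (``"C"``, ``"Cl"``, ``"c"``,
    or a full bracket body such as ``"[N+]"``); ``element`` is the normalized
    periodic-table symbol; ``span`` is the half-open character interval of the
    token in the canonical SMILES.
    """

    symbol: str
    element: str
    atom_index: int
    span: tuple[int, int]


@dataclass
class ChargeBlueprint:
    """A molecule reduced to atom tokens, partial charges and a skeleton."""

    molecule_id: str
    canonical_smiles: str
    tokens: list[AtomToken]
    charges: list[float]
    skeleton: str

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.charges):
            raise ValueError(
                f"{self.molecule_id}: {len(self.tokens)} tokens but "
                f"{len(self.charges)} charges"
            )
        if any(not math.isfinite(q) for q in self.charges):
            raise ValueError(f"{self.molecule_id}: non-finite charge in blueprint")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def n_atoms(self) -> int:
        return len(self.tokens)

    @property
    def elements(self) -> list[str]:
        return [t.element for t in self.tokens]

    @property
    def token_string(self) -> str:
        """Concatenated element symbols — the stripped representation."""
        return "".join(t.element for t in self.tokens)

    def reconstruct(self) -> str:
        """Substitute tokens back into the skeleton (round-trip check)."""
        segments = self.skeleton.split(PLACEHOLDER)
        out: list[str] = []
        for seg, tok in zip(segments, self.tokens):
            out.append(seg)
            out.append(tok.symbol)
        out.append(segments[len(self.tokens)])
        return "".join(out)


@dataclass(frozen=True)
class CanonizationStabilityReport:
    """Summary of how much S-for-O substitution perturbs a canonical SMILES."""

    parent_id: str
    n_variants: int
    mean_levenshtein: float
    std_levenshtein: float
    mean_tanimoto_distance: float
    std_tanimoto_distance: float


# ---------------------------------------------------------------------------
# canonicalization


def _parse(smiles: str) -> Chem.Mol:
    if _unbalanced(smiles):
        raise MalformedSmilesError(f"unbalanced brackets/parentheses in {smiles!r}")
    mol = Chem.MolFromSmiles(smiles, sanitize=True)
    if mol is None:
        raise SmilesParseError(f"could not parse SMILES {smiles!r}")
    return mol


def _unbalanced(smiles: str) -> bool:
    for open_c, close_c in ("()", "[]"):
        depth = 0
        for ch in smiles:
            if ch == open_c:
                depth += 1
            elif ch == close_c:
                depth -= 1
                if depth < 0:
                    return True
        if depth != 0:
            return True
    return False


def rdkit_canonicalize(smiles: str) -> str:
    """Default canonicalizer backend: RDKit canonical SMILES."""
    return Chem.MolToSmiles(_parse(smiles))


def canonicalize(smiles: str, backend: Callable[[str], str] | None = None) -> str:
    """Return a canonical SMILES for ``smiles``.

    The backend contract is: deterministic and idempotent
    (``backend(backend(s)) == backend(s)``).  The default backend is RDKit.

    Raises
    ------
    SmilesParseError
        If the input does not parse as a molecule.
    """
    if backend is None:
        backend = rdkit_canonicalize
    return backend(smiles)


# ---------------------------------------------------------------------------
# tokenization


def _element_of(symbol: str) -> str:
    if symbol.startswith("["):
        m = _BRACKET_ELEMENT_RE.match(symbol)
        if m is None:
            raise MalformedSmilesError(f"cannot read element from {symbol!r}")
        elem = m.group(1) or m.group(2)
    else:
        elem = symbol
    elem = elem.capitalize()
    if Chem.GetPeriodicTable().GetAtomicNumber(elem) == 0 and elem != "*":
        raise MalformedSmilesError(f"{elem!r} is not an element symbol")
    return elem


def tokenize_atoms(canonical_smiles: str) -> tuple[list[AtomToken], str]:
    """Split a canonical SMILES into atom tokens and a skeleton string.

    The skeleton keeps every non-atomic character (bond symbols, ring-closure
    digits, parentheses) and carries one :data:`PLACEHOLDER` per atom;
    substituting the tokens back in order reproduces the input byte-for-byte.
    """
    if _unbalanced(canonical_smiles):
        raise MalformedSmilesError(
            f"unbalanced brackets/parentheses in {canonical_smiles!r}"
        )
    tokens: list[AtomToken] = []
    skeleton_parts: list[str] = []
    pos = 0
    for i, m in enumerate(_ATOM_TOKEN_RE.finditer(canonical_smiles)):
        symbol = m.group(0)
        tokens.append(
            AtomToken(
                symbol=symbol,
                element=_element_of(symbol),
                atom_index=i,
                span=(m.start(), m.end()),
            )
        )
        skeleton_parts.append(canonical_smiles[pos : m.start()])
        skeleton_parts.append(PLACEHOLDER)
        pos = m.end()
    skeleton_parts.append(canonical_smiles[pos:])
    return tokens, "".join(skeleton_parts)


# ---------------------------------------------------------------------------
# charges


def gasteiger_charges(mol: Chem.Mol) -> list[float]:
    """Default charge provider: Gasteiger-Marsili PEOE charges via RDKit.

    Returns one heavy-atom partial charge (elementary-charge units) per atom,
    in atom-index order.  Non-finite values are passed through; filtering is
    the caller's job.
    """
    AllChem.ComputeGasteigerCharges(mol)
    return [a.GetDoubleProp("_GasteigerCharge") for a in mol.GetAtoms()]


def compute_blueprint(
    smiles: str,
    charge_provider: Callable[[Chem.Mol], Sequence[float]] | None = None,
    molecule_id: str | None = None,
    canonicalizer: Callable[[str], str] | None = None,
) -> ChargeBlueprint:
    """Canonicalize, tokenize and charge a molecule.

    Atoms whose charge comes back non-finite (NaN/±inf — unusual atom types or
    numerical trouble in the iterative charge model) are removed from both the
    token and charge lists, and their placeholder slots collapse out of the
    skeleton; each removal is logged with the molecule id.

    Raises
    ------
    ChargeComputationError
        If the provider itself fails.
    EmptyBlueprintError
        If every atom of a non-empty molecule is filtered out.
    """
    if charge_provider is None:
        charge_provider = gasteiger_charges
    mid = molecule_id if molecule_id is not None else smiles
    if smiles == "":
        # The empty molecule: legal as an alignment operand.
        return ChargeBlueprint(mid, "", [], [], "")
    canonical = canonicalize(smiles, backend=canonicalizer)
    mol = _parse(canonical)
    tokens, skeleton = tokenize_atoms(canonical)
    if len(tokens) != mol.GetNumAtoms():
        raise MalformedSmilesError(
            f"{mid}: tokenizer found {len(tokens)} atoms but the toolkit "
            f"reports {mol.GetNumAtoms()} for {canonical!r}"
        )
    try:
        charges = list(charge_provider(mol))
    except Exception as exc:  # provider contract: any failure surfaces as ours
        raise ChargeComputationError(f"{mid}: charge provider failed: {exc}") from exc
    if len(charges) != len(tokens):
        raise ChargeComputationError(
            f"{mid}: provider returned {len(charges)} charges for "
            f"{len(tokens)} atoms"
        )

    keep = [i for i, q in enumerate(charges) if math.isfinite(q)]
    if len(keep) < len(tokens):
        for i in range(len(tokens)):
            if i not in keep:
                logger.warning(
                    "molecule %s: atom %d (%s) has non-finite charge %r; removed",
                    mid, i, tokens[i].symbol, charges[i],
                )
    if not keep:
        raise EmptyBlueprintError(f"{mid}: all atoms filtered (non-finite charges)")
    if len(keep) < len(tokens):
        tokens, skeleton, charges = _drop_atoms(tokens, skeleton, charges, keep)
    return ChargeBlueprint(mid, canonical, tokens, charges, skeleton)


def _drop_atoms(
    tokens: list[AtomToken],
    skeleton: str,
    charges: Sequence[float],
    keep: list[int],
) -> tuple[list[AtomToken], str, list[float]]:
    """Collapse filtered atoms' slots out of the skeleton."""
    segments = skeleton.split(PLACEHOLDER)
    new_segments: list[str] = [""]
    kept_tokens: list[AtomToken] = []
    for i, tok in enumerate(tokens):
        if i in keep:
            new_segments[-1] += segments[i]
            new_segments.append("")
            kept_tokens.append(
                AtomToken(tok.symbol, tok.element, len(kept_tokens), tok.span)
            )
        else:
            new_segments[-1] += segments[i]
    new_segments[-1] += segments[len(tokens)]
    new_skeleton = PLACEHOLDER.join(new_segments)
    return kept_tokens, new_skeleton, [charges[i] for i in keep]


# ---------------------------------------------------------------------------
# reinsertion


def reinsert(
    alignment_tokens: Sequence[AtomToken | None],
    blueprint: ChargeBlueprint,
    gap_symbol: str = "-",
) -> str:
    """Put the stripped SMILES characters back into a gapped token sequence.

    Gap columns become ``gap_symbol``.  Because ``-`` is also a SMILES bond
    character the result is a display string, not necessarily valid SMILES.
    With zero gaps the output equals ``blueprint.canonical_smiles`` exactly.
    """
    real = [t for t in alignment_tokens if t is not GAP]
    if real != blueprint.tokens:
        raise InconsistentAlignmentError(
            f"{blueprint.molecule_id}: gapped tokens do not match blueprint"
        )
    segments = blueprint.skeleton.split(PLACEHOLDER)
    out: list[str] = []
    seg_i = 0
    for tok in alignment_tokens:
        if tok is GAP:
            out.append(gap_symbol)
        else:
            out.append(segments[seg_i])
            out.append(tok.symbol)
            seg_i += 1
    out.append(segments[len(blueprint.tokens)])
    return "".join(out)


# ---------------------------------------------------------------------------
# canonization-stability experiment


def oxygen_to_sulfur_variants(smiles: str) -> list[str]:
    """One variant per oxygen atom, that oxygen replaced by sulfur.

    Substitution happens on the molecule as given; the variant is
    canonicalized only afterwards, so the experiment probes how far a small
    chemically valid edit moves the canonical string.
    """
    mol = _parse(smiles)
    variants: list[str] = []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 8:
            continue
        edited = Chem.RWMol(mol)
        a = edited.GetAtomWithIdx(atom.GetIdx())
        a.SetAtomicNum(16)
        if a.GetIsAromatic():
            a.SetIsAromatic(True)
        try:
            Chem.SanitizeMol(edited)
        except Exception:
            logger.warning("variant of %s at atom %d failed sanitization; skipped",
                           smiles, atom.GetIdx())
            continue
        variants.append(Chem.MolToSmiles(edited))
    return variants


def canonization_stability(
    parents: Sequence[str] | Sequence[tuple[str, str]],
) -> list[CanonizationStabilityReport]:
    """Levenshtein and Tanimoto distance between parents and their S-variants.

    ``parents`` is a list of SMILES or of ``(id, SMILES)`` pairs.  Per parent:
    mean and population std of (a) edit distance between the canonical parent
    and each canonical variant string, (b) Tanimoto *distance* (1 − Tanimoto
    coefficient) between their fingerprints.  Parents with no variants are
    excluded with a warning.
    """
    from .validation import levenshtein_distance, tanimoto_coefficient

    items: list[tuple[str, str]] = [
        p if isinstance(p, tuple) else (p, p) for p in parents
    ]
    reports: list[CanonizationStabilityReport] = []
    for pid, smi in items:
        parent_canonical = canonicalize(smi)
        variants = oxygen_to_sulfur_variants(smi)
        if not variants:
            logger.warning("parent %s has no oxygen atoms; excluded", pid)
            continue
        lev = np.array(
            [levenshtein_distance(parent_canonical, v) for v in variants],
            dtype=float,
        )
        tan = np.array(
            [1.0 - tanimoto_coefficient(parent_canonical, v) for v in variants]
        )
        reports.append(
            CanonizationStabilityReport(
                parent_id=pid,
                n_variants=len(variants),
                mean_levenshtein=float(lev.mean()),
                std_levenshtein=float(lev.std()),
                mean_tanimoto_distance=float(tan.mean()),
                std_tanimoto_distance=float(tan.std()),
            )
        )
    return reports


# ---------------------------------------------------------------------------
# file input


def read_smiles_file(path) -> list[tuple[str, str]]:
    """Read ``(id, smiles)`` pairs from a plain-text or CSV molecule file.

    Accepted layouts: one SMILES per line; tab-separated ``id<TAB>smiles``
    lines; or a CSV with header columns ``id,smiles``.  Lines starting with
    ``#`` are comments.
    """
    import csv

    rows: list[tuple[str, str]] = []
    with open(path, newline="") as fh:
        text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        return rows
    header = [c.strip().lower() for c in re.split(r"[,\t]", lines[0])]
    if "smiles" in header:
        dialect = "\t" if "\t" in lines[0] else ","
        reader = csv.DictReader(lines, delimiter=dialect)
        reader.fieldnames = [f.strip().lower() for f in reader.fieldnames or []]
        for rec in reader:
            rows.append(((rec.get("id") or rec["smiles"]).strip(), rec["smiles"].strip()))
        return rows
    for i, ln in enumerate(lines):
        parts = ln.split("\t")
        if len(parts) >= 2:
            rows.append((parts[0].strip(), parts[1].strip()))
        else:
            rows.append((f"mol{i}", parts[0].strip()))
    return rows
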