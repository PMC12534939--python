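"""Bundled molecule sets and a seeded random-SMILES generator.

Everything here exists so that the rest of the package is exercisable
offline: small reconstructed metabolite sets for the Krebs cycle, glycolysis
and the pentose phosphate cycle (standard textbook structures, not copies of
any external corpus), a mixed demo set, matching truth alignments, and a
random molecule generator for property tests.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .pathway_analysis import Pathway

__all__ = [
    "FixtureCorpus",
    "builtin_corpus",
    "builtin_pathway",
    "builtin_truth",
    "combined_corpus",
    "corpus_blueprints",
    "random_smiles",
    "CORPUS_NAMES",
]

CORPUS_NAMES = ("krebs", "glycolysis", "ppp", "demo")

_PATHWAY_CYCLIC = {"krebs": True, "glycolysis": False, "ppp": True}


@dataclass
class FixtureCorpus:
    name: str
    molecules: list[tuple[str, str]]  # (id, SMILES)
    provenance: str


def _data_path(filename: str) -> Path:
    return Path(str(resources.files("smilesalign") / "data" / filename))


def _read_corpus_tsv(path: Path) -> tuple[list[tuple[str, str]], str]:
    comments: list[str] = []
    rows: list[tuple[int, str, str]] = []
    for ln in path.read_text().splitlines():
        if ln.startswith("#"):
            comments.append(ln.lstrip("# "))
            continue
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if parts[0] in ("order", "position"):
            continue
        rows.append((int(parts[0]), parts[1], parts[2]))
    rows.sort()
    return [(mid, smi) for _, mid, smi in rows], " ".join(comments)


def builtin_corpus(name: str) -> FixtureCorpus:
    """A bundled molecule set: ``krebs``, ``glycolysis``, ``ppp`` or ``demo``."""
    if name not in CORPUS_NAMES:
        raise ValueError(
            f"unknown corpus {name!r}; available: {', '.join(CORPUS_NAMES)}"
        )
    molecules, provenance = _read_corpus_tsv(_data_path(f"{name}.tsv"))
    return FixtureCorpus(name=name, molecules=molecules, provenance=provenance)


def builtin_pathway(name: str) -> Pathway:
    """A bundled corpus as an ordered pathway (krebs/ppp cyclic, glycolysis linear)."""
    if name not in _PATHWAY_CYCLIC:
        raise ValueError(
            f"unknown pathway {name!r}; available: {', '.join(_PATHWAY_CYCLIC)}"
        )
    corpus = builtin_corpus(name)
    return Pathway(name=name, molecules=corpus.molecules, cyclic=_PATHWAY_CYCLIC[name])


def builtin_truth(name: str):
    """Bundled reconstructed truth alignments for ``krebs`` or ``glycolysis``."""
    from .validation import TruthSet

    if name not in ("krebs", "glycolysis"):
        raise ValueError(f"no bundled truth set named {name!r}")
    return TruthSet.from_tsv(_data_path(f"truth_{name}.tsv"), name=name)


def combined_corpus() -> FixtureCorpus:
    """All bundled corpora pooled (duplicate ids keep their first entry)."""
    seen: dict[str, str] = {}
    for name in CORPUS_NAMES:
        for mid, smi in builtin_corpus(name).molecules:
            seen.setdefault(mid, smi)
    return FixtureCorpus(
        name="combined",
        molecules=list(seen.items()),
        provenance="union of the bundled krebs, glycolysis, ppp and demo sets",
    )


def corpus_blueprints(corpus: FixtureCorpus):
    """Charge blueprints for every molecule of a corpus."""
    from .molecule_io import compute_blueprint

    return [compute_blueprint(smi, molecule_id=mid) for mid, smi in corpus.molecules]


# ---------------------------------------------------------------------------
# random molecule generator

_ELEMENTS = ["C", "C", "C", "C", "O", "O", "N", "S"]  # weights by repetition
_VALENCE = {"C": 4, "O": 2, "N": 3, "S": 2}


def random_smiles(
    seed: int,
    n: int,
    max_heavy_atoms: int = 8,
    allow_charged: bool = False,
) -> list[str]:
    """Deterministic random small molecules as canonical SMILES.

    Molecules are built as valence-checked random graphs over {C, O, N, S}
    with single/double bonds, branches, and at most one ring, then emitted as
    canonical SMILES — every output is valid by construction.  Charged
    bracket atoms (an N⁺ here and there) only appear with ``allow_charged``.
    """
    if n < 1 or max_heavy_atoms < 1:
        raise ValueError("n and max_heavy_atoms must be >= 1")
    rng = random.Random(seed)
    return [_random_molecule(rng, max_heavy_atoms, allow_charged) for _ in range(n)]


def _random_molecule(rng: random.Random, max_heavy: int, allow_charged: bool) -> str:
    from rdkit import Chem

    n_atoms = rng.randint(1, max_heavy)
    mol = Chem.RWMol()
    first = rng.choice(_ELEMENTS)
    mol.AddAtom(Chem.Atom(first))
    free = [_VALENCE[first]]
    for _ in range(n_atoms - 1):
        candidates = [i for i, f in enumerate(free) if f >= 1]
        if not candidates:
            break
        parent = rng.choice(candidates)
        elem = rng.choice(_ELEMENTS)
        double = free[parent] >= 2 and _VALENCE[elem] >= 2 and rng.random() < 0.2
        order = 2 if double else 1
        idx = mol.AddAtom(Chem.Atom(elem))
        mol.AddBond(
            parent, idx,
            Chem.BondType.DOUBLE if double else Chem.BondType.SINGLE,
        )
        free[parent] -= order
        free.append(_VALENCE[elem] - order)
    if mol.GetNumAtoms() >= 3 and rng.random() < 0.3:
        _close_one_ring(rng, mol, free)
    if allow_charged and rng.random() < 0.3:
        for atom in mol.GetAtoms():
            if atom.GetSymbol() == "N":
                atom.SetFormalCharge(1)  # N+ tolerates one extra bond/H
                break
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def _close_one_ring(rng: random.Random, mol, free: list[int]) -> None:
    from rdkit import Chem

    candidates = [i for i, f in enumerate(free) if f >= 1]
    rng.shuffle(candidates)
    for ai in range(len(candidates)):
        for bi in range(ai + 1, len(candidates)):
            a, b = candidates[ai], candidates[bi]
            if mol.GetBondBetweenAtoms(a, b) is None:
                mol.AddBond(a, b, Chem.BondType.SINGLE)
                free[a] -= 1
                free[b] -= 1
                return
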