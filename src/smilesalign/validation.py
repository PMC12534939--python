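"""Similarity metrics and the gap-parameter validation sweep.

Produced alignments are judged against curated truth alignments on the
stripped token strings (element symbols plus gap characters), with two
string similarities: *Levenshtein similarity* ``1 − d/max(|s1|, |s2|)`` and
*exact similarity*, the fraction of identical positions.  The sweep runs the
aligner at every integer (g_open, g_extend) combination in [−5, 5]² — 121
cells — and averages both similarities over the molecule pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np

from .alignment import GapPenalties, Scorer, align_blueprints
from .molecule_io import ChargeBlueprint, compute_blueprint

logger = logging.getLogger(__name__)

__all__ = [
    "TruthEntry",
    "TruthSet",
    "SweepCell",
    "levenshtein_distance",
    "levenshtein_similarity",
    "exact_similarity",
    "tanimoto_coefficient",
    "parameter_sweep",
    "best_parameters",
    "sweep_to_frame",
    "truth_from_mcs",
]

SWEEP_RANGE = range(-5, 6)


# ---------------------------------------------------------------------------
# string similarities


def levenshtein_distance(s1: str, s2: str) -> int:
    """Exact edit distance (insert/delete/substitute)."""
    if not s1 or not s2:
        return max(len(s1), len(s2))
    return edlib.align(s1, s2, task="distance")["editDistance"]


def levenshtein_similarity(s1: str, s2: str) -> float:
    """1 − d(s1, s2)/max(|s1|, |s2|); two empty strings count as identical."""
    if not s1 and not s2:
        return 1.0
    return 1.0 - levenshtein_distance(s1, s2) / max(len(s1), len(s2))


def exact_similarity(g1: str, g2: str, gap_symbol: str = "-") -> float:
    """Fraction of positions where two gapped strings agree.

    Unequal lengths are tolerated: the shorter string is padded with the gap
    symbol (logged), since truth and produced alignments can differ in total
    length.
    """
    if not g1 and not g2:
        return 1.0
    if len(g1) != len(g2):
        logger.debug(
            "exact_similarity: lengths differ (%d vs %d); padding with %r",
            len(g1), len(g2), gap_symbol,
        )
        width = max(len(g1), len(g2))
        g1 = g1.ljust(width, gap_symbol)
        g2 = g2.ljust(width, gap_symbol)
    return sum(a == b for a, b in zip(g1, g2)) / len(g1)


# ---------------------------------------------------------------------------
# fingerprint similarity

#: Fingerprint recorded in report metadata: RDKit hashed path fingerprint.
FINGERPRINT_PARAMS = {"kind": "rdkit_path", "fpSize": 2048, "maxPath": 7}


def _fingerprint(smiles: str):
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    from .molecule_io import SmilesParseError

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"could not parse SMILES {smiles!r}")
    gen = rdFingerprintGenerator.GetRDKitFPGenerator(
        fpSize=FINGERPRINT_PARAMS["fpSize"], maxPath=FINGERPRINT_PARAMS["maxPath"]
    )
    return gen.GetFingerprint(mol)


def tanimoto_coefficient(smiles_a: str, smiles_b: str) -> float:
    """|A∩B| / |A∪B| over hashed path-fingerprint bits."""
    from rdkit import DataStructs

    return DataStructs.TanimotoSimilarity(_fingerprint(smiles_a), _fingerprint(smiles_b))


# ---------------------------------------------------------------------------
# truth sets


@dataclass(frozen=True)
class TruthEntry:
    id_a: str
    id_b: str
    gapped_a: str
    gapped_b: str

    def __post_init__(self) -> None:
        if len(self.gapped_a) != len(self.gapped_b):
            raise ValueError(
                f"truth pair {self.id_a}/{self.id_b}: gapped strings differ in length"
            )


@dataclass
class TruthSet:
    """Curated gapped token-string alignments keyed by molecule-id pair."""

    name: str
    entries: list[TruthEntry]

    def lookup(self, id_a: str, id_b: str) -> tuple[str, str]:
        """Truth strings for a pair, in the requested order."""
        for e in self.entries:
            if (e.id_a, e.id_b) == (id_a, id_b):
                return e.gapped_a, e.gapped_b
            if (e.id_a, e.id_b) == (id_b, id_a):
                return e.gapped_b, e.gapped_a
        raise KeyError(f"no truth entry for pair ({id_a}, {id_b})")

    @classmethod
    def from_tsv(cls, path: str | Path, name: str | None = None) -> "TruthSet":
        """Read a TSV with columns pair_id, gapped_a, gapped_b.

        ``pair_id`` is ``"<id_a>|<id_b>"``; lines starting with # are comments.
        """
        path = Path(path)
        entries = []
        for ln in path.read_text().splitlines():
            if not ln.strip() or ln.startswith("#"):
                continue
            pair_id, ga, gb = ln.rstrip("\n").split("\t")
            if pair_id == "pair_id":
                continue
            id_a, id_b = pair_id.split("|")
            entries.append(TruthEntry(id_a, id_b, ga, gb))
        return cls(name=name or path.stem, entries=entries)

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        lines = []
        if header_comment:
            lines.extend(f"# {ln}" for ln in header_comment.splitlines())
        lines.append("pair_id\tgapped_a\tgapped_b")
        for e in self.entries:
            lines.append(f"{e.id_a}|{e.id_b}\t{e.gapped_a}\t{e.gapped_b}")
        Path(path).write_text("\n".join(lines) + "\n")


def truth_from_mcs(
    molecules: Sequence[tuple[str, str]], name: str, gap_symbol: str = "-"
) -> TruthSet:
    """Reconstruct a truth set from maximum-common-substructure atom maps.

    For every unordered pair the RDKit MCS atom correspondence is projected
    onto the canonical token orders; the largest subset of matches that is
    monotone in both orders (longest increasing subsequence) defines the
    aligned columns, and everything else is gapped (tokens of the first
    molecule before those of the second between consecutive matches).  This
    is a *synthetic reconstruction* of site correspondence from shared
    substructure, standing in for manually curated biochemical truth.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFMCS

    blueprints = {mid: compute_blueprint(smi, molecule_id=mid) for mid, smi in molecules}
    mols = {mid: Chem.MolFromSmiles(bp.canonical_smiles) for mid, bp in blueprints.items()}
    entries: list[TruthEntry] = []
    ids = [mid for mid, _ in molecules]
    for i, ia in enumerate(ids):
        for ib in ids[i + 1 :]:
            res = rdFMCS.FindMCS([mols[ia], mols[ib]], timeout=10)
            pairs: list[tuple[int, int]] = []
            if res.numAtoms > 0:
                patt = Chem.MolFromSmarts(res.smartsString)
                ma = mols[ia].GetSubstructMatch(patt)
                mb = mols[ib].GetSubstructMatch(patt)
                pairs = sorted(zip(ma, mb))
                pairs = _longest_increasing(pairs)
            ga, gb = _gapped_from_matches(
                blueprints[ia], blueprints[ib], pairs, gap_symbol
            )
            entries.append(TruthEntry(ia, ib, ga, gb))
    return TruthSet(name=name, entries=entries)


def _longest_increasing(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest subsequence strictly increasing in the second coordinate
    (the list is already sorted by the first)."""
    if not pairs:
        return []
    best_len = [1] * len(pairs)
    prev = [-1] * len(pairs)
    for i in range(len(pairs)):
        for j in range(i):
            if pairs[j][1] < pairs[i][1] and best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    k = max(range(len(pairs)), key=lambda i: best_len[i])
    out = []
    while k != -1:
        out.append(pairs[k])
        k = prev[k]
    return out[::-1]


def _gapped_from_matches(
    bp_a: ChargeBlueprint,
    bp_b: ChargeBlueprint,
    pairs: list[tuple[int, int]],
    gap_symbol: str,
) -> tuple[str, str]:
    ea, eb = bp_a.elements, bp_b.elements
    ga: list[str] = []
    gb: list[str] = []
    pa = pb = 0
    for ma, mb in pairs + [(len(ea), len(eb))]:
        for k in range(pa, ma):
            ga.append(ea[k])
            gb.append(gap_symbol)
        for k in range(pb, mb):
            ga.append(gap_symbol)
            gb.append(eb[k])
        if ma < len(ea):
            ga.append(ea[ma])
            gb.append(eb[mb])
        pa, pb = ma + 1, mb + 1
    return "".join(ga), "".join(gb)


# ---------------------------------------------------------------------------
# parameter sweep


@dataclass(frozen=True)
class SweepCell:
    g_open: int
    g_extend: int
    mean_levenshtein_similarity: float
    mean_exact_similarity: float

    @property
    def difference(self) -> float:
        return self.mean_levenshtein_similarity - self.mean_exact_similarity


def parameter_sweep(
    pairs: Sequence[tuple[tuple[str, str], tuple[str, str]]],
    truth: TruthSet,
    scorer: Scorer,
    grid: Iterable[int] = SWEEP_RANGE,
    gap_symbol: str = "-",
) -> list[SweepCell]:
    """Run the aligner over the full (g_open, g_extend) grid.

    ``pairs`` is a list of ``((id_a, smiles_a), (id_b, smiles_b))``.  Each
    cell averages over pairs the Levenshtein and exact similarity between the
    produced and truth gapped token strings; the per-pair value is the mean
    over the pair's two strings.  Cells are ordered g_open-major.
    """
    grid = list(grid)
    blueprints: dict[str, ChargeBlueprint] = {}
    for (ia, sa), (ib, sb) in pairs:
        blueprints.setdefault(ia, compute_blueprint(sa, molecule_id=ia))
        blueprints.setdefault(ib, compute_blueprint(sb, molecule_id=ib))
        truth.lookup(ia, ib)  # fail early, naming the pair
    cells: list[SweepCell] = []
    for go in grid:
        for ge in grid:
            lev: list[float] = []
            exact: list[float] = []
            for (ia, _), (ib, _) in pairs:
                res = align_blueprints(
                    blueprints[ia], blueprints[ib], scorer,
                    GapPenalties(go, ge), gap_symbol,
                )
                pa, pb = res.gapped_token_strings
                ta, tb = truth.lookup(ia, ib)
                lev.append(
                    0.5 * (levenshtein_similarity(pa, ta) + levenshtein_similarity(pb, tb))
                )
                exact.append(
                    0.5 * (exact_similarity(pa, ta, gap_symbol)
                           + exact_similarity(pb, tb, gap_symbol))
                )
            cells.append(
                SweepCell(go, ge, float(np.mean(lev)), float(np.mean(exact)))
            )
    return cells


def sweep_to_frame(cells: Sequence[SweepCell]):
    import pandas as pd

    return pd.DataFrame(
        {
            "gap_open": [c.g_open for c in cells],
            "gap_extend": [c.g_extend for c in cells],
            "mean_levenshtein": [c.mean_levenshtein_similarity for c in cells],
            "mean_exact": [c.mean_exact_similarity for c in cells],
            "difference": [c.difference for c in cells],
        }
    )


def best_parameters(cells: Sequence[SweepCell]) -> tuple[int, int]:
    """Cell with the highest mean Levenshtein similarity.

    Ties break toward the smaller Levenshtein−exact difference, then
    lexicographically on (g_open, g_extend) — fully deterministic.
    """
    if not cells:
        raise ValueError("empty sweep")
    best = min(
        cells,
        key=lambda c: (-c.mean_levenshtein_similarity, c.difference,
                       c.g_open, c.g_extend),
    )
    return best.g_open, best.g_extend
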