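"""Charge-difference scoring matrices.

The aligner scores a substitution by how surprising the absolute difference
of the two atoms' Gasteiger charges is in a reference corpus.  Differences
are binned in 0.1 steps over [0, 3); each bin's raw score is the base-2 log
of the survival probability — the fraction of observed differences greater
than or equal to the bin's lower edge — in the spirit of BLOSUM log-odds.
Raw scores are then shifted so that the bin holding the corpus mean
difference scores exactly 0: smaller-than-average differences are rewarded,
larger ones penalized.

Two matrix flavours exist: *all-vs-all* pools every charge in the corpus into
one master list; *paired* builds one matrix per unordered element pair
(C–C, C–O, …) from that pair's charges, falling back to the all-vs-all
matrix for rare pairs.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .molecule_io import ChargeBlueprint

__all__ = [
    "BIN_WIDTH",
    "N_BINS",
    "MAX_DIFF",
    "bin_index",
    "ChargePool",
    "ScoringMatrix",
    "PairedScoringSet",
    "build_charge_pool",
    "pairwise_abs_differences",
    "build_scoring_matrix",
    "build_all_vs_all",
    "build_paired",
    "score_lookup",
]

BIN_WIDTH = 0.1
N_BINS = 30
MAX_DIFF = 3.0

# Guard against float-division artefacts when assigning bin indices
# (0.3 / 0.1 is 2.9999…96 in binary floating point).
_BIN_EPS = 1e-9


def bin_index(diff: float) -> int:
    """Bin of an absolute charge difference; differences ≥ 3 clamp to bin 29."""
    if diff < 0:
        raise ValueError("absolute difference cannot be negative")
    return min(int(math.floor(diff / BIN_WIDTH + _BIN_EPS)), N_BINS - 1)


@dataclass
class ChargePool:
    """All finite charges of a corpus, flat and partitioned by element."""

    charges: np.ndarray
    per_element: dict[str, np.ndarray]
    n_molecules: int

    def __post_init__(self) -> None:
        total = sum(len(v) for v in self.per_element.values())
        if total != len(self.charges):
            raise ValueError("per-element partition does not cover the pool")


def build_charge_pool(blueprints: Sequence[ChargeBlueprint]) -> ChargePool:
    """Aggregate blueprint charges into a master list, partitioned by element."""
    if not blueprints:
        raise ValueError("empty corpus")
    flat: list[float] = []
    per: dict[str, list[float]] = {}
    for bp in blueprints:
        for tok, q in zip(bp.tokens, bp.charges):
            flat.append(q)
            per.setdefault(tok.element, []).append(q)
    return ChargePool(
        charges=np.asarray(flat, dtype=float),
        per_element={e: np.asarray(v, dtype=float) for e, v in per.items()},
        n_molecules=len(blueprints),
    )


def pairwise_abs_differences(
    values_a: Sequence[float] | np.ndarray,
    values_b: Sequence[float] | np.ndarray | None = None,
) -> np.ndarray:
    """Exhaustive absolute charge differences.

    Single-list mode (``values_b is None``) returns |qᵢ − qⱼ| over all
    unordered pairs i < j — n(n−1)/2 values.  Two-list mode returns the full
    cross product, used for paired matrices of two distinct elements.
    """
    a = np.asarray(values_a, dtype=float)
    if values_b is None:
        if a.size < 1:
            raise ValueError("empty input")
        iu = np.triu_indices(a.size, k=1)
        return np.abs(a[iu[0]] - a[iu[1]])
    b = np.asarray(values_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("empty input")
    return np.abs(a[:, None] - b[None, :]).ravel()


@dataclass
class ScoringMatrix:
    """Binned log₂-survival scores over absolute charge differences."""

    raw_scores: np.ndarray
    mean_diff: float
    scores: np.ndarray
    n_observations: int
    bin_width: float = BIN_WIDTH
    bin_lower_edges: np.ndarray = field(
        default_factory=lambda: np.arange(N_BINS) * BIN_WIDTH
    )
    metadata: dict = field(default_factory=dict)

    @property
    def floor(self) -> float:
        """Most penalizing score in the matrix."""
        return float(self.scores.min())

    def score(self, diff: float) -> float:
        return float(self.scores[bin_index(diff)])

    def validate(self) -> None:
        """Raise if the matrix violates its construction contract."""
        if self.raw_scores[0] != 0.0:
            raise ValueError("raw_scores[0] must be 0 (survival probability 1)")
        if np.any(np.diff(self.raw_scores) > 1e-12):
            raise ValueError("raw scores must be monotone non-increasing")
        mu_bin = bin_index(self.mean_diff)
        if abs(self.scores[mu_bin]) > 1e-12:
            raise ValueError("bin containing the mean difference must score 0")
        if np.any(self.scores[:mu_bin] < -1e-12):
            raise ValueError("sub-mean bins must score >= 0")
        if np.any(self.scores[mu_bin + 1 :] > 1e-12):
            raise ValueError("super-mean bins must score <= 0")

    # -- serialization -----------------------------------------------------

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "bin_lower_edge": self.bin_lower_edges,
                "raw_score": self.raw_scores,
                "score": self.scores,
            }
        )

    def save(self, prefix: str | Path) -> None:
        """Write ``<prefix>.csv`` (bins) and ``<prefix>.json`` (metadata)."""
        prefix = Path(prefix)
        self.to_frame().to_csv(prefix.with_suffix(".csv"), index=False)
        meta = {
            "mean_diff": self.mean_diff,
            "n_observations": self.n_observations,
            "floor": self.floor,
            "bin_width": self.bin_width,
            **self.metadata,
        }
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, prefix: str | Path) -> "ScoringMatrix":
        import pandas as pd

        prefix = Path(prefix)
        df = pd.read_csv(prefix.with_suffix(".csv"))
        meta = json.loads(prefix.with_suffix(".json").read_text())
        known = {"mean_diff", "n_observations", "floor", "bin_width"}
        return cls(
            raw_scores=df["raw_score"].to_numpy(),
            mean_diff=float(meta["mean_diff"]),
            scores=df["score"].to_numpy(),
            n_observations=int(meta["n_observations"]),
            bin_width=float(meta["bin_width"]),
            bin_lower_edges=df["bin_lower_edge"].to_numpy(),
            metadata={k: v for k, v in meta.items() if k not in known},
        )


def build_scoring_matrix(
    diffs: Sequence[float] | np.ndarray, metadata: dict | None = None
) -> ScoringMatrix:
    """Build a matrix from an exhaustive multiset of absolute differences.

    ``raw_scores[k] = log₂(#{d ≥ 0.1·k} / N)``.  Bins with an empty tail get
    a pseudo-count of one observation (score ``log₂(1/N)``), which produces
    the flat maximum-penalty plateau seen for extreme differences.  Scores are
    raw scores shifted by ``−raw_scores[bin(μ)]`` where μ is the mean
    difference, so the μ bin scores exactly 0.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size == 0:
        raise ValueError("empty difference multiset")
    if np.any(~np.isfinite(d)) or np.any(d < 0):
        raise ValueError("differences must be finite and non-negative")
    n = d.size
    bins = np.minimum(np.floor(d / BIN_WIDTH + _BIN_EPS).astype(int), N_BINS - 1)
    counts = np.bincount(bins, minlength=N_BINS)
    survival = counts[::-1].cumsum()[::-1]  # #{d >= edge_k}
    raw = np.where(survival > 0, np.log2(np.maximum(survival, 1) / n), np.log2(1.0 / n))
    mu = float(d.mean())
    scores = raw - raw[bin_index(mu)]
    m = ScoringMatrix(
        raw_scores=raw,
        mean_diff=mu,
        scores=scores,
        n_observations=int(n),
        metadata=metadata or {},
    )
    m.validate()
    return m


def _corpus_hash(blueprints: Sequence[ChargeBlueprint]) -> str:
    h = hashlib.sha256()
    for bp in blueprints:
        h.update(bp.canonical_smiles.encode())
        h.update(b"\n")
    return h.hexdigest()[:16]


def build_all_vs_all(blueprints: Sequence[ChargeBlueprint]) -> ScoringMatrix:
    """All-vs-all matrix: every charge in the corpus against every other."""
    pool = build_charge_pool(blueprints)
    if pool.charges.size < 2:
        raise ValueError("need at least two charges in the corpus")
    diffs = pairwise_abs_differences(pool.charges)
    return build_scoring_matrix(
        diffs,
        metadata={"mode": "all_vs_all", "corpus_hash": _corpus_hash(blueprints),
                  "n_molecules": pool.n_molecules},
    )


@dataclass
class PairedScoringSet:
    """Element-pair-keyed scoring matrices with an all-vs-all fallback."""

    matrices: dict[tuple[str, str], ScoringMatrix]
    fallback: ScoringMatrix
    min_pair_observations: int

    @staticmethod
    def _key(element_a: str, element_b: str) -> tuple[str, str]:
        return tuple(sorted((element_a, element_b)))  # type: ignore[return-value]

    def matrix_for(self, element_a: str, element_b: str) -> ScoringMatrix:
        return self.matrices.get(self._key(element_a, element_b), self.fallback)

    def score(self, element_a: str, q_a: float, element_b: str, q_b: float) -> float:
        return self.matrix_for(element_a, element_b).score(abs(q_a - q_b))

    # -- serialization -----------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.fallback.save(directory / "fallback")
        manifest = {"min_pair_observations": self.min_pair_observations, "pairs": []}
        for (a, b), m in sorted(self.matrices.items()):
            name = f"pair_{a}_{b}"
            m.save(directory / name)
            manifest["pairs"].append([a, b])
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "PairedScoringSet":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        matrices = {
            (a, b): ScoringMatrix.load(directory / f"pair_{a}_{b}")
            for a, b in manifest["pairs"]
        }
        return cls(
            matrices=matrices,
            fallback=ScoringMatrix.load(directory / "fallback"),
            min_pair_observations=int(manifest["min_pair_observations"]),
        )


def build_paired(
    blueprints: Sequence[ChargeBlueprint],
    min_pair_observations: int = 100,
    intra_molecule_only: bool = False,
) -> PairedScoringSet:
    """One matrix per element pair with enough observations, plus fallback.

    By default charge pooling is cross-molecule: for a pair (A, B) every
    corpus charge of element A meets every corpus charge of element B
    (same-element pairs use unordered within-list differences), mirroring the
    all-vs-all construction.  ``intra_molecule_only`` restricts pairing to
    charges within the same molecule.
    """
    pool = build_charge_pool(blueprints)
    fallback = build_all_vs_all(blueprints)
    elements = sorted(pool.per_element)
    matrices: dict[tuple[str, str], ScoringMatrix] = {}
    for i, ea in enumerate(elements):
        for eb in elements[i:]:
            if intra_molecule_only:
                chunks = []
                for bp in blueprints:
                    qa = [q for t, q in zip(bp.tokens, bp.charges) if t.element == ea]
                    qb = [q for t, q in zip(bp.tokens, bp.charges) if t.element == eb]
                    if ea == eb:
                        if len(qa) >= 2:
                            chunks.append(pairwise_abs_differences(qa))
                    elif qa and qb:
                        chunks.append(pairwise_abs_differences(qa, qb))
                diffs = np.concatenate(chunks) if chunks else np.empty(0)
            else:
                if ea == eb:
                    qa = pool.per_element[ea]
                    diffs = (
                        pairwise_abs_differences(qa) if qa.size >= 2 else np.empty(0)
                    )
                else:
                    diffs = pairwise_abs_differences(
                        pool.per_element[ea], pool.per_element[eb]
                    )
            if diffs.size >= min_pair_observations:
                matrices[(ea, eb)] = build_scoring_matrix(
                    diffs,
                    metadata={"mode": "paired", "pair": [ea, eb],
                              "corpus_hash": _corpus_hash(blueprints)},
                )
    return PairedScoringSet(
        matrices=matrices,
        fallback=fallback,
        min_pair_observations=min_pair_observations,
    )


def score_lookup(
    matrix_or_set: ScoringMatrix | PairedScoringSet,
    element_a: str,
    q_a: float,
    element_b: str,
    q_b: float,
) -> float:
    """Substitution score for two atoms; symmetric in its arguments."""
    if isinstance(matrix_or_set, PairedScoringSet):
        return matrix_or_set.score(element_a, q_a, element_b, q_b)
    return matrix_or_set.score(abs(q_a - q_b))
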