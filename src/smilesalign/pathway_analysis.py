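"""Distance profiles over metabolic pathways.

A pathway is an ordered list of metabolites, cyclic (Krebs, the pentose
phosphate cycle) or linear (glycolysis).  Every unordered molecule pair is
aligned and its score grouped by pathway distance — for cyclic pathways the
minimum step count in either direction, min(|i−j|, n−|i−j|); for linear ones
|i−j|.  Distance 0 holds the self-alignments.  The profile reports the mean,
population standard deviation and pair count per distance; in a cyclic
pathway the mean score is expected to dip at the maximum distance and
recover, while linear pathways drift away from the starting molecule.

A Tanimoto-coefficient profile over the same grouping serves as the
fingerprint-similarity baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .alignment import GapPenalties, Scorer, alignment_score
from .molecule_io import ChargeBlueprint, compute_blueprint

__all__ = [
    "Pathway",
    "DistanceProfile",
    "min_cyclic_distance",
    "distance_profile",
    "tanimoto_profile",
]


def min_cyclic_distance(i: int, j: int, n: int) -> int:
    """Steps between positions i and j around an n-cycle, shorter way."""
    if not (0 <= i < n and 0 <= j < n):
        raise ValueError(f"indices {i},{j} out of range for n={n}")
    d = abs(i - j)
    return min(d, n - d)


@dataclass
class Pathway:
    """Ordered metabolites of one pathway."""

    name: str
    molecules: list[tuple[str, str]]  # (id, SMILES) in pathway order
    cyclic: bool

    def __post_init__(self) -> None:
        if len(self.molecules) < 2:
            raise ValueError(f"pathway {self.name}: need at least 2 molecules")
        ids = [mid for mid, _ in self.molecules]
        if len(set(ids)) != len(ids):
            raise ValueError(f"pathway {self.name}: duplicate molecule ids")

    def __len__(self) -> int:
        return len(self.molecules)

    @classmethod
    def from_tsv(cls, path: str | Path, cyclic: bool, name: str | None = None) -> "Pathway":
        """Read a pathway TSV (columns: order, id, smiles; # comments)."""
        path = Path(path)
        rows: list[tuple[int, str, str]] = []
        for ln in path.read_text().splitlines():
            if not ln.strip() or ln.startswith("#"):
                continue
            parts = ln.rstrip("\n").split("\t")
            if parts[0] in ("order", "position"):
                continue
            rows.append((int(parts[0]), parts[1], parts[2]))
        rows.sort()
        return cls(
            name=name or path.stem,
            molecules=[(mid, smi) for _, mid, smi in rows],
            cyclic=cyclic,
        )


@dataclass
class DistanceProfile:
    """Per-distance mean/std of pair scores over a pathway."""

    pathway_name: str
    metric: str  # "alignment" | "tanimoto"
    distances: np.ndarray
    mean_score: np.ndarray
    std: np.ndarray  # population std (÷N)
    n_pairs: np.ndarray
    pair_scores: pd.DataFrame = field(repr=False)  # id_a, id_b, distance, score

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "distance": self.distances,
                "mean_score": self.mean_score,
                "std": self.std,
                "n_pairs": self.n_pairs,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot(self, path: str | Path, title: str | None = None) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.errorbar(self.distances, self.mean_score, yerr=self.std,
                    marker="o", capsize=3)
        ax.set_xlabel("pathway distance")
        ax.set_ylabel("mean score")
        ax.set_title(title or f"{self.pathway_name} ({self.metric})")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def _pair_distances(n: int, cyclic: bool, versus_first: bool) -> list[tuple[int, int, int]]:
    """(i, j, distance) for every scored pair; self-pairs only at distance 0."""
    if versus_first:
        if cyclic:
            raise ValueError("versus-first profiling is defined for linear pathways")
        return [(0, j, j) for j in range(n)]
    out = [(i, i, 0) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d = min_cyclic_distance(i, j, n) if cyclic else j - i
            out.append((i, j, d))
    return out


def _profile_from_scores(
    pathway: Pathway, metric: str, records: list[tuple[str, str, int, float]]
) -> DistanceProfile:
    table = pd.DataFrame(records, columns=["id_a", "id_b", "distance", "score"])
    grouped = table.groupby("distance")["score"]
    dists = np.array(sorted(table["distance"].unique()))
    return DistanceProfile(
        pathway_name=pathway.name,
        metric=metric,
        distances=dists,
        mean_score=grouped.mean().loc[dists].to_numpy(),
        std=grouped.std(ddof=0).loc[dists].to_numpy(),
        n_pairs=grouped.count().loc[dists].to_numpy(),
        pair_scores=table,
    )


def distance_profile(
    pathway: Pathway,
    scorer: Scorer,
    penalties: GapPenalties = GapPenalties(),
    charge_provider: Callable | None = None,
    versus_first: bool = False,
) -> DistanceProfile:
    """Alignment-score profile of a pathway.

    Every unordered pair is aligned once and grouped by distance (self-pairs
    at distance 0).  For a cyclic pathway of n molecules the distances run
    0..⌊n/2⌋.  ``versus_first`` (linear only) instead scores each molecule
    against the starting molecule, one pair per distance.
    """
    blueprints = [
        compute_blueprint(smi, charge_provider=charge_provider, molecule_id=mid)
        for mid, smi in pathway.molecules
    ]
    records = []
    for i, j, d in _pair_distances(len(pathway), pathway.cyclic, versus_first):
        score = alignment_score(blueprints[i], blueprints[j], scorer, penalties)
        records.append((blueprints[i].molecule_id, blueprints[j].molecule_id, d, score))
    return _profile_from_scores(pathway, "alignment", records)


def tanimoto_profile(pathway: Pathway, versus_first: bool = False) -> DistanceProfile:
    """Tanimoto-coefficient profile with the same distance grouping."""
    from .validation import tanimoto_coefficient

    smiles = [smi for _, smi in pathway.molecules]
    ids = [mid for mid, _ in pathway.molecules]
    records = []
    for i, j, d in _pair_distances(len(pathway), pathway.cyclic, versus_first):
        records.append((ids[i], ids[j], d, tanimoto_coefficient(smiles[i], smiles[j])))
    return _profile_from_scores(pathway, "tanimoto", records)
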