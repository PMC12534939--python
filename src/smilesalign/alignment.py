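"""Affine-gap Needleman-Wunsch global alignment of charge blueprints.

Three score lattices are kept: M (the two current atoms aligned), X (the
first molecule's atom against a gap) and Y (a gap against the second
molecule's atom), with the recurrences

    M(i,j) = max{M(i−1,j−1), X(i−1,j−1), Y(i−1,j−1)} + s(aᵢ, bⱼ)
    X(i,j) = max{M(i−1,j) − g_open, X(i−1,j) − g_extend, Y(i−1,j) − g_open}
    Y(i,j) = max{M(i,j−1) − g_open, Y(i,j−1) − g_extend, X(i,j−1) − g_open}
    F(i,j) = max{M(i,j), X(i,j), Y(i,j)}

where s is the charge-difference substitution score.  The X↔Y cross
transitions (a gap run in one molecule starting right after a gap run in the
other, each run paying its own opening cost) are included so the recurrence
is exact over *all* global alignments — the common two-term abbreviation is
only safe when gaps always cost, and the sweep explores gap rewards too.
Penalties are
*subtracted*, so negative penalty values act as gap rewards — the validation
sweep deliberately covers both signs.  Tie-breaking is a fixed M > X > Y
preference everywhere, making the traceback deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .molecule_io import (
    GAP,
    AtomToken,
    ChargeBlueprint,
    compute_blueprint,
    reinsert,
)
from .scoring import PairedScoringSet, ScoringMatrix, bin_index

__all__ = [
    "NEG_INF",
    "GapPenalties",
    "DPState",
    "AlignmentResult",
    "fill",
    "traceback",
    "align",
    "align_blueprints",
    "alignment_score",
    "rescore_alignment",
]

#: Finite stand-in for −∞ so lattice arithmetic stays total.  Any reachable
#: alignment score is bounded by ~(n+m)·(|floor| + |g|) ≪ 1e12, so a state at
#: the sentinel can never win a max against a real path.
NEG_INF = -1.0e12


@dataclass(frozen=True)
class GapPenalties:
    """Affine gap costs, subtracted from the running score."""

    g_open: float = 0.0
    g_extend: float = 0.0


Scorer = ScoringMatrix | PairedScoringSet


def _substitution_table(
    bp_a: ChargeBlueprint, bp_b: ChargeBlueprint, scorer: Scorer
) -> np.ndarray:
    """s(aᵢ, bⱼ) for all atom pairs, vectorized over the charge-bin lookup."""
    qa = np.asarray(bp_a.charges, dtype=float)
    qb = np.asarray(bp_b.charges, dtype=float)
    diffs = np.abs(qa[:, None] - qb[None, :])
    bins = np.minimum((np.floor(diffs / 0.1 + 1e-9)).astype(int), 29)
    if isinstance(scorer, ScoringMatrix):
        return scorer.scores[bins]
    S = np.empty_like(diffs)
    ea = np.array(bp_a.elements)
    eb = np.array(bp_b.elements)
    for xa in np.unique(ea):
        for xb in np.unique(eb):
            mask = (ea[:, None] == xa) & (eb[None, :] == xb)
            S[mask] = scorer.matrix_for(xa, xb).scores[bins[mask]]
    return S


@dataclass
class DPState:
    """Filled M/X/Y/F lattices plus traceback pointers.

    Pointer codes: in ``ptr_m`` the winning predecessor state of a diagonal
    move (0=M, 1=X, 2=Y); in ``ptr_x``/``ptr_y`` whether the gap was opened
    from M (0), extended (1), or opened across from the opposite gap lattice
    (2); ``ptr_f`` records which lattice supplies F(i,j) with the M > X > Y
    preference.
    """

    M: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    F: np.ndarray
    S: np.ndarray
    n: int
    m: int
    penalties: GapPenalties
    ptr_m: np.ndarray
    ptr_x: np.ndarray
    ptr_y: np.ndarray
    ptr_f: np.ndarray


def fill(
    blueprint_a: ChargeBlueprint,
    blueprint_b: ChargeBlueprint,
    scorer: Scorer,
    penalties: GapPenalties,
) -> DPState:
    """Fill the three affine-gap lattices.

    Boundary conditions: M(0,0)=0 and M elsewhere on row/column 0 is −∞;
    X(i,0) = −g_open − (i−1)·g_extend (the all-gap prefix), X(0,j)=−∞;
    Y mirrors X.
    """
    n, m = len(blueprint_a), len(blueprint_b)
    go, ge = penalties.g_open, penalties.g_extend
    S = (
        _substitution_table(blueprint_a, blueprint_b, scorer)
        if n and m
        else np.zeros((n, m))
    )
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)
    Y = np.full((n + 1, m + 1), NEG_INF)
    ptr_m = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_x = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_y = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -go - (i - 1) * ge
        ptr_x[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0, j] = -go - (j - 1) * ge
        ptr_y[0, j] = 0 if j == 1 else 1
    for i in range(1, n + 1):
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, m + 1):
            # diagonal: best predecessor state, preference M > X > Y
            dm, dx, dy = Mi1[j - 1], Xi1[j - 1], Yi1[j - 1]
            if dm >= dx and dm >= dy:
                best, code = dm, 0
            elif dx >= dy:
                best, code = dx, 1
            else:
                best, code = dy, 2
            M[i, j] = best + S[i - 1, j - 1]
            ptr_m[i, j] = code
            # gap in b (consume a_i): preference open-from-M, extend, open-from-Y
            xo, xe, xy = Mi1[j] - go, Xi1[j] - ge, Yi1[j] - go
            if xo >= xe and xo >= xy:
                X[i, j], ptr_x[i, j] = xo, 0
            elif xe >= xy:
                X[i, j], ptr_x[i, j] = xe, 1
            else:
                X[i, j], ptr_x[i, j] = xy, 2
            # gap in a (consume b_j): preference open-from-M, extend, open-from-X
            yo, ye, yx = M[i, j - 1] - go, Y[i, j - 1] - ge, X[i, j - 1] - go
            if yo >= ye and yo >= yx:
                Y[i, j], ptr_y[i, j] = yo, 0
            elif ye >= yx:
                Y[i, j], ptr_y[i, j] = ye, 1
            else:
                Y[i, j], ptr_y[i, j] = yx, 2
    F = np.maximum(np.maximum(M, X), Y)
    # which lattice supplies F, preference M > X > Y
    ptr_f = np.where(M >= F, 0, np.where(X >= F, 1, 2)).astype(np.int8)
    return DPState(M=M, X=X, Y=Y, F=F, S=S, n=n, m=m, penalties=penalties,
                   ptr_m=ptr_m, ptr_x=ptr_x, ptr_y=ptr_y, ptr_f=ptr_f)


def traceback(
    state: DPState,
    blueprint_a: ChargeBlueprint,
    blueprint_b: ChargeBlueprint,
) -> tuple[list[AtomToken | None], list[AtomToken | None]]:
    """Reconstruct the optimal alignment from the recorded pointers."""
    i, j = state.n, state.m
    which = int(state.ptr_f[i, j])
    out_a: list[AtomToken | None] = []
    out_b: list[AtomToken | None] = []
    while i > 0 or j > 0:
        if which == 0:  # M: a_i aligned with b_j
            if i == 0 or j == 0:
                raise RuntimeError("inconsistent DP lattice: M on a boundary")
            out_a.append(blueprint_a.tokens[i - 1])
            out_b.append(blueprint_b.tokens[j - 1])
            which = int(state.ptr_m[i, j])
            i, j = i - 1, j - 1
        elif which == 1:  # X: a_i against a gap
            out_a.append(blueprint_a.tokens[i - 1])
            out_b.append(GAP)
            code = int(state.ptr_x[i, j])
            which = (0, 1, 2)[code]  # from M, extend X, or cross from Y
            i -= 1
        else:  # Y: gap against b_j
            out_a.append(GAP)
            out_b.append(blueprint_b.tokens[j - 1])
            code = int(state.ptr_y[i, j])
            which = (0, 2, 1)[code]  # from M, extend Y, or cross from X
            j -= 1
    out_a.reverse()
    out_b.reverse()
    return out_a, out_b


@dataclass
class AlignmentResult:
    """A finished global alignment of two molecules."""

    aligned_a: list[AtomToken | None]
    aligned_b: list[AtomToken | None]
    score: float
    aligned_smiles_a: str
    aligned_smiles_b: str
    mode: str
    penalties: GapPenalties
    blueprint_a: ChargeBlueprint
    blueprint_b: ChargeBlueprint
    gap_symbol: str = "-"

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("gapped sequences differ in length")
        for ta, tb in zip(self.aligned_a, self.aligned_b):
            if ta is GAP and tb is GAP:
                raise ValueError("gap-vs-gap column")

    def __len__(self) -> int:
        return len(self.aligned_a)

    @property
    def gapped_token_strings(self) -> tuple[str, str]:
        """Element-symbol strings with gap symbols — the stripped view."""
        sa = "".join(self.gap_symbol if t is GAP else t.element for t in self.aligned_a)
        sb = "".join(self.gap_symbol if t is GAP else t.element for t in self.aligned_b)
        return sa, sb


def align_blueprints(
    blueprint_a: ChargeBlueprint,
    blueprint_b: ChargeBlueprint,
    scorer: Scorer,
    penalties: GapPenalties = GapPenalties(),
    gap_symbol: str = "-",
) -> AlignmentResult:
    """Align two pre-computed blueprints (fill → traceback → reinsert)."""
    state = fill(blueprint_a, blueprint_b, scorer, penalties)
    if blueprint_a.n_atoms == 0 and blueprint_b.n_atoms == 0:
        gapped_a: list[AtomToken | None] = []
        gapped_b: list[AtomToken | None] = []
        score = 0.0
    else:
        gapped_a, gapped_b = traceback(state, blueprint_a, blueprint_b)
        score = float(state.F[state.n, state.m])
    mode = "all_vs_all" if isinstance(scorer, ScoringMatrix) else "paired"
    return AlignmentResult(
        aligned_a=gapped_a,
        aligned_b=gapped_b,
        score=score,
        aligned_smiles_a=reinsert(gapped_a, blueprint_a, gap_symbol),
        aligned_smiles_b=reinsert(gapped_b, blueprint_b, gap_symbol),
        mode=mode,
        penalties=penalties,
        blueprint_a=blueprint_a,
        blueprint_b=blueprint_b,
        gap_symbol=gap_symbol,
    )


def align(
    smiles_a: str,
    smiles_b: str,
    scorer: Scorer,
    penalties: GapPenalties = GapPenalties(),
    gap_symbol: str = "-",
    charge_provider: Callable | None = None,
) -> AlignmentResult:
    """Global alignment of two molecules given as SMILES strings."""
    bp_a = compute_blueprint(smiles_a, charge_provider=charge_provider)
    bp_b = compute_blueprint(smiles_b, charge_provider=charge_provider)
    return align_blueprints(bp_a, bp_b, scorer, penalties, gap_symbol)


def alignment_score(
    blueprint_a: ChargeBlueprint,
    blueprint_b: ChargeBlueprint,
    scorer: Scorer,
    penalties: GapPenalties = GapPenalties(),
) -> float:
    """Optimal score only (no traceback) — used by pathway profiling."""
    if blueprint_a.n_atoms == 0 and blueprint_b.n_atoms == 0:
        return 0.0
    state = fill(blueprint_a, blueprint_b, scorer, penalties)
    return float(state.F[state.n, state.m])


def rescore_alignment(
    gapped_a: Sequence[AtomToken | None],
    gapped_b: Sequence[AtomToken | None],
    charges_a: Sequence[float],
    charges_b: Sequence[float],
    scorer: Scorer,
    penalties: GapPenalties,
) -> float:
    """Re-score a gapped alignment column by column with affine accounting.

    Independent of the DP: a gap column costs g_open when it starts a run in
    its sequence and g_extend when it extends one.  Used to verify that an
    emitted alignment actually attains the reported F(n, m).
    """
    from .scoring import score_lookup

    ia = ib = 0
    total = 0.0
    in_gap_a = in_gap_b = False  # run of gaps in sequence a / b
    for ta, tb in zip(gapped_a, gapped_b):
        if ta is GAP and tb is GAP:
            raise ValueError("gap-vs-gap column")
        if ta is GAP:
            total -= penalties.g_extend if in_gap_a else penalties.g_open
            in_gap_a, in_gap_b = True, False
            ib += 1
        elif tb is GAP:
            total -= penalties.g_extend if in_gap_b else penalties.g_open
            in_gap_b, in_gap_a = True, False
            ia += 1
        else:
            total += score_lookup(
                scorer, ta.element, charges_a[ia], tb.element, charges_b[ib]
            )
            in_gap_a = in_gap_b = False
            ia += 1
            ib += 1
    return total
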