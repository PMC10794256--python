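"""Global alignment of biosynthetic domain architectures (BDAs).

BDAs are token sequences over the domain vocabulary.  Pairs are aligned
by exact Needleman-Wunsch under the domain-homology scoring matrix with
zero gap penalties everywhere (linear gaps of cost 0; end gaps are free
by construction, so leading/trailing shifts cost nothing).  From each
alignment we report M (columns with domains on both sides), N (total
columns), BDA similarity M/N, the uncorrected p-distance 1 - M/N, and a
misalignment audit: columns pairing two domains whose matrix entry is
-1, i.e. domains with zero co-emission probability.

Because gap columns cost 0 while a -1 column strictly lowers the score,
no optimal traceback under the default tie-breaking ever contains a -1
column; the -1 floor therefore fully prevents misalignment in the exact
DP (heuristic text aligners do not share this guarantee).

Tie-breaking among equal-score DP moves is: diagonal when the pair score
is positive, else gap in the first sequence, else gap in the second.
This maximises matched columns without admitting -1 pairs and makes the
reported traceback deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bgc_io import BDA
from .hmm_scoring import ScoringMatrix

__all__ = [
    "BDAAlignment",
    "UnknownTokenError",
    "align_pair",
    "alignment_from_pairs",
    "all_pairs",
    "count_misaligned",
    "align_cluster",
]


class UnknownTokenError(KeyError):
    """A BDA token is absent from the scoring matrix labels."""


@dataclass(frozen=True)
class BDAAlignment:
    """A pairwise BDA alignment and its summary statistics."""

    tokens_a: tuple[str, ...]
    tokens_b: tuple[str, ...]
    pairs: tuple[tuple[Optional[int], Optional[int]], ...]
    score: float
    M: int  # matched (gap-free) columns
    N: int  # total columns
    misaligned: int  # matched columns whose pair scores -1

    @property
    def similarity(self) -> float:
        """BDA similarity M/N (0 when the alignment is empty)."""
        return self.M / self.N if self.N else 0.0

    @property
    def p_distance(self) -> float:
        """Uncorrected p-distance 1 - M/N."""
        return 1.0 - self.similarity

    def rows(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        """The two gapped token rows ('-' for gaps)."""
        row_a = tuple(self.tokens_a[i] if i is not None else "-" for i, _ in self.pairs)
        row_b = tuple(self.tokens_b[j] if j is not None else "-" for _, j in self.pairs)
        return row_a, row_b


def _pair_score(a: str, b: str, matrix: ScoringMatrix, unknown: str) -> float:
    try:
        return matrix.score(a, b)
    except KeyError:
        if unknown == "strict":
            missing = a if a not in matrix else b
            raise UnknownTokenError(
                f"token {missing!r} is not in the scoring matrix"
            ) from None
        return -1.0  # unknown-as-mismatch: -1 against everything


def align_pair(
    a: BDA, b: BDA, matrix: ScoringMatrix, unknown: str = "strict"
) -> BDAAlignment:
    """Exact global alignment of two BDAs with zero gap penalties.

    The score is the DP optimum; the reported traceback follows the
    deterministic tie-breaking rule described in the module docstring.
    Unknown tokens raise :class:`UnknownTokenError` unless
    ``unknown="mismatch"``, which scores them -1 against every label.
    """
    ta, tb = a.tokens, b.tokens
    la, lb = len(ta), len(tb)
    s = np.empty((la, lb))
    for i in range(la):
        for j in range(lb):
            s[i, j] = _pair_score(ta[i], tb[j], matrix, unknown)
    f = np.zeros((la + 1, lb + 1))  # gap cost 0: borders stay 0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            f[i, j] = max(f[i - 1, j - 1] + s[i - 1, j - 1], f[i - 1, j], f[i, j - 1])
    pairs: list[tuple[Optional[int], Optional[int]]] = []
    i, j = la, lb
    while i > 0 or j > 0:
        if (
            i > 0
            and j > 0
            and s[i - 1, j - 1] > 0
            and f[i, j] == f[i - 1, j - 1] + s[i - 1, j - 1]
        ):
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif i > 0 and f[i, j] == f[i - 1, j]:
            pairs.append((i - 1, None))
            i -= 1
        elif j > 0 and f[i, j] == f[i, j - 1]:
            pairs.append((None, j - 1))
            j -= 1
        else:  # forced negative diagonal (cannot occur with 0-cost gaps)
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
    pairs.reverse()
    return _summarise(ta, tb, tuple(pairs), float(f[la, lb]), matrix, unknown)


def alignment_from_pairs(
    a: BDA,
    b: BDA,
    pairs: Sequence[tuple[Optional[int], Optional[int]]],
    matrix: ScoringMatrix,
    unknown: str = "strict",
) -> BDAAlignment:
    """Build a (possibly suboptimal, forced) alignment from explicit pairs."""
    score = sum(
        _pair_score(a.tokens[i], b.tokens[j], matrix, unknown)
        for i, j in pairs
        if i is not None and j is not None
    )
    return _summarise(a.tokens, b.tokens, tuple(pairs), float(score), matrix, unknown)


def _summarise(ta, tb, pairs, score, matrix, unknown) -> BDAAlignment:
    m = sum(1 for i, j in pairs if i is not None and j is not None)
    mis = sum(
        1
        for i, j in pairs
        if i is not None
        and j is not None
        and _pair_score(ta[i], tb[j], matrix, unknown) == -1.0
    )
    return BDAAlignment(
        tokens_a=tuple(ta),
        tokens_b=tuple(tb),
        pairs=pairs,
        score=score,
        M=m,
        N=len(pairs),
        misaligned=mis,
    )


def count_misaligned(alignment: BDAAlignment, matrix: ScoringMatrix) -> tuple[int, float]:
    """Misaligned-column count and rate (count / M; 0 when M = 0).

    A column is misaligned when both sides carry a domain and the matrix
    entry for the pair is -1 (zero co-emission probability).
    """
    count = sum(
        1
        for i, j in alignment.pairs
        if i is not None
        and j is not None
        and matrix.score(alignment.tokens_a[i], alignment.tokens_b[j]) == -1.0
    )
    rate = count / alignment.M if alignment.M else 0.0
    return count, rate


def all_pairs(
    bdas: Sequence[BDA],
    matrix: ScoringMatrix,
    refs: Sequence[BDA] = (),
    unknown: str = "strict",
) -> pd.DataFrame:
    """Pairwise similarity table: candidate x candidate and candidate x reference.

    Input must already be class-homogeneous (BDA alignment is restricted
    to modular classes; the caller partitions by class).  One row per
    unordered candidate pair plus one row per candidate-reference pair;
    deterministic order.
    """
    rows = []
    for i in range(len(bdas)):
        for j in range(i + 1, len(bdas)):
            aln = align_pair(bdas[i], bdas[j], matrix, unknown)
            rows.append((bdas[i].bgc_id, bdas[j].bgc_id, aln.similarity, aln.M, aln.N, aln.misaligned))
    for cand in bdas:
        for ref in refs:
            aln = align_pair(cand, ref, matrix, unknown)
            rows.append((cand.bgc_id, ref.bgc_id, aln.similarity, aln.M, aln.N, aln.misaligned))
    return pd.DataFrame(
        rows, columns=["id_a", "id_b", "similarity", "M", "N", "misaligned"]
    )


# ---------------------------------------------------------------------------
# Progressive cluster re-alignment (for visualization)
# ---------------------------------------------------------------------------


def _profile_column_score(col_a, col_b, matrix, unknown) -> float:
    """Mean pair score over non-gap token pairs of two profile columns."""
    scores = [
        _pair_score(x, y, matrix, unknown)
        for x in col_a
        for y in col_b
        if x != "-" and y != "-"
    ]
    return sum(scores) / len(scores) if scores else 0.0


def _align_profiles(pa, pb, matrix, unknown):
    """NW on column profiles, gap cost 0, same tie-break as align_pair."""
    la, lb = len(pa[0]), len(pb[0])
    s = np.empty((la, lb))
    for i in range(la):
        for j in range(lb):
            s[i, j] = _profile_column_score(
                [row[i] for row in pa], [row[j] for row in pb], matrix, unknown
            )
    f = np.zeros((la + 1, lb + 1))
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            f[i, j] = max(f[i - 1, j - 1] + s[i - 1, j - 1], f[i - 1, j], f[i, j - 1])
    moves = []
    i, j = la, lb
    while i > 0 or j > 0:
        if (
            i > 0
            and j > 0
            and s[i - 1, j - 1] > 0
            and f[i, j] == f[i - 1, j - 1] + s[i - 1, j - 1]
        ):
            moves.append("d")
            i, j = i - 1, j - 1
        elif i > 0 and f[i, j] == f[i - 1, j]:
            moves.append("a")
            i -= 1
        elif j > 0 and f[i, j] == f[i, j - 1]:
            moves.append("b")
            j -= 1
        else:
            moves.append("d")
            i, j = i - 1, j - 1
    moves.reverse()
    out_a = [[] for _ in pa]
    out_b = [[] for _ in pb]
    ia = ib = 0
    for mv in moves:
        if mv in ("d", "a"):
            for r, row in enumerate(pa):
                out_a[r].append(row[ia])
            ia += 1
        else:
            for r in range(len(pa)):
                out_a[r].append("-")
        if mv in ("d", "b"):
            for r, row in enumerate(pb):
                out_b[r].append(row[ib])
            ib += 1
        else:
            for r in range(len(pb)):
                out_b[r].append("-")
    return out_a + out_b


def align_cluster(
    bdas: Sequence[BDA], matrix: ScoringMatrix, unknown: str = "strict"
) -> dict[str, tuple[str, ...]]:
    """Progressive multiple alignment of a BDA cluster.

    The join order is guided by pairwise BDA similarity in descending
    order (most similar pair first, then greedily attach the BDA with
    the highest similarity to any already-aligned member).  All rows
    have equal length and stripping gaps recovers each input BDA.
    Returns bgc_id -> gapped token row.
    """
    if len(bdas) < 2:
        raise ValueError("align_cluster needs >= 2 BDAs")
    n = len(bdas)
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = align_pair(bdas[i], bdas[j], matrix, unknown).similarity
    # seed with the most similar pair (ties: lowest indices)
    best = max(
        ((i, j) for i in range(n) for j in range(i + 1, n)),
        key=lambda ij: (sim[ij], -ij[0], -ij[1]),
    )
    included = [best[0], best[1]]
    profile = _align_profiles(
        [list(bdas[best[0]].tokens)], [list(bdas[best[1]].tokens)], matrix, unknown
    )
    while len(included) < n:
        rest = [k for k in range(n) if k not in included]
        nxt = max(rest, key=lambda k: (max(sim[k, m] for m in included), -k))
        profile = _align_profiles(profile, [list(bdas[nxt].tokens)], matrix, unknown)
        included.append(nxt)
    return {bdas[k].bgc_id: tuple(profile[r]) for r, k in enumerate(included)}
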