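"""Domain-homology scoring from profile-HMM co-emission comparison.

The BDA alignment scoring matrix assigns each pair of biosynthetic
domain labels a homology score derived from their profile HMMs.  Two
profiles are compared by a co-emission score: per pair of match columns,
``log( sum_a e1(a) * e2(a) / bg(a) )`` — the log-odds that both columns
emit the same residue relative to background — maximised over monotone
column alignments by dynamic programming and floored at zero.  Raw
scores are normalized by the geometric mean of the self-scores, so a
profile against itself scores exactly 1 and unrelated profiles score 0.
Zero-co-emission pairs are written into the matrix as -1, which
penalises aligning non-homologous domains at the same position.

Insert/delete states of HMMER3 profiles are parsed but not scored; only
match-state emissions enter the comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, TextIO, Union

import numpy as np

__all__ = [
    "ProfileHMM",
    "ScoringMatrix",
    "DegenerateProfileError",
    "AMINO_ALPHABET",
    "column_score",
    "raw_coemission",
    "normalized_coemission",
    "build_scoring_matrix",
    "read_hmmer3",
    "write_matrix",
    "read_matrix",
]

AMINO_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_K = len(AMINO_ALPHABET)


class DegenerateProfileError(ValueError):
    """A profile whose self co-emission score is zero cannot be normalized."""


@dataclass
class ProfileHMM:
    """Match-state emission profile of one biosynthetic domain family.

    columns: (L, 20) row-stochastic array of match emissions.
    background: length-20 emission distribution (uniform by default).
    """

    label: str
    columns: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(_K, 1.0 / _K))

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.columns.ndim != 2 or self.columns.shape[1] != _K:
            raise ValueError(f"{self.label}: columns must be (L, {_K})")
        if self.columns.shape[0] < 1:
            raise ValueError(f"{self.label}: profile needs >= 1 column")
        if not np.allclose(self.columns.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"{self.label}: emission columns must sum to 1")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-9):
            raise ValueError(f"{self.label}: background must sum to 1")

    def __len__(self) -> int:
        return self.columns.shape[0]


def column_score(
    e1: np.ndarray, e2: np.ndarray, background: np.ndarray
) -> float:
    """Log-odds co-emission score of two match columns.

    ``log( sum_a e1(a) e2(a) / bg(a) )``; -inf when the weighted dot
    product is zero (the columns cannot co-emit any residue).
    """
    dot = float(np.sum(np.asarray(e1) * np.asarray(e2) / np.asarray(background)))
    return math.log(dot) if dot > 0.0 else -math.inf


def raw_coemission(h1: ProfileHMM, h2: ProfileHMM, gap_cost: float = 0.0) -> float:
    """Best monotone column-alignment co-emission score, floored at 0.

    Global dynamic programme over column pairs; unaligned columns cost
    ``gap_cost`` each (default 0, i.e. free).  Deterministic.
    """
    if gap_cost < 0:
        raise ValueError("gap_cost must be >= 0")
    # symmetric comparison: average the two backgrounds
    bg = (h1.background + h2.background) / 2.0
    bg = bg / bg.sum()
    s = np.full((len(h1), len(h2)), -np.inf)
    for i in range(len(h1)):
        for j in range(len(h2)):
            s[i, j] = column_score(h1.columns[i], h2.columns[j], bg)
    f = np.zeros((len(h1) + 1, len(h2) + 1))
    f[1:, 0] = -gap_cost * np.arange(1, len(h1) + 1)
    f[0, 1:] = -gap_cost * np.arange(1, len(h2) + 1)
    for i in range(1, len(h1) + 1):
        for j in range(1, len(h2) + 1):
            f[i, j] = max(
                f[i - 1, j - 1] + s[i - 1, j - 1],
                f[i - 1, j] - gap_cost,
                f[i, j - 1] - gap_cost,
            )
    return max(float(f[len(h1), len(h2)]), 0.0)


def normalized_coemission(
    h1: ProfileHMM, h2: ProfileHMM, gap_cost: float = 0.0, norm: str = "geometric"
) -> float:
    """Self-normalized co-emission similarity in [0, 1].

    ``raw(h1,h2) / sqrt(raw(h1,h1) * raw(h2,h2))`` (or divided by the
    max of the self-scores with ``norm="max"``), clipped to [0, 1];
    identical profiles score exactly 1.
    """
    s11 = raw_coemission(h1, h1, gap_cost)
    s22 = raw_coemission(h2, h2, gap_cost)
    for label, s in ((h1.label, s11), (h2.label, s22)):
        if s <= 1e-9:  # tolerance: float residue can leave a ~1e-16 self-score
            raise DegenerateProfileError(
                f"profile {label!r} has self co-emission score 0"
            )
    if np.array_equal(h1.columns, h2.columns):
        return 1.0
    s12 = raw_coemission(h1, h2, gap_cost)
    if norm == "geometric":
        denom = math.sqrt(s11 * s22)
    elif norm == "max":
        denom = max(s11, s22)
    else:
        raise ValueError(f"unknown norm {norm!r}")
    return min(max(s12 / denom, 0.0), 1.0)


@dataclass
class ScoringMatrix:
    """Symmetric domain-label homology matrix.

    Entries are normalized co-emission similarities in (0, 1]; pairs with
    zero co-emission probability carry -1.  The diagonal is exactly 1.
    """

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in scoring matrix")
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("scoring matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-12):
            raise ValueError("scoring matrix diagonal must be 1")
        off = self.values[~np.eye(n, dtype=bool)]
        if off.size and not np.all((off == -1.0) | ((off > 0.0) & (off <= 1.0))):
            raise ValueError("off-diagonal entries must be in {-1} | (0, 1]")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def score(self, a: str, b: str) -> float:
        """Homology score of a label pair; KeyError on unknown labels."""
        return float(self.values[self._index[a], self._index[b]])

    @classmethod
    def from_groups(cls, groups: Sequence[Sequence[str]]) -> "ScoringMatrix":
        """Block matrix: 1 within each homology group, -1 across groups."""
        labels = [lab for g in groups for lab in g]
        n = len(labels)
        values = np.full((n, n), -1.0)
        pos = 0
        for g in groups:
            k = len(g)
            values[pos : pos + k, pos : pos + k] = 1.0
            pos += k
        return cls(tuple(labels), values)


def build_scoring_matrix(
    hmms: Sequence[ProfileHMM],
    gap_cost: float = 0.0,
    norm: str = "geometric",
    epsilon: float = 0.0,
) -> ScoringMatrix:
    """Build the alignment scoring matrix from a set of domain profiles.

    Entry (i, j) is the normalized co-emission similarity when it
    exceeds ``epsilon`` (default 0) and -1 otherwise; the diagonal is 1
    and the matrix is symmetric by construction.  Duplicate labels are
    an error.
    """
    labels = [h.label for h in hmms]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate profile labels")
    n = len(hmms)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            v = normalized_coemission(hmms[i], hmms[j], gap_cost, norm)
            values[i, j] = values[j, i] = v if v > epsilon else -1.0
    return ScoringMatrix(tuple(labels), values)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_hmmer3(path: Union[str, Path]) -> list[ProfileHMM]:
    """Read HMMER3 text profile(s) into :class:`ProfileHMM` objects.

    Match-state emissions are recovered as probabilities ('*' entries,
    negative-infinite scores, become probability 0); the COMPO line, when
    present, supplies the background distribution, otherwise the
    background is uniform.
    """
    from pyhmmer.plan7 import HMMFile

    profiles = []
    with HMMFile(str(path)) as hmm_file:
        for hmm in hmm_file:
            emissions = np.asarray(hmm.match_emissions, dtype=float)[1:, :]
            # renormalise away residual float error from the text encoding
            emissions = emissions / emissions.sum(axis=1, keepdims=True)
            if hmm.composition is not None:
                bg = np.asarray(hmm.composition, dtype=float)
                # floor zero-probability letters so background odds stay finite
                bg = np.maximum(bg, 1e-6)
                bg = bg / bg.sum()
            else:
                bg = np.full(_K, 1.0 / _K)
            name = hmm.name.decode() if isinstance(hmm.name, bytes) else str(hmm.name)
            profiles.append(ProfileHMM(name, emissions, bg))
    return profiles


def write_matrix(matrix: ScoringMatrix, handle: TextIO) -> None:
    """Write a scoring matrix as TSV with label header row and column."""
    handle.write("label\t" + "\t".join(matrix.labels) + "\n")
    for i, lab in enumerate(matrix.labels):
        row = "\t".join(format(v, ".12g") for v in matrix.values[i])
        handle.write(f"{lab}\t{row}\n")


def read_matrix(handle: TextIO) -> ScoringMatrix:
    """Read a scoring matrix TSV written by :func:`write_matrix`."""
    lines = [ln.rstrip("\n") for ln in handle if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    if header[0] != "label":
        raise ValueError("matrix TSV must start with a 'label' header")
    labels = tuple(header[1:])
    values = np.array(
        [[float(v) for v in ln.split("\t")[1:]] for ln in lines[1:]], dtype=float
    )
    return ScoringMatrix(labels, values)
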