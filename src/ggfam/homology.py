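"""Homology screening by global pairwise alignment score in Dayhoff units.

A candidate protein qualifies as a family homolog when its optimal global
alignment score against *every* query protein exceeds a threshold (default
130) expressed in Dayhoff units, i.e. tens of log10 odds under a PAM-family
substitution model.  The alignment model is global with affine gaps
(Gotoh three-state recursion); a gap run of length L costs
``gap_open + (L - 1) * gap_extend``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from ggfam.motifs import AMINO_ACIDS, ProteinSequence

DEFAULT_GAP_OPEN = -10.0
DEFAULT_GAP_EXTEND = -1.0
DEFAULT_THRESHOLD = 130.0


@dataclass
class ScoringMatrix:
    """Residue substitution scores plus affine gap penalties.

    ``scores`` is square over ``alphabet`` and symmetric.  The diagonal is
    *not* required to dominate each row (PAM-class matrices violate this for
    some residues).  'X' scores 0 against everything, including itself.
    """

    alphabet: list[str]
    scores: np.ndarray
    gap_open: float = DEFAULT_GAP_OPEN
    gap_extend: float = DEFAULT_GAP_EXTEND

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        n = len(self.alphabet)
        if self.scores.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.scores.shape} does not match alphabet size {n}"
            )
        if not np.allclose(self.scores, self.scores.T):
            i, j = np.argwhere(~np.isclose(self.scores, self.scores.T))[0]
            raise ValueError(
                "asymmetric matrix: "
                f"M[{self.alphabet[i]},{self.alphabet[j]}]={self.scores[i, j]} "
                f"!= M[{self.alphabet[j]},{self.alphabet[i]}]={self.scores[j, i]}"
            )
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ValueError("require gap_open <= gap_extend <= 0")
        self._index = {a: i for i, a in enumerate(self.alphabet)}

    def score(self, a: str, b: str) -> float:
        try:
            return float(self.scores[self._index[a], self._index[b]])
        except KeyError as e:
            raise KeyError(f"residue {e.args[0]!r} absent from matrix alphabet") from None

    def to_biopython(self) -> substitution_matrices.Array:
        arr = substitution_matrices.Array(alphabet="".join(self.alphabet), dims=2)
        for i, a in enumerate(self.alphabet):
            for j, b in enumerate(self.alphabet):
                arr[a, b] = self.scores[i, j]
        return arr


@dataclass
class AlignmentResult:
    score: float
    aligned_a: str
    aligned_b: str
    identity: float


@dataclass
class HomologSelection:
    candidate_id: str
    per_query_scores: dict[str, float] = field(default_factory=dict)
    threshold: float = DEFAULT_THRESHOLD

    @property
    def min_score(self) -> float:
        return min(self.per_query_scores.values())

    def passed(self, inclusive: bool = False) -> bool:
        if inclusive:
            return self.min_score >= self.threshold
        return self.min_score > self.threshold


def load_matrix(
    source: str | Path = "pam250",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> ScoringMatrix:
    """Load the built-in PAM250 matrix (Dayhoff units) or a matrix file.

    A file must be whitespace-delimited and square with matching header row
    and column.  The built-in matrix is the classic PAM250 log-odds table
    restricted to the 20 standard residues, extended with an 'X' row/column
    of zeros (neutral unknown).
    """
    if isinstance(source, str) and source.lower() in {"pam250", "dayhoff"}:
        pam = substitution_matrices.load("PAM250")
        letters = sorted(AMINO_ACIDS)
        n = len(letters)
        scores = np.zeros((n + 1, n + 1))
        for i, a in enumerate(letters):
            for j, b in enumerate(letters):
                scores[i, j] = pam[a, b]
        return ScoringMatrix(
            alphabet=letters + ["X"],
            scores=scores,
            gap_open=gap_open,
            gap_extend=gap_extend,
        )
    path = Path(source)
    df = pd.read_csv(path, sep=r"\s+", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(
            f"{path}: matrix not square / header mismatch "
            f"(rows {list(df.index)[:5]}..., cols {list(df.columns)[:5]}...)"
        )
    vals = df.to_numpy(dtype=float)
    if not np.allclose(vals, vals.T):
        i, j = np.argwhere(~np.isclose(vals, vals.T))[0]
        raise ValueError(
            f"{path}: asymmetric at [{df.index[i]},{df.columns[j]}]: "
            f"{vals[i, j]} != {vals[j, i]}"
        )
    return ScoringMatrix(
        alphabet=[str(c) for c in df.columns],
        scores=vals,
        gap_open=gap_open,
        gap_extend=gap_extend,
    )


def write_matrix(matrix: ScoringMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.scores, index=matrix.alphabet, columns=matrix.alphabet)
    df.to_csv(path, sep="\t")


def _aligner(matrix: ScoringMatrix) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix.to_biopython()
    aligner.open_gap_score = matrix.gap_open
    aligner.extend_gap_score = matrix.gap_extend
    return aligner


def _check_sequences(matrix: ScoringMatrix, *seqs: ProteinSequence) -> None:
    known = set(matrix.alphabet)
    for s in seqs:
        if not s.residues:
            raise ValueError(f"sequence {s.id!r} is empty")
        missing = set(s.residues) - known
        if missing:
            raise ValueError(
                f"sequence {s.id!r}: residue(s) {sorted(missing)} absent from matrix"
            )


def rescore_alignment(aligned_a: str, aligned_b: str, matrix: ScoringMatrix) -> float:
    """Recompute the score of a gapped alignment column by column.

    Used to validate alignments: substitution columns score by the matrix,
    each gap run costs ``gap_open + (len - 1) * gap_extend``.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned strings differ in length")
    total = 0.0
    in_gap_a = in_gap_b = False
    for ca, cb in zip(aligned_a, aligned_b):
        if ca == "-" and cb == "-":
            raise ValueError("column with two gaps")
        if ca == "-":
            total += matrix.gap_extend if in_gap_a else matrix.gap_open
            in_gap_a, in_gap_b = True, False
        elif cb == "-":
            total += matrix.gap_extend if in_gap_b else matrix.gap_open
            in_gap_b, in_gap_a = True, False
        else:
            total += matrix.score(ca, cb)
            in_gap_a = in_gap_b = False
    return total


def align_score(
    a: ProteinSequence, b: ProteinSequence, matrix: ScoringMatrix | None = None
) -> AlignmentResult:
    """Optimal global alignment of two proteins under the affine gap model.

    Returns the optimal score together with one optimal alignment (the
    aligner's first traceback, which is deterministic for fixed inputs) and
    the fraction of alignment columns with identical residues.
    """
    matrix = matrix or load_matrix()
    _check_sequences(matrix, a, b)
    aligner = _aligner(matrix)
    alignment = next(iter(aligner.align(a.residues, b.residues)))
    aligned_a, aligned_b = str(alignment[0]), str(alignment[1])
    ident = sum(
        x == y and x != "-" for x, y in zip(aligned_a, aligned_b)
    ) / len(aligned_a)
    return AlignmentResult(
        score=float(alignment.score),
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        identity=ident,
    )


def pairwise_score(
    a: ProteinSequence, b: ProteinSequence, matrix: ScoringMatrix
) -> float:
    """Score-only fast path (no traceback)."""
    _check_sequences(matrix, a, b)
    return float(_aligner(matrix).score(a.residues, b.residues))


def screen_homologs(
    queries: list[ProteinSequence],
    candidates: list[ProteinSequence],
    matrix: ScoringMatrix | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    inclusive: bool = False,
) -> list[HomologSelection]:
    """Apply the all-queries threshold rule to each candidate.

    A candidate passes when its alignment score to *every* query strictly
    exceeds ``threshold`` (``inclusive=True`` relaxes to >=).  All query
    scores are evaluated and reported.
    """
    if not queries:
        raise ValueError("empty query list: the all-queries rule is undefined")
    matrix = matrix or load_matrix()
    out = []
    for cand in candidates:
        scores = {q.id: pairwise_score(q, cand, matrix) for q in queries}
        out.append(
            HomologSelection(
                candidate_id=cand.id, per_query_scores=scores, threshold=threshold
            )
        )
    return out


def selection_table(
    selections: list[HomologSelection], inclusive: bool = False
) -> pd.DataFrame:
    """TSV-ready table: candidate_id, min_score, passed, per-query columns."""
    rows = []
    for s in selections:
        row = {
            "candidate_id": s.candidate_id,
            "min_score": s.min_score,
            "passed": s.passed(inclusive),
        }
        row.update({f"score_{q}": v for q, v in s.per_query_scores.items()})
        rows.append(row)
    return pd.DataFrame(rows)
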