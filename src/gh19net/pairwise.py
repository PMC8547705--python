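"""Global pairwise alignment and percent identity.

Percent identity from Needleman-Wunsch global alignment is the single
metric under every network and cluster in this package. Alignments use
BLOSUM62 with affine gap costs of 10 (opening) and 0.5 (extension): a gap
run of length L costs 10 + (L-1) * 0.5, and terminal gaps are free. This is
the default dialect of the classic global aligner in the EMBOSS suite; the
identity denominator is the full alignment length including gap columns
(that program's "Identity" field). Both conventions are recorded here
because published methods rarely state them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from .records import ALLOWED_RESIDUES, SequenceRecord


@dataclass
class AlignmentResult:
    """A global alignment of two sequences with identity bookkeeping."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")

    @property
    def alignment_length(self) -> int:
        return len(self.aligned_a)

    @property
    def n_identical(self) -> int:
        return sum(1 for x, y in zip(self.aligned_a, self.aligned_b)
                   if x == y and x != "-")


def _blosum62_with_neutral_x():
    """BLOSUM62 with X scoring 0 against everything (neutral ambiguity)."""
    mat = substitution_matrices.load("BLOSUM62")
    x = mat.alphabet.index("X")
    for i in range(len(mat.alphabet)):
        mat[x, i] = 0.0
        mat[i, x] = 0.0
    return mat


def make_aligner(matrix: str = "BLOSUM62", gap_open: float = 10.0,
                 gap_extend: float = 0.5) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    if matrix == "BLOSUM62":
        aligner.substitution_matrix = _blosum62_with_neutral_x()
    else:
        aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aligner.open_end_gap_score = 0.0
    aligner.extend_end_gap_score = 0.0
    return aligner


_DEFAULT_ALIGNER = None


def _default_aligner() -> PairwiseAligner:
    global _DEFAULT_ALIGNER
    if _DEFAULT_ALIGNER is None:
        _DEFAULT_ALIGNER = make_aligner()
    return _DEFAULT_ALIGNER


def _check_residues(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"sequence {name} is empty")
    bad = sorted(set(seq) - ALLOWED_RESIDUES)
    if bad:
        raise ValueError(f"sequence {name} has residues not covered by the "
                         f"scoring matrix: {', '.join(bad)}")


def nw_align(a: str, b: str, aligner: PairwiseAligner | None = None) -> AlignmentResult:
    """Globally align two residue strings; deterministic optimal alignment.

    Ties between co-optimal paths are broken by the aligner's canonical
    first-reported traceback, which is deterministic for given inputs.
    """
    _check_residues(a, "a")
    _check_residues(b, "b")
    if aligner is None:
        aligner = _default_aligner()
    aln = aligner.align(a, b)[0]
    return AlignmentResult(aligned_a=str(aln[0]), aligned_b=str(aln[1]),
                           score=float(aln.score))


def percent_identity(alignment: AlignmentResult, denominator: str = "alignment") -> float:
    """Identity percentage of an alignment.

    ``denominator='alignment'`` (default) divides by the full alignment
    length including gap columns; ``'shorter'`` divides by the shorter
    ungapped sequence length instead.
    """
    if denominator == "alignment":
        denom = alignment.alignment_length
    elif denominator == "shorter":
        denom = min(len(alignment.aligned_a.replace("-", "")),
                    len(alignment.aligned_b.replace("-", "")))
    else:
        raise ValueError(f"unknown identity denominator {denominator!r}")
    return 100.0 * alignment.n_identical / denom


@dataclass
class IdentityMatrix:
    """All-vs-all global identity percentages over an ordered id list."""

    ids: list[str]
    values: np.ndarray  # symmetric, percent in [0, 100]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("identity matrix shape does not match id list")
        self._index = {sid: i for i, sid in enumerate(self.ids)}

    def identity(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def to_long_tsv(self, path) -> None:
        rows = []
        for i, a in enumerate(self.ids):
            for j in range(i + 1, len(self.ids)):
                rows.append((a, self.ids[j], self.values[i, j]))
        pd.DataFrame(rows, columns=["id_a", "id_b", "identity_pct"]).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def from_long_tsv(cls, path) -> "IdentityMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"id_a": str, "id_b": str})
        ids = sorted(set(df["id_a"]) | set(df["id_b"]))
        idx = {sid: i for i, sid in enumerate(ids)}
        values = np.full((len(ids), len(ids)), np.nan)
        np.fill_diagonal(values, 100.0)
        for _, row in df.iterrows():
            i, j = idx[row["id_a"]], idx[row["id_b"]]
            values[i, j] = values[j, i] = row["identity_pct"]
        return cls(ids=ids, values=values)


class PairwiseScorer:
    """Percent-identity computation with a cache shared across stages.

    Clustering at several thresholds and the all-vs-all matrix revisit the
    same sequence pairs; caching by residue-string pair makes the whole
    pipeline cost one alignment per distinct pair.
    """

    def __init__(self, aligner: PairwiseAligner | None = None):
        self.aligner = aligner if aligner is not None else make_aligner()
        self._cache: dict[tuple[str, str], float] = {}

    def identity(self, a: str, b: str) -> float:
        if a == b:
            return 100.0
        key = (a, b) if a <= b else (b, a)
        hit = self._cache.get(key)
        if hit is None:
            hit = percent_identity(nw_align(key[0], key[1], self.aligner))
            self._cache[key] = hit
        return hit


def all_vs_all(records: list[SequenceRecord],
               scorer: PairwiseScorer | None = None) -> IdentityMatrix:
    """Full symmetric identity matrix over the given records."""
    if not records:
        raise ValueError("all_vs_all requires at least one record")
    if scorer is None:
        scorer = PairwiseScorer()
    n = len(records)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = scorer.identity(
                records[i].residues, records[j].residues)
    return IdentityMatrix(ids=[r.id for r in records], values=values)
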