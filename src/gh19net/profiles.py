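"""Subfamily profiles, standard numbering transfer and domain scanning.

A standard numbering scheme assigns one position number to all structurally
equivalent residues of a subfamily. It is realized here by a column profile
built from a seed multiple sequence alignment that contains the reference
structure's sequence: columns where the reference has a residue become
numbered match columns carrying the reference position; reference-gap
columns are insert context. Member sequences are aligned to the profile by
position-specific-score global alignment (log-odds match scores with a
Laplace pseudocount, affine gaps, free end gaps) and matched residues
inherit the column numbers. The numbering semantics depend only on this
column-to-reference mapping, not on full probabilistic profile machinery;
alignments produced by an external profile suite can be supplied instead
through the hit-table reader for drop-in parity.

Domain scanning reports the best-scoring alignment window with an empirical
significance: an extreme-value (Gumbel) fit to the scores of shuffled
queries. These empirical E-values are never numerically comparable to an
external suite's E-values; the filter thresholds apply to whichever source
is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

from .records import CANONICAL_AA, SequenceRecord

log = logging.getLogger("gh19net")

_AA_INDEX = {a: i for i, a in enumerate(CANONICAL_AA)}
_X_CODE = 20

#: background amino-acid frequencies (Robinson & Robinson order of CANONICAL_AA)
_BACKGROUND = np.array([
    0.0781, 0.0192, 0.0536, 0.0629, 0.0397, 0.0738, 0.0220, 0.0514,
    0.0574, 0.0901, 0.0224, 0.0448, 0.0520, 0.0426, 0.0512, 0.0712,
    0.0584, 0.0661, 0.0132, 0.0321,
])
_BACKGROUND /= _BACKGROUND.sum()


def encode(seq: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(c, _X_CODE) for c in seq], dtype=np.int64)


@dataclass
class ProfileColumn:
    frequencies: np.ndarray  # pseudocounted, over the 20 canonical residues
    gap_fraction: float
    standard_position: int | None  # None for insert-context columns


@dataclass
class ProfileModel:
    """Per-column profile anchored to a reference sequence's numbering."""

    profile_id: str
    columns: list[ProfileColumn]
    reference_id: str
    reference_start: int
    reference_seq: str  # ungapped reference residues

    def __post_init__(self) -> None:
        numbered = [c.standard_position for c in self.columns if c.standard_position is not None]
        if any(b <= a for a, b in zip(numbered, numbered[1:])):
            raise ValueError("standard positions must be strictly increasing")

    @property
    def match_columns(self) -> list[ProfileColumn]:
        return [c for c in self.columns if c.standard_position is not None]

    @property
    def standard_positions(self) -> list[int]:
        return [c.standard_position for c in self.match_columns]

    def score_matrix(self) -> np.ndarray:
        """log2-odds match scores, shape (n_match_columns, 21); X scores 0."""
        cols = self.match_columns
        s = np.zeros((len(cols), 21))
        for j, col in enumerate(cols):
            s[j, :20] = np.log2(col.frequencies / _BACKGROUND)
        return s

    def deletion_costs(self, gap_open: float, gap_extend: float
                       ) -> tuple[np.ndarray, np.ndarray]:
        """Occupancy-scaled per-column deletion penalties.

        Columns gapped in most seed sequences (optional loops) are cheap to
        skip; fully occupied columns cost the full affine penalty.
        """
        occ = np.array([max(1.0 - c.gap_fraction, 0.05) for c in self.match_columns])
        return gap_open * occ, gap_extend * occ


def build_profile(msa: list[tuple[str, str]], reference_id: str,
                  profile_id: str = "profile", reference_start: int = 1,
                  pseudocount: float = 0.5) -> ProfileModel:
    """Build a profile from a seed MSA anchored to the reference row.

    ``reference_start`` is the reference-sequence position of its first
    aligned residue (e.g. 24 when an N-terminal signal peptide is excluded
    from the numbered span).
    """
    rows = dict(msa)
    if reference_id not in rows:
        raise ValueError(f"reference {reference_id!r} absent from the MSA")
    ref_row = rows[reference_id]
    lengths = {len(r) for r in rows.values()}
    if len(lengths) != 1:
        raise ValueError("MSA rows have inconsistent lengths")

    columns: list[ProfileColumn] = []
    pos = reference_start - 1
    n_rows = len(rows)
    for j in range(len(ref_row)):
        col = [r[j] for r in rows.values()]
        counts = np.zeros(20)
        gaps = 0
        for c in col:
            if c == "-":
                gaps += 1
            elif c in _AA_INDEX:
                counts[_AA_INDEX[c]] += 1
        freqs = (counts + pseudocount) / (counts.sum() + 20 * pseudocount)
        if ref_row[j] != "-":
            pos += 1
            std = pos
        else:
            std = None
        columns.append(ProfileColumn(frequencies=freqs, gap_fraction=gaps / n_rows,
                                     standard_position=std))
    ref_seq = ref_row.replace("-", "")
    model = ProfileModel(profile_id=profile_id, columns=columns,
                         reference_id=reference_id, reference_start=reference_start,
                         reference_seq=ref_seq)
    log.info("profile %s: %d match columns (reference span %d-%d)",
             profile_id, len(model.match_columns), reference_start, pos)
    return model


@njit(cache=True)
def _profile_dp(S, gap_open, gap_extend, del_open, del_extend):  # pragma: no cover
    """Affine-gap DP on a position-specific score matrix with free end gaps.

    S has shape (n_profile_columns, query_length). Deleting profile column i
    costs ``del_open[i]`` / ``del_extend[i]`` — occupancy-scaled so that
    skipping a mostly-gapped profile column (an optional loop) is cheap, the
    pairwise analogue of a profile HMM's delete-state probabilities.
    Returns the best score and the traceback path as an array of
    (profile_col, query_pos) match pairs (0-based).
    """
    n, m = S.shape
    neg = -1e30
    M = np.full((n + 1, m + 1), neg)
    Ix = np.full((n + 1, m + 1), neg)  # gap in profile: extra query residue
    Iy = np.full((n + 1, m + 1), neg)  # gap in query: deleted profile column
    # pointers: 0 from M, 1 from Ix, 2 from Iy
    pM = np.zeros((n + 1, m + 1), dtype=np.int8)
    pIx = np.zeros((n + 1, m + 1), dtype=np.int8)
    pIy = np.zeros((n + 1, m + 1), dtype=np.int8)

    M[0, 0] = 0.0
    for j in range(1, m + 1):
        Ix[0, j] = 0.0  # leading query flank is free
        pIx[0, j] = 1
    for i in range(1, n + 1):
        Iy[i, 0] = 0.0  # leading profile deletion is free
        pIy[i, 0] = 2

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # match state
            best = M[i - 1, j - 1]
            ptr = 0
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
                ptr = 1
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
                ptr = 2
            M[i, j] = best + S[i - 1, j - 1]
            pM[i, j] = ptr
            # gap in profile (query residue unaligned); free when outside profile
            if i == n:
                go, ge = 0.0, 0.0
            else:
                go, ge = gap_open, gap_extend
            best = M[i, j - 1] - go
            ptr = 0
            if Ix[i, j - 1] - ge > best:
                best = Ix[i, j - 1] - ge
                ptr = 1
            if Iy[i, j - 1] - go > best:
                best = Iy[i, j - 1] - go
                ptr = 2
            Ix[i, j] = best
            pIx[i, j] = ptr
            # gap in query (profile column deleted); free when outside query
            if j == m:
                go, ge = 0.0, 0.0
            else:
                go, ge = del_open[i - 1], del_extend[i - 1]
            best = M[i - 1, j] - go
            ptr = 0
            if Ix[i - 1, j] - go > best:
                best = Ix[i - 1, j] - go
                ptr = 1
            if Iy[i - 1, j] - ge > best:
                best = Iy[i - 1, j] - ge
                ptr = 2
            Iy[i, j] = best
            pIy[i, j] = ptr

    # choose end state
    state = 0
    score = M[n, m]
    if Ix[n, m] > score:
        score = Ix[n, m]
        state = 1
    if Iy[n, m] > score:
        score = Iy[n, m]
        state = 2

    path = np.full((n + m, 2), -1, dtype=np.int64)
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            path[k, 0] = i - 1
            path[k, 1] = j - 1
            k += 1
            state = pM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            state = pIx[i, j]
            j -= 1
        else:
            state = pIy[i, j]
            i -= 1
    return score, path[:k][::-1].copy()


@dataclass
class NumberingMap:
    """Per-residue standard positions for one sequence.

    ``matches`` pairs 1-based residue indices with standard positions;
    ``insertions`` records unmatched residues against their anchor (the
    preceding standard position, 0 for an N-terminal flank) with a 1-based
    rank, conventionally rendered as e.g. 102a, 102b.
    """

    seq_id: str
    matches: list[tuple[int, int]]
    insertions: list[tuple[int, int, int]] = field(default_factory=list)
    score: float = 0.0

    def __post_init__(self) -> None:
        idx = [m[0] for m in self.matches]
        std = [m[1] for m in self.matches]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue indices must be strictly increasing")
        if any(b <= a for a, b in zip(std, std[1:])):
            raise ValueError("standard positions must be strictly increasing")

    def position_of(self, residue_index: int) -> int | None:
        return dict(self.matches).get(residue_index)

    def residue_at(self, standard_position: int) -> int | None:
        return {s: i for i, s in self.matches}.get(standard_position)

    @property
    def standard_positions(self) -> list[int]:
        return [s for _, s in self.matches]

    def insertion_labels(self) -> list[tuple[int, str]]:
        """Insertion residues as (residue_index, '102a'-style label)."""
        out = []
        for idx, anchor, rank in self.insertions:
            suffix = ""
            r = rank
            while r > 0:
                r, rem = divmod(r - 1, 26)
                suffix = chr(ord("a") + rem) + suffix
            out.append((idx, f"{anchor}{suffix}"))
        return out


def align_to_profile(record: SequenceRecord, profile: ProfileModel,
                     gap_open: float = 10.0, gap_extend: float = 0.5) -> NumberingMap:
    """Align a sequence to a profile and transfer the reference numbering."""
    codes = encode(record.residues)
    scores = profile.score_matrix()  # (n_cols, 21)
    S = scores[:, codes]  # (n_cols, m)
    del_open, del_ext = profile.deletion_costs(gap_open, gap_extend)
    score, path = _profile_dp(np.ascontiguousarray(S), gap_open, gap_extend,
                              del_open, del_ext)
    std = profile.standard_positions
    matches = [(int(q) + 1, std[int(c)]) for c, q in path]
    matched_idx = {q for q, _ in matches}
    pos_by_idx = dict(matches)
    insertions: list[tuple[int, int, int]] = []
    anchor, rank = 0, 0
    for idx in range(1, len(record.residues) + 1):
        if idx in matched_idx:
            anchor, rank = pos_by_idx[idx], 0
        else:
            rank += 1
            insertions.append((idx, anchor, rank))
    return NumberingMap(seq_id=record.id, matches=matches,
                        insertions=insertions, score=float(score))


def numbering_matrix(maps: list[NumberingMap], profile: ProfileModel,
                     sequences: dict[str, str]) -> pd.DataFrame:
    """Stack numbering maps into a residue matrix (rows: sequences,
    columns: standard positions, '-' where a sequence has no residue)."""
    positions = profile.standard_positions
    data = {}
    for nmap in maps:
        row = {s: "-" for s in positions}
        seq = sequences[nmap.seq_id]
        for idx, std in nmap.matches:
            row[std] = seq[idx - 1]
        data[nmap.seq_id] = row
    return pd.DataFrame.from_dict(data, orient="index", columns=positions)


@dataclass
class DomainHit:
    """One profile hit on a sequence with acceptance bookkeeping."""

    seq_id: str
    profile_id: str
    start: int
    end: int
    score: float
    bias: float = 0.0
    evalue: float = float("inf")
    accepted: bool = False
    rejection_reason: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def scan_sequence(record: SequenceRecord, profile: ProfileModel,
                  n_shuffles: int = 200, seed: int = 0,
                  gap_open: float = 10.0, gap_extend: float = 0.5) -> DomainHit:
    """Scan a sequence for the profile's domain.

    The best-scoring window comes from the same free-end-gap alignment used
    for numbering; significance is an extreme-value fit to the scores of
    ``n_shuffles`` residue-shuffled copies of the query (empirical E-value).
    Deterministic under a fixed seed.
    """
    codes = encode(record.residues)
    scores = profile.score_matrix()
    del_open, del_ext = profile.deletion_costs(gap_open, gap_extend)
    S = np.ascontiguousarray(scores[:, codes])
    score, path = _profile_dp(S, gap_open, gap_extend, del_open, del_ext)
    if len(path) == 0:
        return DomainHit(seq_id=record.id, profile_id=profile.profile_id,
                         start=1, end=1, score=float(score), accepted=False,
                         rejection_reason="no aligned residues")
    start = int(path[0, 1]) + 1
    end = int(path[-1, 1]) + 1

    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for k in range(n_shuffles):
        perm = rng.permutation(codes)
        null[k], _ = _profile_dp(np.ascontiguousarray(scores[:, perm]),
                                 gap_open, gap_extend, del_open, del_ext)
    loc, scale = stats.gumbel_r.fit(null)
    evalue = float(stats.gumbel_r.sf(score, loc=loc, scale=scale))
    # bias proxy: score attainable from composition alone (mean null score)
    bias = float(max(null.mean(), 0.0))
    return DomainHit(seq_id=record.id, profile_id=profile.profile_id,
                     start=start, end=end, score=float(score), bias=bias,
                     evalue=evalue)


def filter_hits(hits: list[DomainHit], max_evalue: float = 1e-5,
                min_len: int = 120, max_bias_ratio: float = 0.1) -> list[DomainHit]:
    """Flag hits by the acceptance predicates, recording the first failure.

    Defaults match catalytic-domain annotation (E <= 1e-5, length >= 120,
    bias/score < 0.1); accessory binding modules use the looser preset
    (1e-5, 20, 1). The bias-ratio criterion suppresses false positives from
    low-complexity regions.
    """
    for h in hits:
        if h.evalue > max_evalue:
            h.accepted, h.rejection_reason = False, "max_evalue"
        elif h.length < min_len:
            h.accepted, h.rejection_reason = False, "min_len"
        elif h.score <= 0 and h.bias > 0:
            h.accepted, h.rejection_reason = False, "undefined bias ratio"
        elif h.score > 0 and h.bias / h.score >= max_bias_ratio:
            h.accepted, h.rejection_reason = False, "max_bias_ratio"
        else:
            h.accepted, h.rejection_reason = True, None
    n_ok = sum(1 for h in hits if h.accepted)
    log.info("hit filter: %d/%d accepted (E<=%g, len>=%d, bias ratio<%g)",
             n_ok, len(hits), max_evalue, min_len, max_bias_ratio)
    return hits
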