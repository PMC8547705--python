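"""Per-position conservation categories and cross-subfamily pattern rules.

Each numbered position receives a conservation score from 1 (fastest
evolving) to 5 (slowest / most conserved). The per-position rate proxy is
the sequence-weighted expected dissimilarity between residue pairs, with
position-based sequence weights and a substitution-matrix-derived
dissimilarity; a residue-vs-gap pair counts as maximally dissimilar. Rates
are discretized into five equal-frequency categories over all numbered
positions (ties resolved toward the more conserved bin) and positions with
a gap in at least half of the sequences are forced to score 1. Per-site
output of an external empirical-Bayes rate program can be read in as a
drop-in replacement for the proxy.

Two cross-subfamily rules operate on standard positions related by a
correspondence table (the product of structurally aligning the two
reference structures): the shared core (score 5 on both sides, gap in at
most 10% of each subfamily, and some residue above 5% frequency in both)
and subfamily-specific patterns (score-5 positions with no correspondent,
or corresponding but with residue-frequency overlap below 5%; the 5% floor
avoids calling patterns that are not actually subfamily-specific).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .records import CANONICAL_AA

log = logging.getLogger("gh19net")

_AA_INDEX = {a: i for i, a in enumerate(CANONICAL_AA)}


def _dissimilarity_matrix() -> np.ndarray:
    """d(a, b) = 1 - max(B(a,b), 0) / min(B(a,a), B(b,b)); d(a, a) = 0."""
    blosum = substitution_matrices.load("BLOSUM62")
    d = np.zeros((20, 20))
    for i, a in enumerate(CANONICAL_AA):
        for j, b in enumerate(CANONICAL_AA):
            if i == j:
                continue
            sim = max(float(blosum[a, b]), 0.0) / min(float(blosum[a, a]), float(blosum[b, b]))
            d[i, j] = 1.0 - min(sim, 1.0)
    return d


_DISSIM = _dissimilarity_matrix()


@dataclass
class ConservationProfile:
    """Per-standard-position conservation for one subfamily."""

    positions: list[int]
    scores: dict[int, int]          # 1..5 per position
    gap_fractions: dict[int, float]
    frequencies: dict[int, dict[str, float]]  # residue freq among non-gap rows
    rates: dict[int, float] | None = None

    def residue_coverage(self, position: int) -> dict[str, float]:
        """Fraction of all sequences carrying each residue at a position."""
        nongap = 1.0 - self.gap_fractions[position]
        return {r: f * nongap for r, f in self.frequencies[position].items()}


def position_weights(msa: pd.DataFrame) -> np.ndarray:
    """Position-based sequence weights (Henikoff-Henikoff), normalized to sum 1."""
    n_seq = len(msa)
    w = np.zeros(n_seq)
    values = msa.to_numpy()
    for j in range(values.shape[1]):
        col = values[:, j]
        residues, counts = np.unique(col[col != "-"], return_counts=True)
        k = len(residues)
        if k == 0:
            continue
        count_of = dict(zip(residues, counts))
        for i, c in enumerate(col):
            if c != "-":
                w[i] += 1.0 / (k * count_of[c])
    if w.sum() == 0:
        return np.full(n_seq, 1.0 / n_seq)
    return w / w.sum()


def _column_rate(col: np.ndarray, weights: np.ndarray) -> float:
    """Weighted mean pairwise dissimilarity of one column.

    Residue-gap pairs are maximally dissimilar (1.0); gap-gap pairs are
    excluded from the average.
    """
    res_mask = col != "-"
    w_res = weights[res_mask]
    w_gap_total = float(weights[~res_mask].sum())
    codes = np.array([_AA_INDEX.get(c, -1) for c in col[res_mask]])
    valid = codes >= 0  # X and other ambiguity excluded from pairing
    w_res, codes = w_res[valid], codes[valid]

    c = np.zeros(20)
    np.add.at(c, codes, w_res)
    w_res_total = float(w_res.sum())
    # off-diagonal residue pairs, weighted; diagonal contributes 0 by construction
    cross = float(c @ _DISSIM @ c)
    pair_weight = w_res_total**2 - float((w_res**2).sum())
    gap_pairs = 2.0 * w_res_total * w_gap_total
    denom = pair_weight + gap_pairs
    if denom <= 0:
        return 0.0
    return (cross + gap_pairs * 1.0) / denom


def conservation_scores(numbered_msa: pd.DataFrame,
                        rates: dict[int, float] | None = None,
                        gap_score1_fraction: float = 0.5) -> ConservationProfile:
    """Score every numbered position of an aligned subfamily.

    ``numbered_msa``: rows are sequences, columns standard positions,
    entries residues or '-'. Externally computed per-site ``rates`` may be
    supplied; otherwise the internal proxy is used. Positions with a gap
    fraction of at least ``gap_score1_fraction`` are forced to score 1.
    """
    if len(numbered_msa) < 5:
        raise ValueError("conservation scoring needs at least 5 sequences")
    positions = [int(p) for p in numbered_msa.columns]
    values = numbered_msa.to_numpy()
    weights = position_weights(numbered_msa)

    if rates is None:
        rates = {p: _column_rate(values[:, j], weights) for j, p in enumerate(positions)}
    rate_arr = np.array([rates[p] for p in positions], dtype=float)

    qs = np.quantile(rate_arr, [0.2, 0.4, 0.6, 0.8])
    scores: dict[int, int] = {}
    gap_fractions: dict[int, float] = {}
    frequencies: dict[int, dict[str, float]] = {}
    for j, p in enumerate(positions):
        col = values[:, j]
        gap_fractions[p] = float(np.mean(col == "-"))
        res, counts = np.unique(col[col != "-"], return_counts=True)
        total = counts.sum()
        frequencies[p] = ({r: c / total for r, c in zip(res, counts)} if total else {})
        # ties land in the more conserved bin via <=
        r = rate_arr[j]
        if r <= qs[0]:
            s = 5
        elif r <= qs[1]:
            s = 4
        elif r <= qs[2]:
            s = 3
        elif r <= qs[3]:
            s = 2
        else:
            s = 1
        if gap_fractions[p] >= gap_score1_fraction:
            s = 1
        scores[p] = s
    return ConservationProfile(positions=positions, scores=scores,
                               gap_fractions=gap_fractions, frequencies=frequencies,
                               rates=dict(rates))


def read_rate_file(path: str | Path) -> dict[int, float]:
    """Read per-site rates from an external rate program's output.

    Accepts whitespace-separated tables whose first column is the position
    and third column the rate (header/comment lines starting with '#'
    skipped), the common per-site output layout.
    """
    rates: dict[int, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            try:
                pos = int(fields[0])
                rate = float(fields[2] if len(fields) > 2 else fields[1])
            except (ValueError, IndexError):
                continue
            rates[pos] = rate
    if not rates:
        raise ValueError(f"no per-site rates parsed from {path}")
    return rates


@dataclass
class SharedCorePosition:
    position_a: int
    position_b: int
    common_residues: list[str]


@dataclass
class PatternPosition:
    subfamily: str
    position: int
    residues: dict[str, float]  # top residues with coverage fractions
    corresponding: bool


def _coverage(profile: ConservationProfile, position: int) -> dict[str, float]:
    return profile.residue_coverage(position)


def shared_core(profile_a: ConservationProfile, profile_b: ConservationProfile,
                correspondence: list[tuple[int, int]], min_score: int = 5,
                max_gap_fraction: float = 0.10,
                min_common_freq: float = 0.05) -> list[SharedCorePosition]:
    """Positions conserved in both subfamilies with a residue in common.

    Emits correspondence pairs where both sides score >= ``min_score``, both
    gap fractions are <= ``max_gap_fraction`` and at least one residue
    exceeds ``min_common_freq`` of the sequences in both subfamilies.
    """
    out: list[SharedCorePosition] = []
    for pa, pb in correspondence:
        if pa not in profile_a.scores or pb not in profile_b.scores:
            continue
        if profile_a.scores[pa] < min_score or profile_b.scores[pb] < min_score:
            continue
        if profile_a.gap_fractions[pa] > max_gap_fraction:
            continue
        if profile_b.gap_fractions[pb] > max_gap_fraction:
            continue
        cov_a = _coverage(profile_a, pa)
        cov_b = _coverage(profile_b, pb)
        common = sorted(r for r in cov_a
                        if cov_a[r] > min_common_freq and cov_b.get(r, 0.0) > min_common_freq)
        if common:
            out.append(SharedCorePosition(position_a=pa, position_b=pb,
                                          common_residues=common))
    log.info("shared core: %d positions", len(out))
    return out


def frequency_overlap(cov_a: dict[str, float], cov_b: dict[str, float]) -> float:
    """Overlap of two residue coverage distributions: sum of per-residue minima."""
    return sum(min(f, cov_b.get(r, 0.0)) for r, f in cov_a.items())


def specific_patterns(profile_a: ConservationProfile, profile_b: ConservationProfile,
                      correspondence: list[tuple[int, int]], min_score: int = 5,
                      max_overlap: float = 0.05,
                      names: tuple[str, str] = ("A", "B")) -> dict[str, list[PatternPosition]]:
    """Subfamily-specific sequence patterns.

    A score-5 position is specific when it has no correspondent in the other
    subfamily's numbering, or when it corresponds but the residue-frequency
    distributions overlap by less than ``max_overlap``.
    """
    a_to_b = dict(correspondence)
    b_to_a = {b: a for a, b in correspondence}
    result: dict[str, list[PatternPosition]] = {names[0]: [], names[1]: []}

    for name, prof, other, mapping in (
        (names[0], profile_a, profile_b, a_to_b),
        (names[1], profile_b, profile_a, b_to_a),
    ):
        for p in prof.positions:
            if prof.scores[p] < min_score:
                continue
            cov = _coverage(prof, p)
            partner = mapping.get(p)
            if partner is None or partner not in other.scores:
                result[name].append(PatternPosition(subfamily=name, position=p,
                                                    residues=cov, corresponding=False))
            else:
                if frequency_overlap(cov, _coverage(other, partner)) < max_overlap:
                    result[name].append(PatternPosition(subfamily=name, position=p,
                                                        residues=cov, corresponding=True))
    log.info("specific patterns: %s", {k: len(v) for k, v in result.items()})
    return result


def region_conservation(profile: ConservationProfile, start: int, end: int) -> float:
    """Arithmetic mean conservation score over standard positions [start, end]."""
    scores = [profile.scores[p] for p in profile.positions if start <= p <= end]
    if not scores:
        raise ValueError(f"no numbered positions in range {start}-{end}")
    return float(np.mean(scores))
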