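"""Greedy identity-threshold clustering.

The same operation is used at 99% (collapsing near-identical sequence
entries into protein entries), 90% (centroids for network construction),
65% (representatives for conservation analysis) and 40% (phylogeny
centroids). Sequences are processed in descending length order (ties broken
lexicographically by id) and each is assigned to the best-identity existing
centroid meeting the threshold, else it founds a new cluster. Best-hit
assignment rather than first-hit keeps the outcome robust to centroid
ordering; both the order and the assignment rule are deliberate, since
heuristic clustering tools differ on them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .pairwise import PairwiseScorer
from .records import SequenceRecord

log = logging.getLogger("gh19net")


@dataclass
class ClusterSet:
    """A partition of sequence ids into identity clusters around centroids."""

    threshold_pct: float
    clusters: list[tuple[str, list[str]]]  # (centroid_id, member_ids incl. centroid)

    @property
    def centroid_ids(self) -> list[str]:
        return [c for c, _ in self.clusters]

    def membership(self) -> dict[str, str]:
        """Map every member id to its centroid id."""
        return {m: c for c, members in self.clusters for m in members}

    def to_tsv(self, path, identities: dict[str, float] | None = None) -> None:
        import pandas as pd

        rows = []
        for centroid, members in self.clusters:
            for m in members:
                ident = 100.0 if m == centroid else (identities or {}).get(m, float("nan"))
                rows.append((centroid, m, ident))
        pd.DataFrame(rows, columns=["centroid_id", "member_id", "identity_pct"]).to_csv(
            path, sep="\t", index=False)


def greedy_cluster(records: list[SequenceRecord], threshold_pct: float,
                   scorer: PairwiseScorer | None = None) -> ClusterSet:
    """Cluster sequences greedily at a global-identity threshold."""
    if not (0 < threshold_pct <= 100):
        raise ValueError(f"threshold_pct={threshold_pct} outside (0, 100]")
    if scorer is None:
        scorer = PairwiseScorer()
    ordered = sorted(records, key=lambda r: (-len(r), r.id))
    centroids: list[SequenceRecord] = []
    members: dict[str, list[str]] = {}
    for rec in ordered:
        best_id, best_ident = None, -1.0
        for cen in centroids:
            ident = scorer.identity(rec.residues, cen.residues)
            if ident >= threshold_pct and ident > best_ident:
                best_id, best_ident = cen.id, ident
        if best_id is None:
            centroids.append(rec)
            members[rec.id] = [rec.id]
        else:
            members[best_id].append(rec.id)
    clusters = [(c.id, members[c.id]) for c in centroids]
    log.info("greedy clustering at %.1f%%: %d sequences -> %d clusters",
             threshold_pct, len(records), len(clusters))
    return ClusterSet(threshold_pct=threshold_pct, clusters=clusters)


def assign_protein_entries(records: list[SequenceRecord], threshold_pct: float = 99.0,
                           scorer: PairwiseScorer | None = None) -> ClusterSet:
    """Collapse near-identical sequence entries into protein entries (99%)."""
    return greedy_cluster(records, threshold_pct, scorer=scorer)
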