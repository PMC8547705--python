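"""Seed-anchored subfamily and group assignment.

Subfamilies are the connected components of the 40%-identity network that
contain at least one characterized seed; the seeds' shared activity label
(chitinase -> CHIT, endolysin -> ELYS) names the subfamily. Each subfamily
is then split at 60% identity into groups: a component becomes a named group
if it contains a seed or is formed by at least ten centroid sequences.
Labels propagate from centroids to all members of their 90% clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .cluster import ClusterSet
from .records import SequenceRecord

log = logging.getLogger("gh19net")

UNASSIGNED = "unassigned"
CONFLICT = "conflict"

SUBFAMILY_NAMES = {"chitinase": "CHIT", "endolysin": "ELYS", "other": "OTHER"}


@dataclass
class SubfamilyAssignment:
    centroid_labels: dict[str, str]
    sequence_labels: dict[str, str]
    components: list[set[str]] = field(default_factory=list)


@dataclass
class GroupAssignment:
    centroid_labels: dict[str, str]
    sequence_labels: dict[str, str]
    group_info: dict[str, dict] = field(default_factory=dict)  # name -> metadata
    merges: list[tuple[str, ...]] = field(default_factory=list)


def _propagate(centroid_labels: dict[str, str], clusters: ClusterSet | None) -> dict[str, str]:
    if clusters is None:
        return dict(centroid_labels)
    labels: dict[str, str] = {}
    for centroid, members in clusters.clusters:
        lab = centroid_labels.get(centroid, UNASSIGNED)
        for m in members:
            labels[m] = lab
    return labels


def assign_subfamilies(components_at_40: list[set[str]],
                       records: list[SequenceRecord],
                       clusters: ClusterSet | None = None) -> SubfamilyAssignment:
    """Label each 40%-network component by its seeds' activity.

    Components whose seeds disagree on activity are flagged ``conflict``
    rather than silently merged; seedless components stay ``unassigned``
    (they are kept, as small uncharacterized networks are retained in the
    database rather than dropped).
    """
    by_id = {r.id: r for r in records}
    centroid_labels: dict[str, str] = {}
    for comp in components_at_40:
        seed_activities = {
            by_id[cid].activity_label
            for cid in comp
            if cid in by_id and by_id[cid].is_seed
        }
        if not seed_activities:
            label = UNASSIGNED
        elif len(seed_activities) > 1:
            label = CONFLICT
            log.warning("component with conflicting seed activities: %s", sorted(seed_activities))
        else:
            label = SUBFAMILY_NAMES.get(next(iter(seed_activities)), next(iter(seed_activities)))
        for cid in comp:
            centroid_labels[cid] = label
    seq_labels = _propagate(centroid_labels, clusters)
    n_named = sum(1 for v in seq_labels.values() if v not in (UNASSIGNED, CONFLICT))
    log.info("subfamily assignment: %d/%d sequences in named subfamilies",
             n_named, len(seq_labels))
    return SubfamilyAssignment(centroid_labels=centroid_labels,
                               sequence_labels=seq_labels,
                               components=components_at_40)


def assign_groups(components_at_60: list[set[str]],
                  records: list[SequenceRecord],
                  subfamily: str,
                  min_centroids: int = 10,
                  clusters: ClusterSet | None = None) -> GroupAssignment:
    """Number the 60%-components of one subfamily into groups.

    A component is a group if it contains a seed or has at least
    ``min_centroids`` centroid sequences; groups are named by descending
    centroid count (``<subfamily> 1`` is the most populous).
    """
    by_id = {r.id: r for r in records}
    ordered = sorted(components_at_60, key=lambda c: (-len(c), min(c)))
    centroid_labels: dict[str, str] = {}
    group_info: dict[str, dict] = {}
    rank = 0
    for comp in ordered:
        has_seed = any(cid in by_id and by_id[cid].is_seed for cid in comp)
        if has_seed or len(comp) >= min_centroids:
            rank += 1
            name = f"{subfamily} {rank}"
            group_info[name] = {"n_centroids": len(comp), "has_seed": has_seed,
                                "subfamily": subfamily}
        else:
            name = UNASSIGNED
        for cid in comp:
            centroid_labels[cid] = name
    seq_labels = _propagate(centroid_labels, clusters)
    log.info("group assignment in %s: %d groups from %d components",
             subfamily, rank, len(ordered))
    return GroupAssignment(centroid_labels=centroid_labels,
                           sequence_labels=seq_labels, group_info=group_info)


def merge_groups(assignment: GroupAssignment,
                 pairs_to_merge: list[tuple[str, str]]) -> GroupAssignment:
    """Apply explicit curator merges (e.g. groups sharing characterized members).

    Merging across subfamilies is refused; merged groups get a combined
    name and the provenance is retained in ``merges``.
    """
    centroid_labels = dict(assignment.centroid_labels)
    seq_labels = dict(assignment.sequence_labels)
    group_info = {k: dict(v) for k, v in assignment.group_info.items()}
    merges = list(assignment.merges)
    for a, b in pairs_to_merge:
        if a not in group_info or b not in group_info:
            raise ValueError(f"cannot merge unknown group(s): {a!r}, {b!r}")
        if group_info[a]["subfamily"] != group_info[b]["subfamily"]:
            raise ValueError(f"refusing to merge groups across subfamilies: {a!r} vs {b!r}")
        merged = f"{a}+{b.split(' ', 1)[-1]}"
        for labels in (centroid_labels, seq_labels):
            for k, v in labels.items():
                if v in (a, b):
                    labels[k] = merged
        group_info[merged] = {
            "n_centroids": group_info[a]["n_centroids"] + group_info[b]["n_centroids"],
            "has_seed": group_info[a]["has_seed"] or group_info[b]["has_seed"],
            "subfamily": group_info[a]["subfamily"],
            "merged_from": (a, b),
        }
        del group_info[a], group_info[b]
        merges.append((a, b, merged))
        log.info("merged groups %s and %s -> %s", a, b, merged)
    return GroupAssignment(centroid_labels=centroid_labels, sequence_labels=seq_labels,
                           group_info=group_info, merges=merges)
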