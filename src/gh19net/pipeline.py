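"""End-to-end synthetic workflow: simulate -> identity -> cluster -> network
-> classify -> number -> conserve -> loops, with recovery metrics.

This is the reference composition of the package's stages; the CLI's
``pipeline`` subcommand and the acceptance checks drive it. One pairwise
scorer (with its alignment cache) is shared by every stage, so each distinct
sequence pair is aligned once for the whole run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import classify, conservation, loops, network, profiles
from .cluster import ClusterSet, greedy_cluster
from .io import filter_fragments
from .pairwise import IdentityMatrix, PairwiseScorer, all_vs_all
from .records import SequenceRecord
from .simulate import SimulationConfig, TruthTable, simulate_families, truth_report

log = logging.getLogger("gh19net")


@dataclass
class PipelineResult:
    records: list[SequenceRecord]
    truth: TruthTable
    matrix: IdentityMatrix
    clusters: ClusterSet
    subfamilies: classify.SubfamilyAssignment
    groups: dict[str, classify.GroupAssignment]
    sequence_groups: dict[str, str] = field(default_factory=dict)
    conservation_profiles: dict[str, conservation.ConservationProfile] = field(default_factory=dict)
    shared_core: list = field(default_factory=list)
    patterns: dict[str, list] = field(default_factory=dict)
    group_codes: dict[str, str] = field(default_factory=dict)
    report: dict = field(default_factory=dict)


def run_synthetic_pipeline(config: SimulationConfig | None = None, seed: int = 0,
                           subfamily_threshold: float = 40.0,
                           group_threshold: float = 60.0,
                           centroid_threshold: float = 90.0,
                           min_fragment_len: int = 120) -> PipelineResult:
    """Run the full analysis on one synthetic family and score the recovery."""
    records, truth = simulate_families(config, seed=seed)
    records, _fragments = filter_fragments(records, min_len=min_fragment_len)
    scorer = PairwiseScorer()

    # centroids and all-vs-all identity
    clusters = greedy_cluster(records, centroid_threshold, scorer=scorer)
    by_id = {r.id: r for r in records}
    centroids = [by_id[c] for c in clusters.centroid_ids]
    matrix = all_vs_all(centroids, scorer=scorer)

    # subfamilies at 40%
    net40 = network.build_network(matrix, subfamily_threshold)
    comps40 = network.connected_components(net40)
    subfam = classify.assign_subfamilies(comps40, records, clusters=clusters)

    # groups at 60% within each named subfamily
    net60 = network.build_network(matrix, group_threshold)
    groups: dict[str, classify.GroupAssignment] = {}
    sequence_groups: dict[str, str] = {}
    named = sorted({v for v in subfam.centroid_labels.values()
                    if v not in (classify.UNASSIGNED, classify.CONFLICT)})
    for sf in named:
        sf_centroids = {c for c, lab in subfam.centroid_labels.items() if lab == sf}
        sub = net60.subgraph(sf_centroids)
        comps60 = network.connected_components(sub)
        sub_clusters = ClusterSet(
            threshold_pct=clusters.threshold_pct,
            clusters=[(c, m) for c, m in clusters.clusters if c in sf_centroids])
        ga = classify.assign_groups(comps60, records, subfamily=sf, clusters=sub_clusters)
        groups[sf] = ga
        sequence_groups.update(ga.sequence_labels)

    # numbering, conservation and loops per subfamily
    profiles_by_sf: dict[str, profiles.ProfileModel] = {}
    cons: dict[str, conservation.ConservationProfile] = {}
    annotations_by_group: dict[str, list[loops.LoopAnnotation]] = {}
    for sf in named:
        prof = profiles.build_profile(truth.seed_msa[sf], reference_id=f"{sf}_ref",
                                      profile_id=sf)
        profiles_by_sf[sf] = prof
        members = [r for r in records if subfam.sequence_labels.get(r.id) == sf]
        maps = [profiles.align_to_profile(r, prof) for r in members]
        msa = profiles.numbering_matrix(maps, prof, {r.id: r.residues for r in members})
        cons[sf] = conservation.conservation_scores(msa)
        loop_defs = truth.loop_definitions.get(sf, [])
        for nmap in maps:
            gname = sequence_groups.get(nmap.seq_id, classify.UNASSIGNED)
            if gname == classify.UNASSIGNED:
                continue
            annotations_by_group.setdefault(gname, []).append(
                loops.annotate_loops(nmap, loop_defs))

    # cross-subfamily conservation rules (needs exactly the two subfamilies)
    shared = []
    patterns: dict[str, list] = {}
    if len(named) == 2 and named[0] in truth.seed_msa and named[1] in truth.seed_msa:
        sf_a, sf_b = sorted(truth.seed_msa)[0], sorted(truth.seed_msa)[1]
        if sf_a in cons and sf_b in cons:
            shared = conservation.shared_core(cons[sf_a], cons[sf_b], truth.correspondence)
            patterns = conservation.specific_patterns(cons[sf_a], cons[sf_b],
                                                      truth.correspondence,
                                                      names=(sf_a, sf_b))

    group_codes: dict[str, str] = {}
    for gname, anns in annotations_by_group.items():
        loop_names = [d.name for d in truth.loop_definitions[
            groups_subfamily(groups, gname)]]
        group_codes[gname] = loops.group_loop_code(anns, gname,
                                                   loop_names=loop_names).code

    report = truth_report(
        truth,
        inferred_subfamily=subfam.sequence_labels,
        inferred_group=sequence_groups,
        inferred_group_codes=group_codes,
        inferred_core={(s.position_a, s.position_b) for s in shared},
        inferred_patterns={sf: {p.position for p in pts} for sf, pts in patterns.items()},
    )
    log.info("pipeline report: %s", report)
    return PipelineResult(records=records, truth=truth, matrix=matrix,
                          clusters=clusters, subfamilies=subfam, groups=groups,
                          sequence_groups=sequence_groups, conservation_profiles=cons,
                          shared_core=shared, patterns=patterns,
                          group_codes=group_codes, report=report)


def groups_subfamily(groups: dict[str, classify.GroupAssignment], group_name: str) -> str:
    for sf, ga in groups.items():
        if group_name in ga.group_info:
            return sf
    raise KeyError(f"unknown group {group_name!r}")
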