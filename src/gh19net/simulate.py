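"""Synthetic protein families with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: two subfamilies (chitinase-like and endolysin-like) whose members
diverge along a star-per-group design — a root domain gives rise to one
consensus per subfamily, each subfamily consensus to one consensus per
group, and each group consensus to its members. Divergence is ordered
within-group < between-group < between-subfamily, calibrated so that
within-group identities sit well above the 60% group threshold, between
groups of one subfamily between the 40% and 60% thresholds, and between
subfamilies near the empirical 30% peak of real GH19 domain identities.

Structure implanted on top of the substitution process:

* invariant core columns shared across both subfamilies (never mutated),
* subfamily-specific pattern columns — either contrasting fixed residues at
  one ancestral position, or fixed residues inside a subfamily-specific
  insert segment that the other subfamily lacks entirely,
* loop segments: contiguous insertions relative to the loopless ancestor
  with per-group presence flags, so loopless members are subsequences of
  loopful ones at loop positions,
* one subfamily-specific insert per subfamily (present in all its groups).

Indels occur only at segment granularity, so the true column correspondence
is exact and pattern/core recovery can be scored against the truth. The
substitution model is uniform replacement with a BLOSUM-biased proposal
(replacements with a positive BLOSUM62 score to the current residue are
favored 3:1) — protein-like enough to keep identity calibration meaningful,
with no claim of phylogenetic realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from scipy.optimize import linear_sum_assignment

from .loops import LoopDefinition
from .records import CANONICAL_AA, SequenceRecord

_AA = np.array(list(CANONICAL_AA))
_AA_INDEX = {a: i for i, a in enumerate(CANONICAL_AA)}


def _proposal_weights() -> np.ndarray:
    blosum = substitution_matrices.load("BLOSUM62")
    w = np.ones((20, 20))
    for i, a in enumerate(CANONICAL_AA):
        for j, b in enumerate(CANONICAL_AA):
            if i == j:
                w[i, j] = 0.0
            elif blosum[a, b] > 0:
                w[i, j] = 3.0
    return w / w.sum(axis=1, keepdims=True)


_PROPOSAL = _proposal_weights()


@dataclass
class Segment:
    """A contiguous insertion relative to the loopless ancestral domain."""

    name: str
    insert_after: int  # ancestral core position (0 = before the domain)
    length: int
    presence: dict[str, bool]  # group id -> carries the segment


@dataclass
class SimulationConfig:
    n_subfamilies: int = 2
    groups_per_subfamily: int = 3
    sequences_per_group: int = 20
    domain_length: int = 160
    within_group_substitutions_per_site: float = 0.08
    between_group_divergence: float = 0.28
    between_subfamily_divergence: float = 0.50
    fraction_seeds_per_group: float = 0.1
    subfamilies: tuple[str, ...] = ("CHIT", "ELYS")
    activities: dict[str, str] = field(
        default_factory=lambda: {"CHIT": "chitinase", "ELYS": "endolysin"})
    core_columns: list[tuple[int, str]] = field(default_factory=list)
    #: per subfamily: list of (ancestral position | (segment name, offset), residue)
    pattern_columns: dict[str, list[tuple[object, str]]] = field(default_factory=dict)
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_subfamilies != 2:
            raise ValueError("the generator models exactly two subfamilies")
        if not self.core_columns:
            self.core_columns = default_core_columns(self.domain_length)
        if not self.segments:
            self.segments = default_segments(self.subfamilies,
                                             self.groups_per_subfamily)
        if not self.pattern_columns:
            self.pattern_columns = default_pattern_columns(self.subfamilies)
        self._validate()

    def _validate(self) -> None:
        d = (self.within_group_substitutions_per_site,
             self.between_group_divergence, self.between_subfamily_divergence)
        if not (0 <= d[0] < d[1] < d[2] <= 1):
            raise ValueError(
                "divergences must be ordered within < between-group < between-subfamily")
        seg_by_name = {s.name: s for s in self.segments}
        core_pos = {p for p, _ in self.core_columns}
        if any(not (1 <= p <= self.domain_length) for p in core_pos):
            raise ValueError("core column outside the ancestral domain")
        for s in self.segments:
            if not (0 <= s.insert_after <= self.domain_length):
                raise ValueError(f"segment {s.name}: insertion point outside the domain")
        pattern_core: set[int] = set()
        for sf, cols in self.pattern_columns.items():
            groups = [f"{sf}_g{g}" for g in range(1, self.groups_per_subfamily + 1)]
            for pos, _residue in cols:
                if isinstance(pos, tuple):
                    seg_name, offset = pos
                    seg = seg_by_name.get(seg_name)
                    if seg is None:
                        raise ValueError(f"pattern column in unknown segment {seg_name!r}")
                    if not (1 <= offset <= seg.length):
                        raise ValueError(f"pattern offset {offset} outside segment {seg_name}")
                    missing = [g for g in groups if not seg.presence.get(g, False)]
                    if missing:
                        raise ValueError(
                            f"pattern position inside segment {seg_name!r} absent "
                            f"from group(s) {missing} of subfamily {sf}")
                else:
                    if not (1 <= pos <= self.domain_length):
                        raise ValueError(f"pattern position {pos} outside the domain")
                    pattern_core.add(int(pos))
        if pattern_core & core_pos:
            raise ValueError("core and pattern positions must be disjoint")


def default_core_columns(domain_length: int, n_core: int = 40,
                         avoid: tuple[int, ...] = (30, 85, 140)) -> list[tuple[int, str]]:
    """Evenly spread invariant columns with a recurring core motif.

    The default count keeps the fraction of invariant columns near the
    score-5 fractions observed in real subfamilies (about a fifth to a
    quarter of numbered positions), which also lets the equal-frequency
    conservation categories resolve the implanted columns exactly.
    ``avoid`` excludes the default contrasting pattern positions.
    """
    motif = "EGSNYWDHTEGSNYWDHTEGSNYWDH"
    positions = list(np.linspace(4, domain_length - 4, n_core).astype(int))
    out: list[int] = []
    prev = 0
    for p in positions:
        p = int(max(p, prev + 1))
        while p in avoid:
            p += 1
        out.append(p)
        prev = p
    return [(p, motif[i % len(motif)]) for i, p in enumerate(out)]


def default_segments(subfamilies=("CHIT", "ELYS"), groups_per_subfamily: int = 3
                     ) -> list[Segment]:
    """Six loops with per-group presence plus one insert per subfamily.

    Default per-group loop codes (loops 1..5, C-terminal):
    group 1 of each subfamily is loopful; the others mix presence/absence,
    echoing the loopful/loopless contrast of real chitinase groups.
    """
    a, b = subfamilies
    flags = {
        f"{a}_g1": (1, 1, 1, 1, 1, 1),
        f"{a}_g2": (1, 0, 1, 0, 0, 0),
        f"{a}_g3": (1, 1, 0, 1, 1, 0),
        f"{b}_g1": (1, 1, 1, 1, 1, 1),
        f"{b}_g2": (0, 1, 1, 0, 1, 1),
        f"{b}_g3": (1, 0, 1, 1, 0, 1),
    }
    loop_specs = [
        ("loop_1", 20, 8), ("loop_2", 45, 7), ("loop_3", 70, 9),
        ("loop_4", 95, 6), ("loop_5", 120, 7), ("loop_C", 150, 8),
    ]
    segments = [
        Segment(name=name, insert_after=after, length=length,
                presence={g: bool(f[k]) for g, f in flags.items()})
        for k, (name, after, length) in enumerate(loop_specs)
    ]
    groups_a = [f"{a}_g{i}" for i in range(1, groups_per_subfamily + 1)]
    groups_b = [f"{b}_g{i}" for i in range(1, groups_per_subfamily + 1)]
    segments.append(Segment(name=f"insert_{a}", insert_after=60, length=4,
                            presence={**{g: True for g in groups_a},
                                      **{g: False for g in groups_b}}))
    segments.append(Segment(name=f"insert_{b}", insert_after=110, length=3,
                            presence={**{g: False for g in groups_a},
                                      **{g: True for g in groups_b}}))
    return segments


def default_pattern_columns(subfamilies=("CHIT", "ELYS")) -> dict:
    """Three contrasting core positions plus insert-hosted positions.

    The contrasting positions carry a different invariant residue in each
    subfamily (zero frequency overlap), so they are specific to both; the
    insert-hosted positions have no correspondent in the other subfamily.
    Defaults yield six specific positions in the first subfamily and four
    in the second.
    """
    a, b = subfamilies
    return {
        a: [(30, "W"), (85, "H"), (140, "C"),
            ((f"insert_{a}", 1), "P"), ((f"insert_{a}", 2), "W"),
            ((f"insert_{a}", 4), "Y")],
        b: [(30, "D"), (85, "F"), (140, "K"),
            ((f"insert_{b}", 2), "R")],
    }


@dataclass
class TruthTable:
    """Ground truth emitted alongside the synthetic sequences."""

    subfamily: dict[str, str]              # seq id -> subfamily name
    group: dict[str, str]                  # seq id -> true group id
    loop_presence: dict[str, dict[str, bool]]  # seq id -> loop name -> present
    is_seed: dict[str, bool]
    references: dict[str, SequenceRecord]  # subfamily -> reference record
    seed_msa: dict[str, list[tuple[str, str]]]  # subfamily -> aligned seed rows
    loop_definitions: dict[str, list[LoopDefinition]]
    correspondence: list[tuple[int, int]]  # (std position A, std position B)
    core_positions: list[tuple[int, int]]
    pattern_positions: dict[str, set[int]]
    group_loop_codes: dict[str, str]

    def to_frame(self):
        import pandas as pd

        loops = sorted({ln for v in self.loop_presence.values() for ln in v})
        rows = []
        for sid in self.subfamily:
            row = {"id": sid, "subfamily": self.subfamily[sid],
                   "group": self.group[sid], "is_seed": self.is_seed[sid]}
            row.update({f"loop:{ln}": int(self.loop_presence[sid][ln]) for ln in loops})
            rows.append(row)
        return pd.DataFrame(rows)


def _mutate(codes: np.ndarray, p: float, rng: np.random.Generator,
            protected: np.ndarray | None = None) -> np.ndarray:
    out = codes.copy()
    hit = rng.random(len(codes)) < p
    if protected is not None:
        hit &= ~protected
    for i in np.nonzero(hit)[0]:
        out[i] = rng.choice(20, p=_PROPOSAL[out[i]])
    return out


def simulate_families(config: SimulationConfig | None = None, seed: int = 0
                      ) -> tuple[list[SequenceRecord], TruthTable]:
    """Generate two synthetic subfamilies with full ground truth.

    Deterministic under a fixed seed: two runs with identical arguments
    yield identical records and truth tables.
    """
    cfg = config if config is not None else SimulationConfig()
    rng = np.random.default_rng(seed)
    L = cfg.domain_length
    segs = sorted(cfg.segments, key=lambda s: (s.insert_after, s.name))
    sf_a, sf_b = cfg.subfamilies

    # --- root domain and segment sequences -------------------------------
    root_core = rng.integers(0, 20, size=L)
    core_protect = np.zeros(L, dtype=bool)
    for pos, res in cfg.core_columns:
        root_core[pos - 1] = _AA_INDEX[res]
        core_protect[pos - 1] = True
    contrast_positions = {
        int(pos) for cols in cfg.pattern_columns.values()
        for pos, _ in cols if not isinstance(pos, tuple)
    }
    for pos in contrast_positions:
        core_protect[pos - 1] = True  # overwritten per subfamily, never mutated
    root_segs = {s.name: rng.integers(0, 20, size=s.length) for s in segs}

    # --- per-subfamily consensus -----------------------------------------
    sf_core: dict[str, np.ndarray] = {}
    sf_segs: dict[str, dict[str, np.ndarray]] = {}
    seg_protect: dict[str, dict[str, np.ndarray]] = {}
    for sf in cfg.subfamilies:
        core = _mutate(root_core, cfg.between_subfamily_divergence, rng, core_protect)
        protect = {s.name: np.zeros(s.length, dtype=bool) for s in segs}
        for pos, res in cfg.pattern_columns.get(sf, []):
            if isinstance(pos, tuple):
                seg_name, offset = pos
                protect[seg_name][offset - 1] = True
            else:
                core[pos - 1] = _AA_INDEX[res]
        seg_seqs = {}
        for s in segs:
            seg_seqs[s.name] = _mutate(root_segs[s.name],
                                       cfg.between_subfamily_divergence, rng,
                                       protect[s.name])
        for pos, res in cfg.pattern_columns.get(sf, []):
            if isinstance(pos, tuple):
                seg_name, offset = pos
                seg_seqs[seg_name][offset - 1] = _AA_INDEX[res]
        sf_core[sf] = core
        sf_segs[sf] = seg_seqs
        seg_protect[sf] = protect

    # --- per-group consensus ---------------------------------------------
    group_ids = [f"{sf}_g{g}" for sf in cfg.subfamilies
                 for g in range(1, cfg.groups_per_subfamily + 1)]
    group_core: dict[str, np.ndarray] = {}
    group_segs: dict[str, dict[str, np.ndarray]] = {}
    for gid in group_ids:
        sf = gid.rsplit("_g", 1)[0]
        group_core[gid] = _mutate(sf_core[sf], cfg.between_group_divergence,
                                  rng, core_protect)
        group_segs[gid] = {
            s.name: _mutate(sf_segs[sf][s.name], cfg.between_group_divergence,
                            rng, seg_protect[sf][s.name])
            for s in segs if s.presence.get(gid, False)
        }

    # --- standard numbering geometry per subfamily ------------------------
    def reference_layout(sf: str):
        """Columns of the subfamily reference: core positions and segments
        present in at least one group of the subfamily."""
        own_groups = [g for g in group_ids if g.startswith(sf + "_")]
        included = [s for s in segs if any(s.presence.get(g, False) for g in own_groups)]
        core_to_std: dict[int, int] = {}
        seg_start: dict[str, int] = {}
        std = 0
        for s in included:
            if s.insert_after == 0:
                seg_start[s.name] = std + 1
                std += s.length
        for pos in range(1, L + 1):
            std += 1
            core_to_std[pos] = std
            for s in included:
                if s.insert_after == pos:
                    seg_start[s.name] = std + 1
                    std += s.length
        return included, core_to_std, seg_start, std

    layout = {sf: reference_layout(sf) for sf in cfg.subfamilies}

    def assemble(core: np.ndarray, seg_seqs: dict[str, np.ndarray],
                 included: list[Segment]) -> str:
        parts = []
        for s in included:
            if s.insert_after == 0 and s.name in seg_seqs:
                parts.append(seg_seqs[s.name])
        for pos in range(1, L + 1):
            parts.append(core[pos - 1: pos])
            for s in included:
                if s.insert_after == pos and s.name in seg_seqs:
                    parts.append(seg_seqs[s.name])
        return "".join(_AA[c] for c in np.concatenate(parts))

    def msa_row(core: np.ndarray, seg_seqs: dict[str, np.ndarray],
                included: list[Segment]) -> str:
        cols = []
        for s in included:
            if s.insert_after == 0:
                cols.append("".join(_AA[c] for c in seg_seqs[s.name])
                            if s.name in seg_seqs else "-" * s.length)
        for pos in range(1, L + 1):
            cols.append(_AA[core[pos - 1]])
            for s in included:
                if s.insert_after == pos:
                    cols.append("".join(_AA[c] for c in seg_seqs[s.name])
                                if s.name in seg_seqs else "-" * s.length)
        return "".join(cols)

    # --- members -----------------------------------------------------------
    subfamily_truth: dict[str, str] = {}
    group_truth: dict[str, str] = {}
    loop_truth: dict[str, dict[str, bool]] = {}
    seed_truth: dict[str, bool] = {}
    loop_names = [s.name for s in segs if s.name.startswith("loop")]
    n_seeds = max(1, round(cfg.fraction_seeds_per_group * cfg.sequences_per_group))

    member_data: list[tuple[str, str, bool, np.ndarray, dict]] = []
    for gid in group_ids:
        sf = gid.rsplit("_g", 1)[0]
        for i in range(1, cfg.sequences_per_group + 1):
            core = _mutate(group_core[gid], cfg.within_group_substitutions_per_site,
                           rng, core_protect)
            seg_seqs = {
                name: _mutate(arr, cfg.within_group_substitutions_per_site,
                              rng, seg_protect[sf][name])
                for name, arr in group_segs[gid].items()
            }
            sid = f"{gid}_s{i:02d}"
            is_seed = i <= n_seeds
            member_data.append((sid, sf, is_seed, core, seg_seqs))
            subfamily_truth[sid] = sf
            group_truth[sid] = gid
            loop_truth[sid] = {ln: ln in seg_seqs for ln in loop_names}
            seed_truth[sid] = is_seed

    # Polymorphic background: a non-implanted column that happens to come
    # out invariant within a subfamily would be indistinguishable from an
    # implanted one, so the generator breaks such chance invariance by
    # re-mutating the column in one member (skipped in the zero-noise limit).
    if cfg.within_group_substitutions_per_site > 0:
        for sf in cfg.subfamilies:
            own = [m for m in member_data if m[1] == sf]
            for pos in range(L):
                if core_protect[pos]:
                    continue
                residues = {m[3][pos] for m in own}
                if len(residues) == 1:
                    victim = own[rng.integers(len(own))]
                    victim[3][pos] = rng.choice(20, p=_PROPOSAL[victim[3][pos]])
            for s in segs:
                carriers = [m for m in own if s.name in m[4]]
                if len(carriers) < 2:
                    continue
                for k in range(s.length):
                    if seg_protect[sf][s.name][k]:
                        continue
                    if len({m[4][s.name][k] for m in carriers}) == 1:
                        victim = carriers[rng.integers(len(carriers))]
                        victim[4][s.name][k] = rng.choice(20, p=_PROPOSAL[victim[4][s.name][k]])

    records: list[SequenceRecord] = []
    seed_rows: dict[str, list[tuple[str, str]]] = {sf: [] for sf in cfg.subfamilies}
    for sid, sf, is_seed, core, seg_seqs in member_data:
        included = layout[sf][0]
        records.append(SequenceRecord(
            id=sid, residues=assemble(core, seg_seqs, included),
            is_seed=is_seed,
            activity_label=cfg.activities[sf] if is_seed else None,
            truth_group=group_truth[sid],
        ))
        if is_seed:
            seed_rows[sf].append((sid, msa_row(core, seg_seqs, included)))

    # --- references, seed MSAs, loop definitions ---------------------------
    references: dict[str, SequenceRecord] = {}
    loop_defs: dict[str, list[LoopDefinition]] = {}
    for sf in cfg.subfamilies:
        included, core_to_std, seg_start, ref_len = layout[sf]
        ref_segs = {s.name: sf_segs[sf][s.name] for s in included}
        ref_id = f"{sf}_ref"
        references[sf] = SequenceRecord(
            id=ref_id, residues=assemble(sf_core[sf], ref_segs, included),
            is_seed=True, activity_label=cfg.activities[sf])
        seed_rows[sf].insert(0, (ref_id, msa_row(sf_core[sf], ref_segs, included)))
        loop_defs[sf] = [
            LoopDefinition(name=s.name, start_std=seg_start[s.name],
                           end_std=seg_start[s.name] + s.length - 1,
                           reference_length=s.length)
            for s in included if s.name.startswith("loop")
        ]

    # --- correspondence and implanted-position truth ------------------------
    inc_a, core_std_a, seg_start_a, _ = layout[sf_a]
    inc_b, core_std_b, seg_start_b, _ = layout[sf_b]
    names_a = {s.name for s in inc_a}
    names_b = {s.name for s in inc_b}
    correspondence: list[tuple[int, int]] = []
    for pos in range(1, L + 1):
        correspondence.append((core_std_a[pos], core_std_b[pos]))
    for s in segs:
        if s.name in names_a and s.name in names_b:
            for k in range(s.length):
                correspondence.append((seg_start_a[s.name] + k,
                                       seg_start_b[s.name] + k))
    correspondence.sort()

    core_positions = [(core_std_a[p], core_std_b[p]) for p, _ in cfg.core_columns]
    pattern_positions: dict[str, set[int]] = {}
    for sf in cfg.subfamilies:
        core_std = layout[sf][1]
        seg_start = layout[sf][2]
        own: set[int] = set()
        for pos, _res in cfg.pattern_columns.get(sf, []):
            if isinstance(pos, tuple):
                own.add(seg_start[pos[0]] + pos[1] - 1)
            else:
                own.add(core_std[int(pos)])
        # contrasting positions fixed in the *other* subfamily are invariant
        # and zero-overlap here too, hence specific to this subfamily as well
        other = sf_b if sf == sf_a else sf_a
        for pos, _res in cfg.pattern_columns.get(other, []):
            if not isinstance(pos, tuple):
                own.add(core_std[int(pos)])
        pattern_positions[sf] = own

    group_codes = {
        gid: "".join(
            "1" if next(s for s in segs if s.name == ln).presence.get(gid, False) else "0"
            for ln in loop_names)
        for gid in group_ids
    }

    truth = TruthTable(
        subfamily=subfamily_truth, group=group_truth, loop_presence=loop_truth,
        is_seed=seed_truth, references=references, seed_msa=seed_rows,
        loop_definitions=loop_defs, correspondence=correspondence,
        core_positions=core_positions, pattern_positions=pattern_positions,
        group_loop_codes=group_codes,
    )
    return records, truth


# --------------------------------------------------------------------------
# recovery metrics


def match_labels(truth_labels: dict[str, str], inferred_labels: dict[str, str]
                 ) -> dict[str, str]:
    """Optimal one-to-one mapping from inferred label names to truth names.

    Inferred partitions carry arbitrary names (e.g. rank-based group names);
    the mapping maximizing total overlap (Hungarian assignment) aligns them
    with the truth before accuracies are computed.
    """
    t_names = sorted(set(truth_labels.values()))
    i_names = sorted(set(inferred_labels.values()))
    overlap = np.zeros((len(i_names), len(t_names)))
    for sid, t in truth_labels.items():
        inf = inferred_labels.get(sid)
        if inf is not None:
            overlap[i_names.index(inf), t_names.index(t)] += 1
    rows, cols = linear_sum_assignment(-overlap)
    return {i_names[r]: t_names[c] for r, c in zip(rows, cols) if overlap[r, c] > 0}


def label_accuracy(truth_labels: dict[str, str], inferred_labels: dict[str, str],
                   align_names: bool = False) -> float:
    """Fraction of sequences assigned their true label.

    Ids present in the truth but missing from the inference count as wrong;
    an id mismatch in the other direction is an error.
    """
    extra = set(inferred_labels) - set(truth_labels)
    if extra:
        raise ValueError(f"inferred labels for unknown ids: {sorted(extra)[:5]}")
    mapping = (match_labels(truth_labels, inferred_labels)
               if align_names else None)
    n_ok = 0
    for sid, t in truth_labels.items():
        inf = inferred_labels.get(sid)
        if inf is None:
            continue
        if mapping is not None:
            inf = mapping.get(inf, inf)
        n_ok += inf == t
    return n_ok / len(truth_labels)


def set_precision_recall(truth_set: set, inferred_set: set) -> tuple[float, float]:
    if not inferred_set:
        return (1.0 if not truth_set else 0.0, 0.0 if truth_set else 1.0)
    tp = len(truth_set & inferred_set)
    precision = tp / len(inferred_set)
    recall = tp / len(truth_set) if truth_set else 1.0
    return precision, recall


def truth_report(truth: TruthTable,
                 inferred_subfamily: dict[str, str],
                 inferred_group: dict[str, str] | None = None,
                 inferred_group_codes: dict[str, str] | None = None,
                 inferred_core: set[tuple[int, int]] | None = None,
                 inferred_patterns: dict[str, set[int]] | None = None) -> dict:
    """Score inferred labels and discovered positions against the truth."""
    report: dict = {
        "subfamily_accuracy": label_accuracy(truth.subfamily, inferred_subfamily),
    }
    if inferred_group is not None:
        report["group_accuracy"] = label_accuracy(truth.group, inferred_group,
                                                  align_names=True)
    if inferred_group_codes is not None:
        mapping = match_labels(truth.group, inferred_group or {})
        codes_ok, codes_all = 0, 0
        for inf_name, true_gid in mapping.items():
            if inf_name in inferred_group_codes:
                codes_all += 1
                codes_ok += inferred_group_codes[inf_name] == truth.group_loop_codes[true_gid]
        report["loop_code_exact_match"] = codes_ok / codes_all if codes_all else 0.0
        report["n_group_codes_compared"] = codes_all
    if inferred_core is not None:
        p, r = set_precision_recall(set(truth.core_positions), inferred_core)
        report["core_precision"], report["core_recall"] = p, r
    if inferred_patterns is not None:
        for sf, inferred in inferred_patterns.items():
            p, r = set_precision_recall(truth.pattern_positions[sf], inferred)
            report[f"pattern_precision_{sf}"] = p
            report[f"pattern_recall_{sf}"] = r
    return report
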