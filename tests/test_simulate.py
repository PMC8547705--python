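"""Synthetic family generator: determinism, structure, recovery metrics."""

import numpy as np
import pytest

from gh19net.pairwise import PairwiseScorer
from gh19net.simulate import (SimulationConfig, label_accuracy,
                              set_precision_recall, simulate_families)


def small_config(**overrides):
    defaults = dict(groups_per_subfamily=2, sequences_per_group=4)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def test_fixed_seed_is_reproducible():
    r1, t1 = simulate_families(small_config(), seed=7)
    r2, t2 = simulate_families(small_config(), seed=7)
    assert [(a.id, a.residues, a.is_seed) for a in r1] == \
        [(b.id, b.residues, b.is_seed) for b in r2]
    assert t1.to_frame().equals(t2.to_frame())
    assert t1.correspondence == t2.correspondence
    r3, _ = simulate_families(small_config(), seed=8)
    assert [a.residues for a in r1] != [b.residues for b in r3]


def test_zero_within_group_noise_gives_identical_members():
    cfg = small_config(within_group_substitutions_per_site=0.0,
                       between_group_divergence=0.2,
                       between_subfamily_divergence=0.5)
    records, truth = simulate_families(cfg, seed=1)
    by_group = {}
    for r in records:
        by_group.setdefault(truth.group[r.id], set()).add(r.residues)
    assert all(len(s) == 1 for s in by_group.values())


def test_loop_presence_bookkeeping_matches_config():
    cfg = small_config()
    records, truth = simulate_families(cfg, seed=2)
    seg_by_name = {s.name: s for s in cfg.segments}
    for r in records:
        gid = truth.group[r.id]
        for loop, present in truth.loop_presence[r.id].items():
            assert present == seg_by_name[loop].presence[gid]
    # group codes reflect the per-group flags directly
    for gid, code in truth.group_loop_codes.items():
        expected = "".join("1" if seg_by_name[f].presence[gid] else "0"
                           for f in ("loop_1", "loop_2", "loop_3",
                                     "loop_4", "loop_5", "loop_C"))
        assert code == expected


def test_seed_msa_rows_ungap_to_member_sequences():
    records, truth = simulate_families(small_config(), seed=3)
    by_id = {r.id: r for r in records}
    for sf, rows in truth.seed_msa.items():
        assert rows[0][0] == f"{sf}_ref"
        assert rows[0][1].replace("-", "") == truth.references[sf].residues
        for sid, aligned in rows[1:]:
            assert aligned.replace("-", "") == by_id[sid].residues


def test_increasing_subfamily_divergence_decreases_cross_identity():
    means = []
    scorer = PairwiseScorer()
    for d in (0.35, 0.50, 0.65):
        cfg = small_config(sequences_per_group=3, between_subfamily_divergence=d)
        records, truth = simulate_families(cfg, seed=5)
        a = [r for r in records if truth.subfamily[r.id] == "CHIT"][:4]
        b = [r for r in records if truth.subfamily[r.id] == "ELYS"][:4]
        means.append(np.mean([scorer.identity(x.residues, y.residues)
                              for x in a for y in b]))
    assert means[0] > means[1] > means[2]


def test_infeasible_configs_rejected():
    with pytest.raises(ValueError, match="ordered"):
        small_config(within_group_substitutions_per_site=0.4,
                     between_group_divergence=0.3)
    cfg = small_config()
    seg = next(s for s in cfg.segments if s.name == "loop_2")
    with pytest.raises(ValueError, match="absent"):
        small_config(pattern_columns={"CHIT": [(("loop_2", 1), "W")], "ELYS": []})
    with pytest.raises(ValueError, match="disjoint"):
        small_config(core_columns=[(30, "E")])  # collides with default pattern


def test_every_subfamily_has_a_labeled_seed():
    records, truth = simulate_families(small_config(), seed=4)
    for sf, activity in (("CHIT", "chitinase"), ("ELYS", "endolysin")):
        seeds = [r for r in records if r.is_seed and truth.subfamily[r.id] == sf]
        assert seeds and all(r.activity_label == activity for r in seeds)


def test_label_accuracy_and_set_metrics():
    truth = {f"s{i}": "g1" if i < 30 else "g2" for i in range(60)}
    perfect = dict(truth)
    assert label_accuracy(truth, perfect) == 1.0
    one_wrong = dict(truth)
    one_wrong["s0"] = "g2"
    assert label_accuracy(truth, one_wrong) == pytest.approx(59 / 60)
    renamed = {k: {"g1": "x", "g2": "y"}[v] for k, v in truth.items()}
    assert label_accuracy(truth, renamed, align_names=True) == 1.0
    nothing = {k: "unassigned" for k in truth}
    assert label_accuracy(truth, nothing) == 0.0
    with pytest.raises(ValueError, match="unknown ids"):
        label_accuracy(truth, {"zz": "g1"})

    assert set_precision_recall({1, 2, 3}, {1, 2, 3}) == (1.0, 1.0)
    p, r = set_precision_recall({1, 2, 3, 4}, {1, 2, 9})
    assert p == pytest.approx(2 / 3) and r == pytest.approx(0.5)
    assert set_precision_recall({1}, set()) == (0.0, 0.0)
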