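"""Loop annotation, binary loop codes and module presence."""

import pytest

from gh19net.loops import (GroupLoopCode, LoopAnnotation, LoopDefinition,
                           annotate_loops, chitinase_group_loop_frequencies,
                           code_from_frequencies, distinct_codes,
                           group_loop_code, module_presence_by_group,
                           read_loop_definitions, write_loop_definitions)
from gh19net.profiles import DomainHit, NumberingMap


def _map(matched_positions, seq_id="s", insertions=()):
    return NumberingMap(seq_id=seq_id,
                        matches=[(i + 1, p) for i, p in enumerate(matched_positions)],
                        insertions=list(insertions))


LOOP = LoopDefinition(name="1", start_std=10, end_std=17, reference_length=8)
FLANKS = [5, 6, 7, 8, 9] + [18, 19, 20]


def test_loop_presence_boundary_is_reference_minus_four():
    full = _map(FLANKS[:5] + list(range(10, 18)) + FLANKS[5:])
    assert annotate_loops(full, [LOOP]).status["1"] == "present"          # 8 = ref
    minus4 = _map(FLANKS[:5] + list(range(10, 14)) + FLANKS[5:])
    assert annotate_loops(minus4, [LOOP]).status["1"] == "present"        # 8 - 4
    minus5 = _map(FLANKS[:5] + list(range(10, 13)) + FLANKS[5:])
    assert annotate_loops(minus5, [LOOP]).status["1"] == "absent"         # 8 - 5
    absent = _map(FLANKS)
    assert annotate_loops(absent, [LOOP]).status["1"] == "absent"
    assert annotate_loops(absent, [LOOP]).observed_lengths["1"] == 0


def test_insertions_anchored_in_loop_count_toward_length():
    nmap = _map(FLANKS[:5] + list(range(10, 14)) + FLANKS[5:],
                insertions=[(99, 12, 1), (100, 12, 2)])
    ann = annotate_loops(nmap, [LOOP])
    assert ann.observed_lengths["1"] == 6


def test_truncated_numbering_gives_undefined_status():
    truncated = _map([12, 13, 14, 18, 19])  # nothing before the loop start
    assert annotate_loops(truncated, [LOOP]).status["1"] == "undefined"
    no_tail = _map([5, 6, 10, 11])          # nothing after the loop end
    assert annotate_loops(no_tail, [LOOP]).status["1"] == "undefined"


def test_loop_outside_profile_span_is_an_error():
    with pytest.raises(ValueError, match="outside"):
        annotate_loops(_map(FLANKS), [LOOP], profile_span=(1, 12))


def test_code_from_frequencies_thresholds():
    assert code_from_frequencies([88.2, 93.1, 88.7, 97.8, 96.7, 91.8]) == "111111"
    assert code_from_frequencies([95.4, 0, 99.8, 5.6, 0, 0]) == "101000"
    # heterogeneous group: mid-range frequencies stay undefined
    assert code_from_frequencies([17.9, 53.6, 100, 78.6, 60.7, 42.9]) == "0-11--"
    assert code_from_frequencies([65.0, 30.0, 64.9, 30.1, 0, 100]) == "10--01"


def test_group_loop_code_excludes_undefined_from_denominator():
    anns = [
        LoopAnnotation("a", {"1": 8}, {"1": "present"}),
        LoopAnnotation("b", {"1": 0}, {"1": "undefined"}),
        LoopAnnotation("c", {"1": 8}, {"1": "present"}),
    ]
    code = group_loop_code(anns, "g", loop_names=("1",))
    assert code.frequencies["1"] == pytest.approx(100.0)
    assert code.code == "1"
    with pytest.raises(ValueError, match="no annotated"):
        group_loop_code([], "g", loop_names=("1",))


def test_distinct_codes_counting():
    n, space = distinct_codes(["111111", "111111", "101000"])
    assert (n, space) == (2, 64)
    n2, _ = distinct_codes([GroupLoopCode("g", {}, "0-11--"),
                            GroupLoopCode("h", {}, "111111")])
    assert n2 == 1  # codes with '-' are not fully defined


def test_published_group_frequencies_give_at_least_eight_codes():
    df = chitinase_group_loop_frequencies()
    assert df.shape == (17, 6)
    codes = [code_from_frequencies(row.to_dict()) for _, row in df.iterrows()]
    n, space = distinct_codes(codes)
    assert space == 64
    assert n >= 8
    assert n == 9  # under the documented 65/30 thresholds


def test_loop_definitions_tsv_round_trip(tmp_path):
    defs = [LoopDefinition("1", 10, 17, 8), LoopDefinition("C-terminal", 150, 160, 11)]
    path = tmp_path / "loops.tsv"
    write_loop_definitions(defs, path)
    assert read_loop_definitions(path) == defs


def test_module_presence_by_group():
    labels = {f"s{i}": ("g1" if i < 10 else "g2") for i in range(15)}
    hits = [DomainHit(f"s{i}", "LysM", 1, 40, score=30.0, evalue=1e-8, accepted=True)
            for i in range(7)]
    hits.append(DomainHit("s1", "LysM", 50, 90, score=28.0, evalue=1e-7, accepted=True))
    hits.append(DomainHit("s12", "CBM18", 1, 40, score=3.0, evalue=0.5, accepted=False))
    table = module_presence_by_group(hits, labels)
    assert table.loc["g1", "LysM"] == pytest.approx(0.7)
    assert table.loc["g2", "LysM"] == 0.0
    assert (table["CBM18"] == 0.0).all()  # rejected hits never count
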