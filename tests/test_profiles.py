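"""Profile building, standard-numbering transfer and domain scanning."""

import numpy as np
import pytest

from gh19net.profiles import (align_to_profile, build_profile, filter_hits,
                              DomainHit, scan_sequence)
from gh19net.records import SequenceRecord
from gh19net.simulate import SimulationConfig, simulate_families

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="module")
def chit_profile():
    _, truth = simulate_families(SimulationConfig(), seed=1)
    prof = build_profile(truth.seed_msa["CHIT"], reference_id="CHIT_ref",
                         profile_id="CHIT")
    return prof, truth.references["CHIT"]


def test_single_sequence_profile_numbers_every_column():
    ref = "".join(np.random.default_rng(0).choice(list(AA), 200))
    prof = build_profile([("ref", ref)], reference_id="ref")
    assert len(prof.match_columns) == 200
    assert prof.standard_positions == list(range(1, 201))


def test_reference_gap_column_is_unnumbered():
    msa = [("ref", "ACD-FG"), ("other", "ACDEFG")]
    prof = build_profile(msa, reference_id="ref")
    assert [c.standard_position for c in prof.columns] == [1, 2, 3, None, 4, 5]


def test_reference_span_offset():
    # numbering may start past an excluded N-terminal signal peptide,
    # e.g. a 243-column profile spanning reference positions 24..266
    ref = "".join(np.random.default_rng(1).choice(list(AA), 243))
    prof = build_profile([("ref", ref)], reference_id="ref", reference_start=24)
    assert len(prof.match_columns) == 243
    assert prof.standard_positions[0] == 24
    assert prof.standard_positions[-1] == 266


def test_missing_reference_is_an_error():
    with pytest.raises(ValueError, match="absent"):
        build_profile([("a", "ACDEF")], reference_id="ref")


def test_reference_maps_to_itself_exactly(chit_profile):
    prof, ref = chit_profile
    nmap = align_to_profile(ref, prof)
    assert nmap.matches == [(i, i) for i in range(1, len(ref.residues) + 1)]
    assert nmap.insertions == []


@pytest.mark.parametrize("k", list(range(1, 21)))
def test_nterminal_extension_shifts_indices_not_positions(k, chit_profile):
    prof, ref = chit_profile
    extended = SequenceRecord(id="ext", residues="M" * k + ref.residues)
    nmap = align_to_profile(extended, prof)
    assert [(i - k, s) for i, s in nmap.matches] == \
        [(i, i) for i in range(1, len(ref.residues) + 1)]
    # the added flank is recorded as insertions before the first position
    flank = [ins for ins in nmap.insertions if ins[0] <= k]
    assert [(idx, anchor) for idx, anchor, _ in flank] == [(i, 0) for i in range(1, k + 1)]


def test_internal_deletion_omits_those_positions(chit_profile):
    prof, ref = chit_profile
    deleted = ref.residues[:99] + ref.residues[110:]  # drop positions 100..110
    nmap = align_to_profile(SequenceRecord(id="del", residues=deleted), prof)
    expected = [(i, i) for i in range(1, 100)] + \
        [(i - 11, i) for i in range(111, len(ref.residues) + 1)]
    assert nmap.matches == expected


def test_insertion_labels_use_anchor_plus_rank():
    from gh19net.profiles import NumberingMap

    nmap = NumberingMap(seq_id="s", matches=[(1, 102)],
                        insertions=[(2, 102, 1), (3, 102, 2)])
    assert nmap.insertion_labels() == [(2, "102a"), (3, "102b")]


def test_scan_reference_is_highly_significant(chit_profile):
    prof, ref = chit_profile
    hit = scan_sequence(ref, prof, n_shuffles=100, seed=0)
    assert hit.evalue < 1e-5
    assert hit.start == 1 and hit.end == len(ref.residues)
    filter_hits([hit])
    assert hit.accepted


def test_scan_shuffled_query_is_rejected(chit_profile):
    prof, ref = chit_profile
    rng = np.random.default_rng(3)
    shuffled = "".join(rng.permutation(list(ref.residues)))
    hit = scan_sequence(SequenceRecord(id="shuf", residues=shuffled), prof,
                        n_shuffles=100, seed=1)
    filter_hits([hit])
    assert not hit.accepted


def test_scan_locates_embedded_domain(chit_profile):
    prof, ref = chit_profile
    rng = np.random.default_rng(7)
    left = "".join(rng.choice(list(AA), 100))
    right = "".join(rng.choice(list(AA), 100))
    query = SequenceRecord(id="embedded", residues=left + ref.residues + right)
    hit = scan_sequence(query, prof, n_shuffles=100, seed=2)
    assert abs(hit.start - 101) <= 5
    assert abs(hit.end - (100 + len(ref.residues))) <= 5


def test_filter_hits_predicates():
    ok = DomainHit("s", "p", 1, 150, score=50.0, bias=2.5, evalue=1e-6)
    short = DomainHit("s", "p", 1, 119, score=50.0, bias=2.5, evalue=1e-6)
    weak = DomainHit("s", "p", 1, 150, score=50.0, bias=2.5, evalue=1e-3)
    biased = DomainHit("s", "p", 1, 150, score=50.0, bias=10.0, evalue=1e-6)
    undefined = DomainHit("s", "p", 1, 150, score=-1.0, bias=2.0, evalue=1e-6)
    filter_hits([ok, short, weak, biased, undefined])
    assert ok.accepted and ok.rejection_reason is None
    assert (not short.accepted) and short.rejection_reason == "min_len"
    assert (not weak.accepted) and weak.rejection_reason == "max_evalue"
    assert (not biased.accepted) and biased.rejection_reason == "max_bias_ratio"
    assert (not undefined.accepted) and undefined.rejection_reason == "undefined bias ratio"

    # accessory-module preset: shorter hits and high bias tolerated
    accessory = DomainHit("s", "cbm", 1, 25, score=30.0, bias=15.0, evalue=1e-6)
    filter_hits([accessory], max_evalue=1e-5, min_len=20, max_bias_ratio=1.0)
    assert accessory.accepted


def test_numbering_map_monotonicity_enforced():
    from gh19net.profiles import NumberingMap

    with pytest.raises(ValueError, match="strictly increasing"):
        NumberingMap(seq_id="s", matches=[(1, 10), (2, 9)])
    with pytest.raises(ValueError, match="strictly increasing"):
        NumberingMap(seq_id="s", matches=[(3, 10), (2, 12)])
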