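"""Conservation categories, shared core and subfamily-specific patterns."""

import numpy as np
import pandas as pd
import pytest

from gh19net.conservation import (ConservationProfile, conservation_scores,
                                  frequency_overlap, read_rate_file,
                                  region_conservation, shared_core,
                                  specific_patterns)

AA = "ACDEFGHIKLMNPQRSTVWY"


def _msa(columns: dict[int, list[str]]) -> pd.DataFrame:
    n = len(next(iter(columns.values())))
    return pd.DataFrame(columns, index=[f"s{i}" for i in range(n)])


def test_invariant_column_most_conserved_uniform_least():
    rng = np.random.default_rng(0)
    n = 20
    cols = {1: ["W"] * n,                       # invariant
            2: list(AA),                         # uniform
            3: [AA[i % 3] for i in range(n)],    # moderately variable
            4: list(rng.choice(list(AA), n)),
            5: ["G"] * 18 + ["A", "S"]}
    prof = conservation_scores(_msa(cols))
    assert prof.scores[1] == 5
    assert prof.scores[2] < prof.scores[1]
    assert prof.scores[2] == 1
    assert prof.rates[1] == 0.0


def test_gap_majority_rule_forces_score_1():
    n = 20
    cols = {1: ["W"] * 8 + ["-"] * 12,   # 60% gaps, residues invariant
            2: ["W"] * n,
            3: list(AA),
            4: ["D"] * n,
            5: list(reversed(AA))}
    prof = conservation_scores(_msa(cols))
    assert prof.scores[1] == 1
    assert prof.gap_fractions[1] == pytest.approx(0.6)
    assert prof.scores[2] == 5


def test_scores_invariant_to_sequence_order():
    rng = np.random.default_rng(1)
    df = _msa({p: list(rng.choice(list(AA), 12)) for p in range(1, 9)})
    prof1 = conservation_scores(df)
    prof2 = conservation_scores(df.sample(frac=1.0, random_state=3))
    assert prof1.scores == prof2.scores


def test_too_few_sequences_rejected():
    with pytest.raises(ValueError, match="at least 5"):
        conservation_scores(_msa({1: ["A"] * 4}))


def test_external_rates_are_a_drop_in(tmp_path):
    df = _msa({1: ["W"] * 10, 2: list(AA)[:10], 3: ["D"] * 10,
               4: ["A", "C"] * 5, 5: ["E"] * 10})
    path = tmp_path / "rates.txt"
    path.write_text("# per-site output\n1 W 0.01\n2 A 2.5\n3 D 0.02\n4 A 1.0\n5 E 0.03\n")
    rates = read_rate_file(path)
    assert rates[2] == 2.5
    prof = conservation_scores(df, rates=rates)
    assert prof.scores[2] == 1 and prof.scores[1] == 5


def _profile(data: dict[int, tuple[int, float, dict[str, float]]]) -> ConservationProfile:
    return ConservationProfile(
        positions=list(data),
        scores={p: v[0] for p, v in data.items()},
        gap_fractions={p: v[1] for p, v in data.items()},
        frequencies={p: v[2] for p, v in data.items()},
    )


def test_shared_core_identity_case_and_exclusions():
    a = _profile({
        1: (5, 0.0, {"E": 0.95, "D": 0.05}),
        2: (5, 0.0, {"G": 1.0}),
        3: (4, 0.0, {"S": 1.0}),          # below score threshold
        4: (5, 0.15, {"N": 1.0}),          # too many gaps
        5: (5, 0.0, {"C": 0.96, "W": 0.04}),
    })
    b = _profile({
        1: (5, 0.0, {"E": 0.9, "Q": 0.1}),
        2: (5, 0.05, {"G": 0.98, "A": 0.02}),
        3: (5, 0.0, {"S": 1.0}),
        4: (5, 0.0, {"N": 1.0}),
        5: (5, 0.0, {"I": 0.96, "W": 0.04}),  # only residue in common at 4%
    })
    corr = [(p, p) for p in range(1, 6)]
    result = shared_core(a, b, corr)
    assert [(s.position_a, s.position_b) for s in result] == [(1, 1), (2, 2)]
    assert result[0].common_residues == ["E"]


def test_specific_patterns_rules():
    a = _profile({
        1: (5, 0.0, {"C": 0.93, "S": 0.07}),   # aligned, disjoint residues
        2: (5, 0.0, {"A": 0.8, "G": 0.2}),     # aligned, shared A
        3: (5, 0.0, {"W": 1.0}),                # no correspondence partner
        4: (3, 0.0, {"Y": 1.0}),                # not conserved enough
    })
    b = _profile({
        1: (5, 0.0, {"I": 0.8, "V": 0.2}),
        2: (5, 0.0, {"A": 0.9, "S": 0.1}),
    })
    corr = [(1, 1), (2, 2)]
    pats = specific_patterns(a, b, corr, names=("A", "B"))
    assert [p.position for p in pats["A"]] == [1, 3]
    assert [p.position for p in pats["B"]] == [1]
    assert not any(p.position == 2 for p in pats["A"])  # 80%/90% shared A


def test_frequency_overlap_is_min_sum():
    assert frequency_overlap({"A": 0.8, "C": 0.2}, {"A": 0.1, "W": 0.9}) == \
        pytest.approx(0.1)
    assert frequency_overlap({"A": 1.0}, {"C": 1.0}) == 0.0


def test_region_conservation_mean():
    prof = _profile({p: (s, 0.0, {"A": 1.0})
                     for p, s in zip(range(1, 5), (1, 2, 2, 2))})
    assert region_conservation(prof, 1, 4) == pytest.approx(1.75)
    all5 = _profile({p: (5, 0.0, {"A": 1.0}) for p in range(1, 4)})
    assert region_conservation(all5, 1, 3) == 5.0
    with pytest.raises(ValueError, match="no numbered positions"):
        region_conservation(prof, 50, 60)
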