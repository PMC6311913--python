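import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

import stemloop as sl
from stemloop.profile_features import (
    PROFILE_FEATURE_NAMES,
    consensus_kmers,
    efm,
    gc_content,
    nccs_and_ecs,
    pseudo_pssm,
)


def one_hot_pssm(seq: str, match: int = 5, mismatch: int = -5) -> sl.PSSM:
    return pseudo_pssm(sl.RnaRecord("t", seq), match, mismatch)


def fm_from_rows(rows) -> "sl.profile_features.FrequencyMatrix":
    from stemloop.profile_features import FrequencyMatrix

    return FrequencyMatrix(np.asarray(rows, dtype=float))


@pytest.mark.parametrize(
    "score,expected", [(0, 1.0), (10, 2.0), (-10, 0.5), (20, 4.0), (-20, 0.25)]
)
def test_score_transform_spot_values(score, expected):
    pssm = sl.PSSM(np.full((4, 5), score, dtype=np.int64), sl.RnaRecord("t", "ACGU"))
    assert sl.transform_scores(pssm) == pytest.approx(np.full((4, 5), expected))


def test_row_normalisation():
    t = np.array([[1, 1, 1, 1, 1], [2, 1, 1, 1, 1]], dtype=float)
    fm = sl.to_frequency_matrix(t)
    assert fm.values[0] == pytest.approx([0.2] * 5)
    assert fm.values[1] == pytest.approx([1 / 3, 1 / 6, 1 / 6, 1 / 6, 1 / 6])
    assert fm.values.sum(axis=1) == pytest.approx([1.0, 1.0])


class TestConsensus:
    def test_clear_winner(self):
        fm = fm_from_rows([[0.7, 0.1, 0.1, 0.05, 0.05]])
        assert sl.consensus(fm) == "A"

    def test_gap_column_never_wins(self):
        fm = fm_from_rows([[0.1, 0.1, 0.1, 0.1, 0.6]])
        assert sl.consensus(fm) == "A"  # 4-way tie among nucleotides -> A

    @pytest.mark.parametrize(
        "tied,expected",
        [((0, 1), "A"), ((1, 2), "C"), ((2, 3), "G"), ((0, 3), "A"), ((1, 3), "C")],
    )
    def test_tie_breaks_to_lowest_alphabet_index(self, tied, expected):
        row = [0.1, 0.1, 0.1, 0.1, 0.0]
        for j in tied:
            row[j] = 0.35
        fm = fm_from_rows([np.array(row) / sum(row)])
        assert sl.consensus(fm) == expected

    def test_one_hot_profile_recovers_sequence(self):
        fm = sl.to_frequency_matrix(sl.transform_scores(one_hot_pssm("GACU")))
        assert sl.consensus(fm) == "GACU"


class TestCompositionEntropies:
    def test_uniform_composition(self):
        nccs, ecs = nccs_and_ecs("ACGU")
        assert nccs == pytest.approx([0.25] * 4)
        assert ecs == pytest.approx(math.log(4))

    def test_degenerate_composition(self):
        nccs, ecs = nccs_and_ecs("AAAA")
        assert nccs == pytest.approx([1, 0, 0, 0])
        assert ecs == 0.0

    def test_mixed_composition_matches_hand_value(self):
        _, ecs = nccs_and_ecs("AACG")
        expected = -(0.5 * math.log(0.5) + 2 * 0.25 * math.log(0.25))
        assert ecs == pytest.approx(expected)
        assert ecs == pytest.approx(1.039721, abs=1e-6)

    def test_efm_uniform_rows(self):
        fm = fm_from_rows([[0.2] * 5, [0.2] * 5])
        assert efm(fm) == pytest.approx(math.log(5))

    def test_efm_one_hot_rows_is_zero(self):
        fm = fm_from_rows([[1, 0, 0, 0, 0], [0, 0, 1, 0, 0]])
        assert efm(fm) == 0.0

    def test_efm_mixed_rows_matches_hand_value(self):
        fm = fm_from_rows([[0.5, 0.5, 0, 0, 0], [0.2] * 5])
        assert efm(fm) == pytest.approx((math.log(2) + math.log(5)) / 2)
        assert efm(fm) == pytest.approx(1.151293, abs=1e-6)


def kmer_oracle(s: str, k: int) -> dict[str, float]:
    """Direct window enumeration, independent of the indexing arithmetic."""
    counts = {"".join(p): 0 for p in itertools.product("ACGU", repeat=k)}
    for i in range(len(s) - k + 1):
        counts[s[i : i + k]] += 1
    total = len(s) - k + 1
    return {km: c / total for km, c in counts.items()}


class TestConsensusKmers:
    def test_homopolymer(self):
        v = consensus_kmers("AAAA")
        assert v[0] == 1.0 and v[1:16].sum() == 0  # dimer AA only
        assert v[16] == 1.0 and v[17:].sum() == 0  # trimer AAA only

    def test_acgu_dimers(self):
        v = consensus_kmers("ACGU")
        dimers = dict(zip([n.split(".")[-1] for n in PROFILE_FEATURE_NAMES[6:22]], v[:16]))
        assert dimers["AC"] == pytest.approx(1 / 3)
        assert dimers["CG"] == pytest.approx(1 / 3)
        assert dimers["GU"] == pytest.approx(1 / 3)

    def test_alternating_case_matches_hand_values(self):
        v = consensus_kmers("ACAC")
        dimer_names = [n.split(".")[-1] for n in PROFILE_FEATURE_NAMES[6:22]]
        trimer_names = [n.split(".")[-1] for n in PROFILE_FEATURE_NAMES[22:86]]
        dimers = dict(zip(dimer_names, v[:16]))
        trimers = dict(zip(trimer_names, v[16:]))
        assert dimers["AC"] == pytest.approx(2 / 3)
        assert dimers["CA"] == pytest.approx(1 / 3)
        assert trimers["ACA"] == pytest.approx(0.5)
        assert trimers["CAC"] == pytest.approx(0.5)

    @given(s=st.text(alphabet="ACGU", min_size=3, max_size=50))
    def test_matches_window_enumeration_oracle(self, s):
        v = consensus_kmers(s)
        d2 = kmer_oracle(s, 2)
        d3 = kmer_oracle(s, 3)
        names2 = [n.split(".")[-1] for n in PROFILE_FEATURE_NAMES[6:22]]
        names3 = [n.split(".")[-1] for n in PROFILE_FEATURE_NAMES[22:86]]
        assert v[:16] == pytest.approx([d2[k] for k in names2])
        assert v[16:] == pytest.approx([d3[k] for k in names3])
        assert v[:16].sum() == pytest.approx(1.0)
        assert v[16:].sum() == pytest.approx(1.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            consensus_kmers("AC")


@pytest.mark.parametrize("cs,expected", [("GGCC", 1.0), ("AAUU", 0.0), ("GACU", 0.5)])
def test_gc_content(cs, expected):
    assert gc_content(cs) == expected


class TestProfileBlock:
    def test_has_87_features_in_frozen_layout(self):
        block = sl.profile_block(one_hot_pssm("ACGUACGU"))
        assert block.shape == (87,)
        assert len(PROFILE_FEATURE_NAMES) == 87
        assert len(set(PROFILE_FEATURE_NAMES)) == 87
        assert PROFILE_FEATURE_NAMES[0] == "psi.nccs.A"
        assert PROFILE_FEATURE_NAMES[4] == "psi.ecs"
        assert PROFILE_FEATURE_NAMES[5] == "psi.efm"
        assert PROFILE_FEATURE_NAMES[6] == "psi.dimer.AA"
        assert PROFILE_FEATURE_NAMES[22] == "psi.trimer.AAA"
        assert PROFILE_FEATURE_NAMES[86] == "psi.gc"

    def test_one_hot_composition_case(self):
        block = sl.profile_block(one_hot_pssm("ACGU"))
        assert block[:4] == pytest.approx([0.25] * 4)  # NCCS uniform
        assert block[4] == pytest.approx(math.log(4))  # ECS
        # EFM small but nonzero: the one-hot profile is exponentiated, not exact
        assert 0 <= block[5] < math.log(5)

    @given(
        scores=hnp.arrays(np.int64, (8, 5), elements=st.integers(-12, 12)),
        shift=st.integers(-7, 7),
    )
    def test_shift_invariance(self, scores, shift):
        seq = sl.RnaRecord("t", "ACGUACGU")
        a = sl.profile_block(sl.PSSM(scores, seq))
        b = sl.profile_block(sl.PSSM(scores + shift, seq))
        assert a == pytest.approx(b, abs=1e-12)

    def test_entropy_bounds(self, rng):
        for _ in range(20):
            scores = rng.integers(-10, 10, size=(12, 5))
            block = sl.profile_block(sl.PSSM(scores, sl.RnaRecord("t", "ACGUACGUACGU")))
            assert 0 <= block[4] <= math.log(4) + 1e-12
            assert 0 <= block[5] <= math.log(5) + 1e-12
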