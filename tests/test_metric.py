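"""TCRdist metric: residue costs, gapped loop alignment, scalar vs batch."""
import dataclasses
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cetfinder import (Clonotype, CdrProfile, Repertoire, TcrdistParams,
                       aa_distance, cdr_distance, pairwise_matrix, tcrdist,
                       trim_cdr3)
from cetfinder.metric import AA_ALPHABET

PARAMS = TcrdistParams()
AA = st.sampled_from(AA_ALPHABET)


@pytest.mark.parametrize("a,b,expected", [
    ("A", "A", 0),        # identity
    ("I", "L", 2),        # BLOSUM62 S=2 -> min(4, 4-2)
    ("W", "G", 4),        # S=-2 -> capped at 4
    ("S", "T", 3),        # S=1 -> 3
    ("W", "W", 0),        # high self-score clamps to 0, not negative
])
def test_aa_distance_values(a, b, expected):
    assert aa_distance(a, b, PARAMS) == expected


@given(a=AA, b=AA)
@settings(deadline=None)
def test_aa_distance_symmetric_and_bounded(a, b):
    d = aa_distance(a, b, PARAMS)
    assert d == aa_distance(b, a, PARAMS)
    assert 0 <= d <= PARAMS.mismatch_cap
    if a == b:
        assert d == 0


def test_aa_distance_nonstandard():
    with pytest.raises(ValueError):
        aa_distance("A", "X", PARAMS)
    lenient = dataclasses.replace(PARAMS, on_nonstandard="max")
    assert aa_distance("A", "X", lenient) == PARAMS.mismatch_cap


@pytest.mark.parametrize("s1,s2,weight,expected", [
    ("CASS", "CASS", 1, 0),
    ("SS", "ST", 1, 3),
    ("AAA", "AAAA", 1, 4),     # 3 matches + 1 gap position
    ("CASS", "CASS", 3, 0),
    ("SS", "ST", 3, 9),        # weight multiplies the total
    ("", "", 1, 0),
    ("", "AA", 1, 8),          # all-gap alignment
])
def test_cdr_distance_examples(s1, s2, weight, expected):
    assert cdr_distance(s1, s2, weight, PARAMS) == expected


def _gap_oracle(short, long, params):
    """Exhaustive enumeration of every single-gap placement."""
    dlen = len(long) - len(short)
    best = None
    for g in range(len(short) + 1):
        cost = dlen * params.gap_penalty
        for p in range(g):
            cost += aa_distance(short[p], long[p], params)
        for p in range(g, len(short)):
            cost += aa_distance(short[p], long[p + dlen], params)
        best = cost if best is None else min(best, cost)
    return best


@given(st.text(AA_ALPHABET, min_size=0, max_size=8),
       st.text(AA_ALPHABET, min_size=0, max_size=12))
@settings(deadline=None, max_examples=200)
def test_gapped_alignment_matches_enumeration(s1, s2):
    short, long = sorted((s1, s2), key=len)
    assert cdr_distance(s1, s2, 1, PARAMS) == _gap_oracle(short, long, PARAMS)
    assert cdr_distance(s1, s2, 1, PARAMS) == cdr_distance(s2, s1, 1, PARAMS)


def test_trim_cdr3():
    assert trim_cdr3("CASSLGQAYEQYF", PARAMS) == "SLGQAYEQ"
    assert trim_cdr3("CASSF", PARAMS) == ""
    assert trim_cdr3("CAF", PARAMS) == ""


def _clonotype(v_call, cdr3_aa, chain="beta", j_call="TRBJ2-7"):
    nt = "".join({"A": "GCT", "C": "TGC", "S": "AGC", "F": "TTC", "I": "ATT",
                  "L": "CTG", "Q": "CAG", "Y": "TAC", "E": "GAA", "G": "GGT",
                  "R": "CGT", "T": "ACC", "W": "TGG", "N": "AAT"}[a]
                 for a in cdr3_aa)
    return Clonotype(chain=chain, v_call=v_call, j_call=j_call, cdr3_nt=nt,
                     cdr3_aa=cdr3_aa, count=1, frequency=0.5)


class TestTcrdist:
    def test_identical_profiles_zero(self, cdr_table):
        a = _clonotype("TRBV19", "CASSIRSSYEQYF")
        b = _clonotype("TRBV19", "CASSIRSSYEQYF", j_call="TRBJ2-1")
        # distance ignores J; identical V profile + junction -> 0
        assert tcrdist(a, b, cdr_table, PARAMS) == 0

    def test_single_trimmed_il_substitution_costs_six(self, cdr_table):
        a = _clonotype("TRBV19", "CASSIRSSYEQYF")
        b = _clonotype("TRBV19", "CASSLRSSYEQYF")
        assert tcrdist(a, b, cdr_table, PARAMS) == 6  # cost 2 x CDR3 weight 3

    def test_distant_pair_exceeds_100(self, cdr_table):
        a = _clonotype("TRBV19", "CASSIRSSYEQYF")
        b = _clonotype("TRBV2", "CAWWWWWGGGNTEAFF")
        assert tcrdist(a, b, cdr_table, PARAMS) > 100

    def test_identity_iff_profiles_match(self, cdr_table, small_background):
        rep, _ = small_background
        params = PARAMS
        for a, b in itertools.islice(itertools.combinations(rep, 2), 150):
            d = tcrdist(a, b, cdr_table, params)
            same = (CdrProfile.from_clonotype(a, cdr_table, params)
                    == CdrProfile.from_clonotype(b, cdr_table, params))
            assert (d == 0) == same

    def test_symmetry(self, cdr_table, small_background):
        rep, _ = small_background
        rng = np.random.default_rng(0)
        for _ in range(50):
            i, j = rng.integers(len(rep), size=2)
            assert (tcrdist(rep[i], rep[j], cdr_table, PARAMS)
                    == tcrdist(rep[j], rep[i], cdr_table, PARAMS))

    def test_extra_mismatch_never_decreases(self, cdr_table):
        base = "CASSIRSSYEQYF"
        prev = 0
        mutated = base
        for pos, sub in [(5, "W"), (6, "W"), (7, "W")]:
            mutated = mutated[:pos] + sub + mutated[pos + 1:]
            d = tcrdist(_clonotype("TRBV19", base),
                        _clonotype("TRBV19", mutated), cdr_table, PARAMS)
            assert d >= prev
            prev = d

    def test_chain_mismatch_raises(self, cdr_table):
        a = _clonotype("TRBV19", "CASSIRSSYEQYF")
        b = _clonotype("TRAV27", "CAGGSQGNLIF", chain="alpha", j_call="TRAJ42")
        with pytest.raises(ValueError, match="chain"):
            tcrdist(a, b, cdr_table, PARAMS)

    def test_missing_germline_raises(self, cdr_table):
        a = _clonotype("TRBV999", "CASSIRSSYEQYF")
        with pytest.raises(KeyError, match="TRBV999"):
            tcrdist(a, a, cdr_table, PARAMS)


class TestPairwiseMatrix:
    def test_singleton(self, cdr_table):
        rep = Repertoire.build([_clonotype("TRBV19", "CASSIRSSYEQYF")],
                               renormalize=False)
        m = pairwise_matrix(rep, cdr_table)
        assert m.values.shape == (1, 1) and m.values[0, 0] == 0

    def test_matches_scalar_oracle(self, cdr_table, small_background):
        """Batched kernel is integer-exact against the scalar implementation."""
        rep, _ = small_background
        rep50 = Repertoire(sample_id="x", clonotypes=rep.clonotypes[:50])
        m = pairwise_matrix(rep50, cdr_table)
        for i in range(50):
            for j in range(50):
                assert m.values[i, j] == tcrdist(rep50[i], rep50[j],
                                                 cdr_table, PARAMS)

    def test_symmetric_zero_diag(self, cdr_table, small_background):
        rep, _ = small_background
        m = pairwise_matrix(rep, cdr_table)
        assert (m.values == m.values.T).all()
        assert (np.diag(m.values) == 0).all()
        assert (m.values >= 0).all()

    def test_mixed_chain_rejected(self, cdr_table):
        a = _clonotype("TRBV19", "CASSIRSSYEQYF")
        b = _clonotype("TRAV27", "CAGGSQGNLIF", chain="alpha", j_call="TRAJ42")
        rep = Repertoire(sample_id="x", clonotypes=(a, b))
        with pytest.raises(ValueError, match="chain"):
            pairwise_matrix(rep, cdr_table)
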