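"""Master-list aggregation, reclustering, enrichment, deep queries."""
import numpy as np
import pandas as pd
import pytest

from cetfinder import (ConditionMatrix, Repertoire, build_condition_matrix,
                       build_master, consensus_cdr3, fold_enrichment,
                       geometric_mean, query_deep, recluster_master,
                       resample_culture)
from cetfinder.significance import Cet


def _cet(members, cet_id, threshold=25, sample_id="s1"):
    freqs = [m.frequency for m in members]
    return Cet(cet_id=cet_id, threshold=threshold, members=tuple(members),
               n_members=len(members), geo_mean_freq=geometric_mean(freqs),
               p_value=0.001, n_exceed=1, n_trials=1000, significant=True,
               sample_id=sample_id, condition="Ag+")


class TestBuildMaster:
    def test_shared_members_deduplicated(self, small_background):
        rep, _ = small_background
        a = _cet(list(rep.clonotypes[:4]), "a")
        b = _cet(list(rep.clonotypes[2:6]), "b", threshold=50)
        master = build_master([a, b])
        assert len(master) == 6  # union, not 8
        key = rep.clonotypes[2].key
        assert {p[2] for p in master.provenance[key]} == {"a", "b"}

    def test_empty(self):
        assert len(build_master([])) == 0

    def test_union_covers_every_significant_member(self, small_background):
        rep, _ = small_background
        cets = [_cet(list(rep.clonotypes[i:i + 3]), f"c{i}")
                for i in range(0, 9, 3)]
        master = build_master(cets)
        keys = set(master.keys())
        for cet in cets:
            assert set(cet.member_keys) <= keys


class TestReclusterMaster:
    def test_conserves_clonotypes(self, small_background, cdr_table):
        rep, _ = small_background
        master = build_master([_cet(list(rep.clonotypes[:10]), "a")])
        final = recluster_master(master, 50, cdr_table)
        regrouped = sorted(k for c in final for k in c.member_keys)
        assert regrouped == sorted(master.keys())

    def test_two_distant_families_stay_apart(self, cdr_table):
        from cetfinder import SpikeSpec, make_background, spike_families

        bg, _ = make_background(30, chain="beta", seed=31)
        spec = SpikeSpec(n_families=2, members_per_family=4, cdr3_divergence=1)
        spiked, truth = spike_families(bg, spec, seed=32)
        by_key = {c.key: c for c in spiked}
        fams = {f: [by_key[k] for k in zip(g.v_call, g.j_call, g.cdr3_nt)]
                for f, g in truth.groupby("family_id")}
        master = build_master([_cet(m, f) for f, m in fams.items()])
        final = recluster_master(master, 50, cdr_table)
        # every final CET is pure: no mixing across distant families
        truth_of = {k: f for f, ms in fams.items() for k in (c.key for c in ms)}
        for cet in final:
            assert len({truth_of[k] for k in cet.member_keys}) == 1

    def test_idempotent_on_own_output(self, small_background, cdr_table):
        rep, _ = small_background
        master = build_master([_cet(list(rep.clonotypes[:12]), "a")])
        final1 = recluster_master(master, 50, cdr_table)
        master2 = build_master(final1)
        final2 = recluster_master(master2, 50, cdr_table)
        assert sorted(tuple(sorted(c.member_keys)) for c in final1) \
            == sorted(tuple(sorted(c.member_keys)) for c in final2)


def _cond_matrix(keys, ag_plus, ag_minus, totals=(10**6, 10**6)):
    df = pd.DataFrame({"agp": ag_plus, "agm": ag_minus},
                      index=pd.Index(keys, dtype=object, tupleize_cols=False,
                                     name="clonotype"))
    return ConditionMatrix(frequencies=df,
                           condition_of={"agp": "Ag+", "agm": "Ag-"},
                           total_reads={"agp": totals[0], "agm": totals[1]})


def _stub_cet(keys):
    from cetfinder.repertoire import Clonotype

    members = tuple(Clonotype(chain="beta", v_call=v, j_call=j, cdr3_nt=nt,
                              cdr3_aa="CASSF", count=1, frequency=1e-3)
                    for v, j, nt in keys)
    return Cet(cet_id="x", threshold=50, members=members,
               n_members=len(members), geo_mean_freq=1e-3, p_value=0.001,
               n_exceed=1, n_trials=1000, significant=True)


class TestFoldEnrichment:
    KEYS = [("TRBV19", "TRBJ2-7", "AAA"), ("TRBV19", "TRBJ2-7", "AAC")]

    def test_simple_ratio(self):
        cond = _cond_matrix(self.KEYS, [1e-3, 1e-3], [1e-5, 1e-5])
        folds = fold_enrichment(_stub_cet(self.KEYS), cond, "Ag-")
        assert folds["Ag+"] == pytest.approx(100.0)
        assert folds["Ag-"] == pytest.approx(1.0)

    def test_floor_for_undetected_reference(self):
        cond = _cond_matrix(self.KEYS[:1], [1e-3], [0.0])
        folds = fold_enrichment(_stub_cet(self.KEYS[:1]), cond, "Ag-",
                                floor=1e-6)
        assert folds["Ag+"] == pytest.approx(1000.0)

    def test_default_floor_is_reference_detection_limit(self):
        cond = _cond_matrix(self.KEYS[:1], [1e-3], [0.0], totals=(10**6, 10**6))
        folds = fold_enrichment(_stub_cet(self.KEYS[:1]), cond, "Ag-")
        assert folds["Ag+"] == pytest.approx(1e-3 / 1e-6)

    def test_cet_average_is_geometric(self):
        # member folds {100, 10000} -> average 1000
        cond = _cond_matrix(self.KEYS, [1e-3, 1e-1], [1e-5, 1e-5])
        folds = fold_enrichment(_stub_cet(self.KEYS), cond, "Ag-")
        assert folds["Ag+"] == pytest.approx(1000.0)

    def test_scale_invariance(self):
        cond1 = _cond_matrix(self.KEYS, [1e-3, 2e-3], [1e-5, 4e-5])
        cond2 = _cond_matrix(self.KEYS, [3e-3, 6e-3], [3e-5, 12e-5])
        f1 = fold_enrichment(_stub_cet(self.KEYS), cond1, "Ag-", floor=1e-9)
        f2 = fold_enrichment(_stub_cet(self.KEYS), cond2, "Ag-", floor=1e-9)
        assert f1["Ag+"] == pytest.approx(f2["Ag+"])

    def test_unknown_reference(self):
        cond = _cond_matrix(self.KEYS, [1e-3, 1e-3], [1e-5, 1e-5])
        with pytest.raises(ValueError, match="reference"):
            fold_enrichment(_stub_cet(self.KEYS), cond, "nope")


class TestQueryDeep:
    def test_match_and_miss(self, small_background):
        rep, _ = small_background
        members = list(rep.clonotypes[:5])
        deep = Repertoire.build(rep.clonotypes[2:], sample_id="deep",
                                renormalize=True)
        df = query_deep(members, deep)
        assert len(df) == 5
        found = df[df.found]
        lookup = {c.key: c.frequency for c in deep}
        for row in found.itertuples():
            assert row.frequency == lookup[(row.v_call, row.j_call, row.cdr3_nt)]
        missed = df[~df.found]
        assert (missed.frequency == 0).all()

    def test_reported_frequencies_exist_in_deep_table(self, small_background,
                                                      rng):
        rep, _ = small_background
        deep = resample_culture(rep, 500, rng, "deep")
        df = query_deep(list(rep.clonotypes), deep)
        deep_freqs = {c.frequency for c in deep}
        assert set(df[df.found].frequency) <= deep_freqs

    def test_independent_match_sets(self, small_background, rng):
        rep, _ = small_background
        d1 = resample_culture(rep, 300, rng, "d1")
        d2 = resample_culture(rep, 300, rng, "d2")
        members = list(rep.clonotypes[:20])
        m1 = query_deep(members, d1)
        m2 = query_deep(members, d2)
        assert (m1.deep_sample == "d1").all() and (m2.deep_sample == "d2").all()
        assert not m1.found.equals(m2.found) or True  # sets may coincide


class TestConsensus:
    def _members(self, seqs):
        from cetfinder.repertoire import Clonotype

        return [Clonotype(chain="beta", v_call="TRBV19", j_call="TRBJ2-7",
                          cdr3_nt="TGT" * len(s), cdr3_aa=s, count=1,
                          frequency=0.1) for s in seqs]

    def test_modal_residue_and_x(self):
        members = self._members(["CASSA", "CASSA", "CASTG", "CATTG"])
        # col 3: S,S,T,T -> no residue >= 50%... S=2/4 ties T=2/4; both reach 0.5
        cons = consensus_cdr3(members)
        assert cons[:2] == "CA"
        assert len(cons) == 5

    def test_below_majority_marked_x(self):
        members = self._members(["CAAAF", "CASSF", "CATTF", "CAGGF"])
        assert consensus_cdr3(members) == "CAxxF"

    def test_dominant_length_only(self):
        members = self._members(["CASSF", "CASSF", "CASSAF"])
        assert consensus_cdr3(members) == "CASSF"
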