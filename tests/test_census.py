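"""The census post-processing: filters, HSP merging, escalation, rescue,
architecture classification and alignment trimming."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromcensus.census import (
    CensusConfig,
    DEFAULT_RULES,
    Evidence,
    Interval,
    LocusWindow,
    assemble_architecture,
    call_presence,
    classify_family,
    compute_coverage,
    escalation_decision,
    filter_domain_hits,
    filter_matches,
    join_match_sets,
    merge_hsps,
    rescue_windows,
    single_exon_rescue,
    trim_alignment_columns,
    union_intervals,
)
from chromcensus.io import Msa

from .conftest import make_domhit, make_hsp

CFG = CensusConfig()


def coverage_oracle(intervals, seq_len):
    """Per-position boolean-array reference for interval coverage."""
    covered = np.zeros(seq_len, dtype=bool)
    for iv in intervals:
        covered[iv.start - 1:iv.end] = True
    return covered.sum() / seq_len


class TestDomainHitFilter:
    @pytest.mark.parametrize(
        "hmm_from,hmm_to,env_from,env_to,kept",
        [
            (1, 70, 10, 79, True),     # model coverage 70/130 = 0.538
            (1, 60, 10, 89, False),    # 60/130 = 0.462 and 80/200 = 0.40
            (1, 130, 10, 139, True),   # full-length model match
            (1, 60, 10, 109, True),    # hit-side coverage 100/200 = 0.5 exactly
        ],
    )
    def test_model_or_hit_coverage(self, hmm_from, hmm_to, env_from, env_to, kept):
        hit = make_domhit(hmm_from=hmm_from, hmm_to=hmm_to,
                          env_from=env_from, env_to=env_to)
        assert (filter_domain_hits([hit], CFG) == [hit]) is kept

    def test_order_preserved(self):
        hits = [make_domhit(target=f"p{i}") for i in range(5)]
        assert filter_domain_hits(hits, CFG) == hits


class TestCoverage:
    @pytest.mark.parametrize(
        "ivs,seq_len,expected",
        [
            ([(1, 50)], 100, 0.5),
            ([(1, 50), (41, 60)], 100, 0.6),
            ([], 100, 0.0),
        ],
    )
    def test_examples(self, ivs, seq_len, expected):
        intervals = [Interval(a, b) for a, b in ivs]
        assert compute_coverage(intervals, seq_len) == pytest.approx(expected)

    def test_interval_exceeding_length_is_an_error(self):
        with pytest.raises(ValueError):
            compute_coverage([Interval(90, 120)], 100)

    @settings(max_examples=300, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(1, 1000), st.integers(0, 60)),
            max_size=12,
        ),
        st.integers(1, 1060),
    )
    def test_matches_boolean_array_oracle(self, raw, seq_len):
        intervals = [
            Interval(s, min(s + l, seq_len))
            for s, l in raw if s <= seq_len
        ]
        assert compute_coverage(intervals, seq_len) == pytest.approx(
            coverage_oracle(intervals, seq_len)
        )


class TestMergeHsps:
    def test_non_overlapping_concatenation(self):
        hsps = [
            make_hsp(qstart=1, qend=100, sstart=1, send=100, evalue=1e-20),
            make_hsp(qstart=120, qend=200, sstart=120, send=200, evalue=1e-10),
        ]
        m = merge_hsps(hsps, query_len=200, subject_len=200)
        assert m.coverage_query == pytest.approx(181 / 200)
        assert m.representative_evalue == 1e-10  # worst of the two

    def test_singleton_is_identity(self):
        h = make_hsp(qstart=10, qend=60, evalue=3e-8)
        m = merge_hsps([h], 100, 100)
        assert m.query_intervals == (Interval(10, 60),)
        assert m.representative_evalue == 3e-8

    def test_overlap_collapses_to_union(self):
        hsps = [make_hsp(qstart=1, qend=100), make_hsp(qstart=50, qend=150)]
        m = merge_hsps(hsps, 200, 200)
        assert m.query_intervals == (Interval(1, 150),)
        assert sum(len(iv) for iv in m.query_intervals) == 150

    def test_best_evalue_rule_switch(self):
        hsps = [make_hsp(evalue=1e-20), make_hsp(qstart=120, qend=150, evalue=1e-10)]
        m = merge_hsps(hsps, 200, 200, CensusConfig(evalue_rule="best"))
        assert m.representative_evalue == 1e-20

    def test_mixed_pairs_rejected(self):
        with pytest.raises(ValueError):
            merge_hsps([make_hsp(sseqid="s1"), make_hsp(sseqid="s2")], 100, 100)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            merge_hsps([], 100, 100)

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(1, 900), st.integers(0, 99),
                      st.floats(1e-40, 1e-3)),
            min_size=1, max_size=8,
        )
    )
    def test_order_invariant_and_matches_oracle(self, raw):
        hsps = [
            make_hsp(qstart=s, qend=s + l, sstart=s, send=s + l, evalue=e)
            for s, l, e in raw
        ]
        m1 = merge_hsps(hsps, 1000, 1000)
        m2 = merge_hsps(list(reversed(hsps)), 1000, 1000)
        assert m1 == m2
        assert m1.coverage_query == pytest.approx(
            coverage_oracle(m1.query_intervals, 1000)
        )
        # idempotence: union of the merged intervals changes nothing
        assert union_intervals(m1.query_intervals) == m1.query_intervals
        # merged coverage dominates every constituent HSP
        for h in hsps:
            assert m1.coverage_query >= (h.qend - h.qstart + 1) / 1000 - 1e-12


class TestFilterMatches:
    def _match(self, evalue, cov):
        span = max(1, round(cov * 200))
        return merge_hsps(
            [make_hsp(qstart=1, qend=span, sstart=1, send=span, evalue=evalue)],
            200, 400,  # subject twice as long: query side drives coverage
        )

    def test_retained_when_both_strict_tests_pass(self):
        assert filter_matches([self._match(1e-6, 0.6)], CFG)

    def test_evalue_boundary_is_strict(self):
        assert filter_matches([self._match(1e-5, 0.9)], CFG) == []

    def test_coverage_boundary_is_strict(self):
        m = self._match(1e-10, 0.5)
        assert m.coverage_query == pytest.approx(0.5)
        assert filter_matches([m], CFG) == []

    def test_idempotent(self):
        matches = [self._match(1e-6, 0.6), self._match(1e-4, 0.9),
                   self._match(1e-10, 0.3)]
        once = filter_matches(matches, CFG)
        assert filter_matches(once, CFG) == once


class TestEscalation:
    def _matches(self, n_asp, n_out=3, best_subject="aspX|p7", best_e=1e-40):
        out = []
        for i in range(n_asp):
            e = best_e if i == 0 else 1e-20
            sid = best_subject if i == 0 else f"asp{i:02d}|p1"
            out.append(merge_hsps([make_hsp(sseqid=sid, evalue=e)], 100, 100))
        for i in range(n_out):
            out.append(merge_hsps([make_hsp(sseqid=f"out{i:02d}|p1")], 100, 100))
        return out

    def _asp_species(self):
        return {"aspX"} | {f"asp{i:02d}" for i in range(100)}

    def test_enough_hits_no_escalation(self):
        plan = escalation_decision(self._matches(12), self._asp_species(), "q0", CFG)
        assert plan.escalate is False

    def test_few_hits_escalate_with_best_aspergilli_query(self):
        plan = escalation_decision(self._matches(9), self._asp_species(), "q0", CFG)
        assert plan.escalate is True
        assert plan.next_query_id == "aspX|p7"

    def test_no_aspergilli_match_reuses_original_query(self):
        plan = escalation_decision(self._matches(0), self._asp_species(), "q0", CFG)
        assert plan.escalate is True
        assert plan.next_query_id == "q0"

    def test_tie_breaks_are_deterministic(self):
        # equal e-values and coverages: lexicographically smaller id wins
        m1 = merge_hsps([make_hsp(sseqid="aspA|p2", evalue=1e-30)], 100, 100)
        m2 = merge_hsps([make_hsp(sseqid="aspA|p1", evalue=1e-30)], 100, 100)
        plan = escalation_decision([m1, m2], {"aspA"}, "q0", CFG)
        assert plan.next_query_id == "aspA|p1"


class TestJoinMatchSets:
    def _m(self, sid, evalue, span=80):
        return merge_hsps(
            [make_hsp(sseqid=sid, qstart=1, qend=span, sstart=1, send=span,
                      evalue=evalue)], 100, 100
        )

    def test_disjoint_union(self):
        joined = join_match_sets(
            [self._m(f"s{i}", 1e-10) for i in range(3)],
            [self._m(f"t{i}", 1e-10) for i in range(2)],
        )
        assert len(joined) == 5

    def test_collision_keeps_smaller_evalue(self):
        joined = join_match_sets([self._m("s1", 1e-8)], [self._m("s1", 1e-20)])
        assert len(joined) == 1
        assert joined[0].representative_evalue == 1e-20

    def test_empty_secondary_is_identity(self):
        primary = [self._m("s1", 1e-10)]
        assert join_match_sets(primary, []) == primary


class TestRescue:
    def test_flank_arithmetic(self):
        hit = make_hsp(sseqid="c1", sstart=10000, send=10300, evalue=1e-20)
        (w,) = rescue_windows([hit], {"c1": 1_000_000}, CFG)
        assert (w.start, w.end) == (5500, 14800)

    def test_left_clamp(self):
        hit = make_hsp(sseqid="c1", sstart=1000, send=1200, evalue=1e-20)
        (w,) = rescue_windows([hit], {"c1": 1_000_000}, CFG)
        assert (w.start, w.end) == (1, 5700)

    def test_overlapping_windows_merge_with_concatenated_evalues(self):
        hits = [
            make_hsp(sseqid="c1", sstart=10000, send=10300, evalue=1e-20),
            make_hsp(sseqid="c1", sstart=12000, send=12300, evalue=1e-9),
        ]
        (w,) = rescue_windows(hits, {"c1": 1_000_000}, CFG)
        assert (w.start, w.end) == (5500, 16800)
        assert sorted(w.source_evalues) == [1e-20, 1e-9]

    def test_weak_hits_dropped_strictly(self):
        hit = make_hsp(sseqid="c1", sstart=10000, send=10300, evalue=1e-5)
        assert rescue_windows([hit], {"c1": 1_000_000}, CFG) == []

    def test_unknown_contig_is_an_error(self):
        hit = make_hsp(sseqid="c9", sstart=10, send=40, evalue=1e-20)
        with pytest.raises(KeyError):
            rescue_windows([hit], {"c1": 100}, CFG)

    def test_windows_disjoint_within_contig_strand(self):
        rng = np.random.default_rng(0)
        hits = [
            make_hsp(sseqid="c1", sstart=int(s), send=int(s) + 200, evalue=1e-20)
            for s in rng.integers(5000, 200_000, size=30)
        ]
        windows = rescue_windows(hits, {"c1": 1_000_000}, CFG)
        spans = sorted((w.start, w.end) for w in windows)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2
            assert 1 <= s1 and e2 <= 1_000_000

    def test_forward_orf_translated(self):
        protein = "M" + "AGLV" * 30  # 121 aa
        codons = {"M": "ATG", "A": "GCT", "G": "GGT", "L": "CTT", "V": "GTT"}
        cds = "".join(codons[a] for a in protein) + "TAA"
        contig = "TTTT" + cds + "TTTT"
        w = LocusWindow("c1", 1, len(contig), "+", (1e-9,))
        cands = single_exon_rescue(w, contig, CFG)
        assert cands and cands[0].sequence == protein

    def test_reverse_strand_orf_found(self):
        from Bio.Seq import Seq

        protein = "M" + "AGLV" * 30
        codons = {"M": "ATG", "A": "GCT", "G": "GGT", "L": "CTT", "V": "GTT"}
        cds = "".join(codons[a] for a in protein) + "TAA"
        contig = "TTTT" + str(Seq(cds).reverse_complement()) + "TTTT"
        w = LocusWindow("c1", 1, len(contig), "+", (1e-9,))
        cands = single_exon_rescue(w, contig, CFG)
        assert any(c.sequence == protein for c in cands)

    def test_pure_n_window_yields_nothing(self):
        w = LocusWindow("c1", 1, 600, "+", (1e-9,))
        assert single_exon_rescue(w, "N" * 600, CFG) == []


class TestArchitecture:
    def test_sorted_by_envelope_start(self):
        hits = [
            make_domhit(domain="PF00271", env_from=600, env_to=700, target_len=800,
                        hmm_len=100, hmm_from=1, hmm_to=100),
            make_domhit(domain="PF00145", env_from=10, env_to=200, target_len=800,
                        hmm_len=190, hmm_from=1, hmm_to=190),
            make_domhit(domain="PF00176", env_from=300, env_to=500, target_len=800,
                        hmm_len=200, hmm_from=1, hmm_to=200),
        ]
        assert assemble_architecture(hits) == ("PF00145", "PF00176", "PF00271")

    def test_overlapping_same_accession_collapse(self):
        hits = [
            make_domhit(env_from=10, env_to=100, target_len=200, hmm_len=100,
                        hmm_from=1, hmm_to=91),
            make_domhit(env_from=60, env_to=150, target_len=200, hmm_len=100,
                        hmm_from=1, hmm_to=91),
        ]
        assert assemble_architecture(hits) == ("PF00856",)

    def test_empty_architecture(self):
        assert assemble_architecture([]) == ()

    @pytest.mark.parametrize(
        "arch,expected",
        [
            ({"PF00145", "PF00176", "PF00271"}, "DNMT5"),
            ({"PF00856", "PF17907"}, "Ash1"),
            ({"PF00856", "PF17907", "PF08236"}, "SET2"),
            ({"PF00856", "PF05033"}, "Dim-5"),
            ({"PF00856", "PF11764", "PF11767"}, "SET1"),
            ({"PF00583", "PF00439"}, "Gcn5"),
            ({"PF00583", "PF04055", "PF16199"}, "Elp3"),
            ({"PF01853", "PF17772"}, "Sas3"),
            ({"PF00850", "PF09757"}, "HdaA"),
            ({"PF00856", "PF09273"}, "RKMT"),
            ({"PF00856"}, "SET-unclassified"),
            ({"PF99999"}, "UNCLASSIFIED"),
        ],
    )
    def test_family_rules(self, arch, expected):
        assert classify_family(arch, DEFAULT_RULES) == expected

    def test_classification_total_and_deterministic(self):
        rng = np.random.default_rng(1)
        accs = ["PF00856", "PF17907", "PF08236", "PF05033", "PF00583", "PF00439"]
        for _ in range(50):
            arch = {a for a in accs if rng.random() < 0.5}
            l1 = classify_family(arch, DEFAULT_RULES)
            l2 = classify_family(arch, DEFAULT_RULES)
            assert isinstance(l1, str) and l1 == l2


class TestPresenceCalls:
    def test_domain_scan_tier_wins(self):
        calls = call_presence(
            domain_scan={("sp1", "SET1"): ["sp1|p1"]},
            blastp={("sp1", "SET1"): ["sp1|p1"]},
        )
        (c,) = calls
        assert c.present and c.evidence is Evidence.DOMAIN_SCAN

    def test_no_evidence_absent_on_grid(self):
        calls = call_presence(grid=(["sp1"], ["SET1"]))
        (c,) = calls
        assert not c.present and c.evidence is Evidence.ABSENT
        assert c.supporting_ids == ()

    def test_rescue_only_is_rescue_tier(self):
        calls = call_presence(rescue={("sp1", "SET1"): ["c1:1-100:+1:orf1"]})
        (c,) = calls
        assert c.present and c.evidence is Evidence.RESCUE

    def test_adding_evidence_never_lowers_tier_or_flips_to_absent(self):
        base = call_presence(blastp={("sp1", "SET1"): ["x"]})
        more = call_presence(
            blastp={("sp1", "SET1"): ["x"]},
            rescue={("sp1", "SET1"): ["y"]},
            domain_scan={("sp1", "SET1"): ["z"]},
        )
        assert base[0].present and more[0].present
        assert more[0].evidence.value <= base[0].evidence.value


class TestTrim:
    def test_boundary_gap_fraction_kept(self):
        # 10 sequences, first column gapped in exactly 9 (0.9): kept
        records = tuple(
            (f"s{i}", ("-" if i < 9 else "A") + "C") for i in range(10)
        )
        out = trim_alignment_columns(Msa(records), CFG)
        assert out.n_columns == 2

    def test_all_gap_column_removed(self):
        records = tuple((f"s{i}", "-C") for i in range(10))
        out = trim_alignment_columns(Msa(records), CFG)
        assert out.n_columns == 1
        assert all(seq == "C" for _, seq in out.records)

    def test_gapless_alignment_unchanged(self):
        msa = Msa((("a", "ACDE"), ("b", "ACDE")))
        assert trim_alignment_columns(msa, CFG) == msa
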