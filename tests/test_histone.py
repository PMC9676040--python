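"""Digestion, modified-form enumeration, masses and %RA quantification."""

import numpy as np
import pytest

from chromcensus.histone import (
    DEFAULT_HISTONES,
    KState,
    ModForm,
    MsConfig,
    PeptideSpan,
    PtmStatus,
    detect_ptm_status,
    digest_argc,
    enumerate_forms,
    filter_identifications,
    form_mass,
    parse_form_label,
    ppm_match,
    relative_abundance,
)
from chromcensus.io import AucObservation, ProteinRecord

CFG = MsConfig()

# ---------------------------------------------------------------------------
# independent mass oracle: elemental composition with CODATA atomic masses,
# assembled by hand (kept independent of the pyteomics-backed implementation)

ATOM = {"H": 1.00782503, "C": 12.0, "N": 14.00307401, "O": 15.99491462,
        "S": 31.97207069}

# residue (i.e. amino acid minus water) elemental compositions
RESIDUE_COMP = {
    "G": dict(C=2, H=3, N=1, O=1), "A": dict(C=3, H=5, N=1, O=1),
    "S": dict(C=3, H=5, N=1, O=2), "P": dict(C=5, H=7, N=1, O=1),
    "V": dict(C=5, H=9, N=1, O=1), "T": dict(C=4, H=7, N=1, O=2),
    "C": dict(C=3, H=5, N=1, O=1, S=1), "L": dict(C=6, H=11, N=1, O=1),
    "I": dict(C=6, H=11, N=1, O=1), "N": dict(C=4, H=6, N=2, O=2),
    "D": dict(C=4, H=5, N=1, O=3), "Q": dict(C=5, H=8, N=2, O=2),
    "K": dict(C=6, H=12, N=2, O=1), "E": dict(C=5, H=7, N=1, O=3),
    "M": dict(C=5, H=9, N=1, O=1, S=1), "H": dict(C=6, H=7, N=3, O=1),
    "F": dict(C=9, H=9, N=1, O=1), "R": dict(C=6, H=12, N=4, O=1),
    "Y": dict(C=9, H=9, N=1, O=2), "W": dict(C=11, H=10, N=2, O=1),
}

DELTA_COMP = {
    KState.PR: dict(C=3, H=4, O=1),
    KState.ME1PR: dict(C=4, H=6, O=1),
    KState.ME2: dict(C=2, H=4),
    KState.ME3: dict(C=3, H=6),
    KState.AC: dict(C=2, H=2, O=1),
}
PIC_COMP = dict(C=7, H=5, N=1, O=1)
WATER_COMP = dict(H=2, O=1)


def _mass(comp):
    return sum(ATOM[el] * n for el, n in comp.items())


def oracle_mass(sequence, k_states):
    comp = {el: 0 for el in ATOM}
    for aa in sequence:
        for el, n in RESIDUE_COMP[aa].items():
            comp[el] += n
    for add in (WATER_COMP, PIC_COMP, *(DELTA_COMP[s] for s in k_states)):
        for el, n in add.items():
            comp[el] += n
    return _mass(comp)


# ---------------------------------------------------------------------------


class TestDigestion:
    def test_h3_tail_span_enumeration(self):
        prot = ProteinRecord("H3", "H3", "ARTKQTARKSTGGKAPR")
        spans = {(s.start, s.end) for s in digest_argc(prot, CFG)}
        # the 1-2 "AR" peptide is dropped (length 2 < 4)
        assert spans == {(3, 8), (9, 17), (1, 8), (3, 17), (1, 17)}

    def test_lysine_does_not_cut(self):
        prot = ProteinRecord("x", "x", "AKAKAR")
        spans = digest_argc(prot, CFG)
        assert [(s.start, s.end) for s in spans] == [(1, 6)]

    def test_non_r_terminus_included(self):
        prot = ProteinRecord("x", "x", "AAARGGGG")
        spans = {(s.start, s.end) for s in digest_argc(prot, CFG)}
        assert (5, 8) in spans  # C-terminal peptide without terminal R

    def test_missed_cleavage_bound_respected(self):
        prot = ProteinRecord("x", "x", "AAAARBBBBRCCCCRDDDDR".replace("B", "G")
                             .replace("C", "G").replace("D", "G"))
        for s in digest_argc(prot, CFG):
            assert s.missed_cleavages <= CFG.max_missed_cleavages
            assert s.sequence[:-1].count("R") == s.missed_cleavages

    def test_zero_mc_peptides_tile_the_protein(self, h3):
        spans = [s for s in digest_argc(h3, MsConfig(min_peptide_len=1))
                 if s.missed_cleavages == 0]
        spans.sort(key=lambda s: s.start)
        assert spans[0].start == 1
        assert spans[-1].end == h3.length
        for a, b in zip(spans, spans[1:]):
            assert b.start == a.end + 1


class TestFormEnumeration:
    @pytest.mark.parametrize("seq,start,n_k", [("TKQTAR", 3, 1),
                                               ("KSTGGKAPR", 9, 2),
                                               ("STGGR", 1, 0)])
    def test_five_to_the_k_forms(self, seq, start, n_k):
        span = PeptideSpan("H3", start, start + len(seq) - 1, seq,
                           seq[:-1].count("R"))
        forms = enumerate_forms(span, CFG)
        assert len(forms) == 5 ** n_k
        assert len({f.label for f in forms}) == len(forms)

    def test_too_many_lysines_rejected(self):
        seq = "K" * 7 + "R"
        span = PeptideSpan("x", 1, 8, seq, 0)
        with pytest.raises(ValueError, match="split the span"):
            enumerate_forms(span, CFG)

    def test_label_grammar_round_trip(self):
        span = PeptideSpan("H3", 9, 17, "KSTGGKAPR", 0)
        for form in enumerate_forms(span, CFG):
            parsed = parse_form_label(form.label, span=(9, 17))
            assert parsed == dict(form.k_states)

    @pytest.mark.parametrize("bad", ["K9me4", "K9", "me2", "K9me2+K9pr",
                                     "K14pr+K9me2", "K9xx"])
    def test_bad_labels_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_form_label(bad)


class TestMasses:
    def test_reference_peptide_mass_and_mz(self):
        # TKQTAR with K4 propionylated, PIC on the N-terminus, doubly charged
        span = PeptideSpan("H3", 3, 8, "TKQTAR", 0)
        form = ModForm(span, {4: KState.PR})
        fm = form_mass(form, CFG)
        assert fm.monoisotopic_mass == pytest.approx(878.4610, abs=1e-3)
        assert fm.mz == pytest.approx(440.2378, abs=1e-3)

    def test_me2_vs_pr_delta_is_exact(self):
        span = PeptideSpan("H3", 3, 8, "TKQTAR", 0)
        m_pr = form_mass(ModForm(span, {4: KState.PR}), CFG).monoisotopic_mass
        m_me2 = form_mass(ModForm(span, {4: KState.ME2}), CFG).monoisotopic_mass
        assert m_me2 - m_pr == pytest.approx(28.03130 - 56.02621, abs=1e-5)

    def test_against_elemental_composition_oracle_20_peptides(self, h3, h4):
        """Implementation masses match an independent hand-built elemental
        oracle on a 20-peptide fixture within 1e-3 Da."""
        fixture = []
        for prot in (h3, h4):
            for span in digest_argc(prot, CFG):
                if len(span.k_positions) <= 2:
                    fixture.append(span)
        fixture = fixture[:20]
        assert len(fixture) == 20
        rng = np.random.default_rng(0)
        for span in fixture:
            states = {
                pos: list(KState)[rng.integers(5)] for pos in span.k_positions
            }
            form = ModForm(span, states)
            got = form_mass(form, CFG).monoisotopic_mass
            want = oracle_mass(span.sequence, states.values())
            assert got == pytest.approx(want, abs=1e-3)

    def test_mass_additivity_between_forms(self):
        span = PeptideSpan("H3", 9, 17, "KSTGGKAPR", 0)
        forms = enumerate_forms(span, CFG)
        base = form_mass(forms[0], CFG).monoisotopic_mass
        from chromcensus.histone import STATE_DELTA

        for f in forms:
            expected = base + sum(
                STATE_DELTA[f.k_states[p]] - STATE_DELTA[forms[0].k_states[p]]
                for p in span.k_positions
            )
            assert form_mass(f, CFG).monoisotopic_mass == pytest.approx(
                expected, abs=1e-9
            )

    def test_non_canonical_residue_rejected(self):
        span = PeptideSpan("x", 1, 4, "AXAR", 0)
        with pytest.raises(ValueError):
            form_mass(ModForm(span, {}), CFG)


class TestPpm:
    def test_identity_matches(self):
        assert ppm_match(440.2378, 440.2378, 10)

    def test_boundary(self):
        theo = 440.2378
        just_inside = theo * (1 + 9.999e-6)
        just_beyond = theo * (1 + 10.5e-6)
        assert ppm_match(just_inside, theo, 10)
        assert not ppm_match(just_beyond, theo, 10)

    def test_far_off_rejected(self):
        assert not ppm_match(441.0, 440.2378, 10)


def obs(form, auc, score=120.0, prob=0.99, span=(9, 17), histone="H3"):
    return AucObservation(histone, span[0], span[1], form, auc, score, prob)


class TestIdentificationFilter:
    def test_strict_boundaries(self):
        kept = filter_identifications(
            [
                obs("K9pr+K14pr", 100, score=51, prob=0.8),
                obs("K9me2+K14pr", 100, score=50, prob=0.99),
                obs("K9ac+K14pr", 100, score=120, prob=0.75),
            ],
            CFG,
        )
        assert [o.form_label for o in kept] == ["K9pr+K14pr"]


class TestRelativeAbundance:
    def test_simple_ratio(self):
        q = relative_abundance([obs("K9pr+K14pr", 800), obs("K9me1+K14pr", 200)])
        assert q.ra("H3", 9, 17, "K9pr+K14pr") == pytest.approx(80.0)
        assert q.ra("H3", 9, 17, "K9me1+K14pr") == pytest.approx(20.0)

    def test_sums_to_100_and_scale_invariant(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            aucs = rng.uniform(1, 1e6, size=5)
            labels = ["K9pr+K14pr", "K9me1+K14pr", "K9me2+K14pr",
                      "K9me3+K14pr", "K9ac+K14pr"]
            base = relative_abundance([obs(l, a) for l, a in zip(labels, aucs)])
            scaled = relative_abundance(
                [obs(l, a * 3.7) for l, a in zip(labels, aucs)]
            )
            total = sum(base.table[("H3", 9, 17)].values())
            assert total == pytest.approx(100.0, abs=1e-9)
            for l in labels:
                assert base.ra("H3", 9, 17, l) == pytest.approx(
                    scaled.ra("H3", 9, 17, l), abs=1e-9
                )

    def test_all_zero_span_omitted(self):
        q = relative_abundance([obs("K9pr+K14pr", 0.0)])
        assert q.table == {}

    def test_duplicate_form_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            relative_abundance([obs("K9pr+K14pr", 10), obs("K9pr+K14pr", 20)])


class TestPtmStatus:
    def test_unmodified_only_span_reports_not_detected_but_ac_detected(self):
        seqs = dict(DEFAULT_HISTONES)
        # K27-covering span observed only in methylation-free forms; K27ac seen
        rows = [
            obs("K27pr+K36pr+K37pr", 500, span=(27, 40)),
            obs("K27ac+K36pr+K37pr", 100, span=(27, 40)),
        ]
        q = relative_abundance(filter_identifications(rows, CFG))
        report = detect_ptm_status(
            q, [("H3", 27, "me"), ("H3", 27, "ac")], seqs, CFG
        )
        assert report[("H3", 27, "me")] is PtmStatus.NOT_DETECTED
        assert report[("H3", 27, "ac")] is PtmStatus.DETECTED

    def test_missing_span_reports_span_not_observed(self):
        q = relative_abundance([obs("K9me2+K14pr", 100)])
        report = detect_ptm_status(q, [("H4", 20, "me")], DEFAULT_HISTONES, CFG)
        assert report[("H4", 20, "me")] is PtmStatus.SPAN_NOT_OBSERVED

    def test_detected_with_positive_ra(self):
        q = relative_abundance(
            [obs("K9me2+K14pr", 12), obs("K9pr+K14pr", 88)]
        )
        report = detect_ptm_status(q, [("H3", 9, "me2")], DEFAULT_HISTONES, CFG)
        assert report[("H3", 9, "me2")] is PtmStatus.DETECTED

    def test_non_lysine_target_rejected(self):
        q = relative_abundance([obs("K9pr+K14pr", 10)])
        with pytest.raises(ValueError):
            detect_ptm_status(q, [("H3", 8, "me")], DEFAULT_HISTONES, CFG)
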