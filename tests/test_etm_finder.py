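import dataclasses

import pytest
from hypothesis import given, strategies as st

from etmnet.io_formats import Alphabet, SequenceRecord
from etmnet.etm_finder import (
    GAP,
    AlignmentColumn,
    EtmParams,
    PairClass,
    PairingAlignment,
    alignment_from_gapped_site,
    best_alignment,
    evaluate_alignment,
    pair_class,
    render_alignment,
    reverse_complement_rna,
    scan_lncrna,
)
from etmnet.synthetic_data import PlantedEtm, SynthConfig, gen_sequences

from .oracles import brute_force_scan

MIR156H = "UGACAGAAGAAAGAGAGCAC"
SITE_156H_7374 = "GUGCUCUCUAUCUUCUGUCA"


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("A", "U", PairClass.watson_crick),
        ("U", "A", PairClass.watson_crick),
        ("G", "C", PairClass.watson_crick),
        ("C", "G", PairClass.watson_crick),
        ("G", "U", PairClass.wobble),
        ("U", "G", PairClass.wobble),
        ("C", "U", PairClass.mismatch),
        ("A", "A", PairClass.mismatch),
    ],
)
def test_pair_class(a, b, expected):
    assert pair_class(a, b) is expected


def test_pair_class_rejects_non_rna():
    with pytest.raises(ValueError):
        pair_class("T", "A")


class TestEvaluateAlignment:
    def test_published_mir156h_site_passes_with_one_mismatch(self):
        """The gapless published duplex has exactly one mismatch, at
        miRNA position 11, and satisfies all three rules."""
        aln = alignment_from_gapped_site(MIR156H, SITE_156H_7374)
        rep = evaluate_alignment(aln)
        assert rep.verdict
        assert rep.n_mismatch == 1 and rep.mismatch_positions == (11,)
        assert rep.n_wobble == 0 and rep.bulges == ()

    def test_perfect_duplex_passes_clean(self):
        mirna = "UGACAGAAGAGAGAGAGCACU"
        aln = alignment_from_gapped_site(mirna, reverse_complement_rna(mirna))
        rep = evaluate_alignment(aln)
        assert rep.verdict
        assert (rep.n_mismatch, rep.n_wobble, rep.bulges) == (0, 0, ())

    def test_seed_mismatch_flips_rule1(self):
        """Mutating the site base opposite miRNA position 5 breaks the
        perfect-seed requirement and therefore the overall verdict."""
        gapped = list(SITE_156H_7374)
        col = len(MIR156H) - 5  # site index pairing miRNA position 5
        orig = gapped[col]
        gapped[col] = {"A": "C", "C": "A", "G": "A", "U": "C"}[orig]
        rep = evaluate_alignment(alignment_from_gapped_site(MIR156H, "".join(gapped)))
        assert not rep.rule1_ok and not rep.verdict

    def test_two_mismatches_plus_wobble_fail_rule3(self):
        # build a duplex with mismatches at 13, 15 and a wobble at 17
        mirna = "AACCAACCAACCGACAGAAUU"
        revsite = list(reverse_complement_rna(mirna)[::-1])  # pairing orientation
        revsite[12] = "A"  # opposite G at position 13 -> mismatch
        revsite[14] = "C"  # opposite A at position 15 -> mismatch
        revsite[16] = "U"  # opposite G at position 17 -> wobble
        gapped = "".join(reversed(revsite))
        rep = evaluate_alignment(alignment_from_gapped_site(mirna, gapped))
        assert rep.n_mismatch == 2 and rep.n_wobble == 1
        assert not rep.rule3_ok and not rep.verdict

    def test_terminal_overhang_not_counted_as_bulge(self):
        """A dangling site gap at the duplex end (as printed for the
        lch-miR157a-3p pair) is an overhang, not a rule-2 bulge."""
        aln = alignment_from_gapped_site(
            "GCUCUCUAGCCUUCUGUCAUC", "GAUGACAGAAGCAUAGAGAG-"
        )
        rep = evaluate_alignment(aln)
        assert rep.bulges == ()
        assert rep.verdict and rep.n_mismatch == 2

    def test_one_nt_bulge_anchored_at_position_9(self):
        """The published lch-lnc7276 rendering carries a single unpaired
        miRNA base at position 9 — a legal bulge — though its three
        mismatches exceed the rule-3 budget."""
        aln = alignment_from_gapped_site(
            "AUGGACUGGCCUGAUUUUUAAGCC", "GGCCCAAAAAUCAGG-CAGUCCAA"
        )
        rep = evaluate_alignment(aln)
        assert rep.bulges == ((9, 1, "mirna"),)
        assert rep.rule2_ok
        assert rep.n_mismatch == 3 and not rep.rule3_ok

    def test_three_nt_bulge_within_window_ok(self):
        aln = alignment_from_gapped_site(
            "AUCUGUCUGAUUUUUGUGAACGUG", "AAGGUUCACAAAA---AGACAGAA"
        )
        rep = evaluate_alignment(aln)
        assert rep.bulges == ((9, 3, "mirna"),)
        assert rep.rule2_ok

    def test_oversized_bulge_fails_rule2(self):
        params = EtmParams(max_bulge=2)
        aln = alignment_from_gapped_site(
            "AUCUGUCUGAUUUUUGUGAACGUG", "AAGGUUCACAAAA---AGACAGAA"
        )
        assert not evaluate_alignment(aln, params).rule2_ok

    def test_alignment_invariants_enforced(self):
        cols = (
            AlignmentColumn("A", "U", 1, PairClass.watson_crick),
        )
        with pytest.raises(ValueError):
            PairingAlignment("m", "l", "AC", "GU", cols)


class TestScan:
    def _plant(self, seed, **spec_kwargs):
        cfg = SynthConfig(
            seed=seed,
            n_mirnas=1,
            n_lncrnas=1,
            lncrna_length_range=(400, 500),
            planted_etm_spec=[PlantedEtm(0, 0, 150, **spec_kwargs)],
        )
        mirnas, lncrnas, manifest = gen_sequences(cfg)
        return mirnas[0], lncrnas[0], manifest.etm_sites[0]

    def test_planted_site_recovered_at_exact_offset(self):
        mirna, lncrna, truth = self._plant(11, n_mismatches=1)
        hits = scan_lncrna(mirna, lncrna)
        assert len(hits) == 1
        aln, rep = hits[0]
        assert (aln.site_start, aln.site_end) == (
            truth["site_start"], truth["site_end"]
        )
        assert rep.verdict and rep.n_mismatch == 1

    def test_planted_bulged_site_recovered(self):
        mirna, lncrna, truth = self._plant(12, bulge_length=2, n_wobbles=1)
        hits = scan_lncrna(mirna, lncrna)
        assert len(hits) == 1
        aln, rep = hits[0]
        assert (aln.site_start, aln.site_end) == (
            truth["site_start"], truth["site_end"]
        )
        # the rendering may trade the planted wobble for a mismatch at an
        # equivalent anchor, but the duplex quality is pinned down
        assert sum(l for _, l, _ in rep.bulges) == 2 and rep.score == 1

    def test_unrelated_lncrna_yields_nothing(self, rng):
        from .conftest import random_rna

        mirna = SequenceRecord("m", Alphabet.RNA, "UGACAGAAGAGAGAGAGCAC")
        # complement-free lncRNA: only A and G can never seed-pair a
        # site for a miRNA whose seed needs C/U partners
        lncrna = SequenceRecord(
            "l", Alphabet.RNA, "".join(rng.choice(list("AG"), size=300))
        )
        assert scan_lncrna(mirna, lncrna) == []

    def test_non_rna_input_rejected(self):
        m = SequenceRecord("m", Alphabet.DNA, "ACGT" * 5)
        l = SequenceRecord("l", Alphabet.DNA, "ACGT" * 30)
        with pytest.raises(ValueError, match="RNA"):
            scan_lncrna(m, l)

    def test_short_lncrna_rejected(self):
        m = SequenceRecord("m", Alphabet.RNA, "ACGU" * 6)
        l = SequenceRecord("l", Alphabet.RNA, "ACGU")
        with pytest.raises(ValueError, match="shorter"):
            scan_lncrna(m, l)

    def test_matches_brute_force_on_planted_instances(self, rng):
        """Production scanner and the independent enumerator agree on
        sites, including planted ones, over random instances."""
        from .conftest import random_rna

        for trial in range(15):
            cfg = SynthConfig(
                seed=1000 + trial,
                n_mirnas=1,
                n_lncrnas=1,
                mirna_length_range=(20, 24),
                lncrna_length_range=(150, 200),
                planted_etm_spec=[
                    PlantedEtm(
                        0, 0, int(rng.integers(0, 100)),
                        bulge_length=int(rng.integers(0, 3)),
                        n_mismatches=int(rng.integers(0, 2)),
                        n_wobbles=int(rng.integers(0, 2)),
                    )
                ],
            )
            mirnas, lncrnas, _ = gen_sequences(cfg)
            got = [
                (a.site_start, a.site_end, r.n_mismatch, r.n_wobble)
                for a, r in scan_lncrna(mirnas[0], lncrnas[0])
            ]
            expected = brute_force_scan(mirnas[0].residues, lncrnas[0].residues)
            assert sorted(got) == expected


def test_degrading_a_passing_alignment_flips_verdict():
    """Property: forcing any seed-region column of a passing duplex to a
    mismatch makes the verdict false."""
    aln = alignment_from_gapped_site(MIR156H, SITE_156H_7374)
    assert evaluate_alignment(aln).verdict
    for pos in range(2, 9):
        gapped = list(SITE_156H_7374)
        col = len(MIR156H) - pos
        mirna_char = MIR156H[pos - 1]
        gapped[col] = mirna_char  # same base never pairs in RNA
        rep = evaluate_alignment(
            alignment_from_gapped_site(MIR156H, "".join(gapped))
        )
        assert not rep.verdict and not rep.rule1_ok


def test_render_alignment_shows_duplex():
    aln = alignment_from_gapped_site(MIR156H, SITE_156H_7374)
    text = render_alignment(aln)
    lines = text.splitlines()
    assert MIR156H in lines[0]
    assert SITE_156H_7374[::-1] in lines[2]


def test_best_alignment_handles_longer_site():
    """A site longer than the miRNA is placed with inserted nucleotides
    at the best-scoring legal anchor."""
    mirna = "GUUCAAUAAAGCUGUGGGAAG"
    site = "CGUCCCACAGUCACAUAUUGAAG"  # 2 nt longer than the miRNA
    aln, rep = best_alignment(mirna, site)
    assert len(aln.site_seq) == len(site)
    assert any(side == "target" for _, _, side in rep.bulges)
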