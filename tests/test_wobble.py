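import numpy as np
import pytest
from scipy import stats

from atdqc import synthetic as synth
from atdqc import wobble as wob

from .oracles import fisher_exact_enumeration


def _gene(seq, isotype="Thr", organism="org", score=70.0, ss=None):
    return wob.TRNAGene(organism, isotype, "AGU", score, seq, ss)


def _canonical(g4="G", u69="U"):
    """73-nt gene: WC stem except pair 4, deterministic filler body.

    The 5' stem starts GC so the 3' end cannot spell an accidental CCA
    (which would be stripped and shift the numbering).
    """
    stem5 = list("GCCAGCA")
    stem5[3] = g4
    wc = {"A": "U", "U": "A", "G": "C", "C": "G"}
    stem3 = [wc[b] for b in stem5[::-1]]
    stem3[-4] = u69
    body = ("AUCG" * 15)[:58]
    return "".join(stem5) + body + "".join(stem3) + "A"


class TestReadTable:
    def test_tsv_round_trip(self, tmp_path):
        p = tmp_path / "genes.tsv"
        p.write_text(
            "organism\tisotype\tanticodon\tscore\tsequence\n"
            + "\n".join(
                f"org\tThr\tAGT\t{60 + i}\t{_canonical()}" for i in range(3)
            )
            + "\n"
        )
        genes = wob.read_trna_table(p, "tsv")
        assert len(genes) == 3
        assert genes[0].sequence.count("T") == 0  # T normalized to U

    def test_missing_score_column_is_schema_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("organism\tisotype\tanticodon\tsequence\nx\tThr\tAGT\tACGU\n")
        with pytest.raises(wob.SchemaError, match="score"):
            wob.read_trna_table(p, "tsv")

    def test_fasta_with_structured_headers(self, tmp_path):
        p = tmp_path / "genes.fasta"
        p.write_text(
            f">g1 organism=Homo_sapiens isotype=Thr anticodon=AGU score=75.2\n{_canonical()}\n"
        )
        (g,) = wob.read_trna_table(p, "fasta")
        assert g.organism == "Homo_sapiens"
        assert g.score == pytest.approx(75.2)


class TestScoreFilter:
    def test_strictly_greater(self):
        genes = [_gene(_canonical(), score=s) for s in (49.0, 50.0, 51.0)]
        kept = wob.filter_by_score(genes, 50.0)
        assert [g.score for g in kept] == [51.0]

    def test_empty_input(self):
        assert wob.filter_by_score([], 50.0) == []

    def test_minus_infinity_is_identity(self):
        genes = [_gene(_canonical(), score=s) for s in (1.0, 99.0)]
        assert wob.filter_by_score(genes, float("-inf")) == genes


class TestAcceptorStem:
    def test_pair4_g4u69(self):
        stem = wob.acceptor_stem_pairs(_gene(_canonical()))
        five, three, p5, p3 = stem.pairs[3]
        assert (five, three) == ("G", "U")
        assert (p5, p3) == (4, 69)

    def test_cca_stripping_invariance(self):
        g = _gene(_canonical())
        g_cca = _gene(_canonical() + "CCA")
        assert wob.acceptor_stem_pairs(g) == wob.acceptor_stem_pairs(g_cca)

    def test_watson_crick_stem(self):
        stem = wob.acceptor_stem_pairs(_gene(_canonical(g4="A", u69="U")))
        wc = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
        assert all((f, t) in wc for f, t, _, _ in stem.pairs)

    def test_short_sequence_refused(self):
        with pytest.raises(ValueError, match="short"):
            wob.acceptor_stem_pairs(_gene("ACGU" * 10))

    def test_secondary_structure_override(self):
        seq = _canonical()
        ss = "(" * 7 + "." * 58 + ")" * 7 + "."
        stem = wob.acceptor_stem_pairs(_gene(seq, ss=ss))
        assert stem.pairs[3][:2] == ("G", "U")


class TestDetectWobble:
    @pytest.mark.parametrize(
        "g4,u69,expect_gu,expect_ug",
        [("G", "U", True, False), ("U", "G", False, True), ("A", "U", False, False)],
    )
    def test_directionality(self, g4, u69, expect_gu, expect_ug):
        stem = wob.acceptor_stem_pairs(_gene(_canonical(g4=g4, u69=u69)))
        call = wob.detect_wobble(stem, 4)
        assert call.is_G4U69 is expect_gu
        assert call.is_U4G69 is expect_ug

    def test_gu_at_other_pair_is_not_g4u69(self):
        stem = wob.acceptor_stem_pairs(_gene(_canonical()))
        call = wob.detect_wobble(stem, 2)
        assert not call.is_G4U69


class TestEnrichment:
    def test_one_in_five_is_twenty_percent(self):
        genes = [_gene(_canonical())] + [_gene(_canonical(g4="A", u69="U"))] * 4
        (row,) = wob.enrichment(genes)
        assert row.n_total == 5 and row.n_wobble == 1
        assert row.fraction == pytest.approx(20.0)

    def test_order_permutation_invariance(self, rng):
        genes = synth.gen_trna_set({"Thr": 30}, {"Thr": 0.4}, seed=2)
        base = wob.enrichment(genes)
        shuffled = list(genes)
        rng.shuffle(shuffled)
        assert wob.enrichment(shuffled) == base

    def test_binomial_sampling(self):
        """Generated at p=0.3, n=200: the measured fraction falls in the
        95% binomial interval around 30%."""
        genes = synth.gen_trna_set({"Thr": 200}, {"Thr": 0.3}, seed=7)
        (row,) = wob.enrichment(genes)
        lo, hi = stats.binom.interval(0.95, 200, 0.3)
        assert lo <= row.n_wobble <= hi


class TestFisherAndCooccurrence:
    def test_textbook_table(self):
        assert wob.fisher_exact_two_sided(((5, 0), (0, 5))) == pytest.approx(
            2 / 252, abs=1e-12
        )

    def test_matches_exact_enumeration_small_margins(self):
        for a in range(5):
            for b in range(5):
                for c in range(5):
                    for d in range(5):
                        got = wob.fisher_exact_two_sided(((a, b), (c, d)))
                        exp = fisher_exact_enumeration(a, b, c, d)
                        assert got == pytest.approx(exp, abs=1e-10), (a, b, c, d)

    def test_matches_scipy(self, rng):
        for _ in range(50):
            t = rng.integers(0, 15, size=(2, 2))
            got = wob.fisher_exact_two_sided(tuple(map(tuple, t)))
            exp = stats.fisher_exact(t, alternative="two-sided")[1]
            assert got == pytest.approx(exp, rel=1e-8)

    def test_perfect_concordance(self):
        rows, presence = synth.gen_presence_table(10, concordance=1.0, seed=3)
        rep = wob.cooccurrence(rows, presence)
        assert rep.concordance == pytest.approx(1.0)

    def test_single_organism_refused(self):
        rows, presence = synth.gen_presence_table(1, concordance=1.0, seed=3)
        with pytest.raises(ValueError):
            wob.cooccurrence(rows, presence)

    def test_shuffled_presence_concordance_near_half(self, rng):
        """Under independence the expected concordance is determined by
        the marginal enriched fraction; permuting presence labels must
        reproduce it."""
        rows, presence = synth.gen_presence_table(60, concordance=1.0, seed=4)
        orgs = list(presence)
        vals = [v for v in presence.values()]
        p_pres = np.mean(vals)
        enr = np.array([r.fraction >= 10.0 for r in rows])
        p_enr = enr.mean()
        expected = p_enr * p_pres + (1 - p_enr) * (1 - p_pres)
        sims = []
        for _ in range(500):
            rng.shuffle(vals)
            shuffled = dict(zip(orgs, vals))
            sims.append(wob.cooccurrence(rows, shuffled).concordance)
        se = np.std(sims) / np.sqrt(len(sims)) + 1e-9
        assert abs(np.mean(sims) - expected) < 5 * se + 0.01


class TestConsensus:
    def test_identical_genes_fully_conserved(self):
        genes = [_gene(_canonical())] * 5
        rep = wob.acceptor_consensus(genes)
        assert all(freq == pytest.approx(1.0) for _, freq in rep.conservation)

    def test_divergence_at_one_pair(self):
        a = _canonical()
        b = list(_canonical())
        b[5] = "A"  # pair 6 five-prime base
        b[67 - 1] = "U"  # its partner, position 67
        genes = [_gene(a)] * 5 + [_gene("".join(b))] * 5
        rep = wob.acceptor_consensus(genes)
        freqs = [f for _, f in rep.conservation]
        assert freqs[5] == pytest.approx(0.5)
        assert all(f == pytest.approx(1.0) for i, f in enumerate(freqs) if i != 5)

    def test_generated_wobble_set_modal_pair4(self):
        genes = synth.gen_trna_set({"Thr": 30}, {"Thr": 1.0}, seed=6)
        rep = wob.acceptor_consensus(genes)
        assert rep.conservation[3][0] == ("G", "U")
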