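"""Translated-search contracts: six-frame translation against an independent
codon-table oracle, seed-and-extend against brute-force best-diagonal-segment
search, Karlin-Altschul E-value behaviour, and the virus/nonvirus best-hit
arbitration rules."""

import math

import numpy as np
import pytest

from conftest import random_dna, random_protein
from viroseek import classify as cls
from viroseek import synthetic_data as sd
from viroseek._sequtils import revcomp
from viroseek.records import AlignmentHit, ProteinDbRecord

PARAMS = cls.ClassifyParams()


def back_translate(pep, rng):
    return "".join(
        sd._CODONS[a][rng.integers(0, len(sd._CODONS[a]))] for a in pep
    )


class TestSixFrame:
    def test_standard_code(self):
        frames = dict(cls.six_frame_translate("ATGAAA"))
        assert frames[1] == "MK"

    def test_against_biopython_oracle(self):
        from Bio.Seq import Seq

        rng = np.random.default_rng(1)
        seq = random_dna(rng, 60)
        frames = dict(cls.six_frame_translate(seq))
        for f in (1, 2, 3):
            fwd = seq[f - 1 :]
            fwd = fwd[: len(fwd) - len(fwd) % 3]
            assert frames[f] == str(Seq(fwd).translate())
            rev = revcomp(seq)[f - 1 :]
            rev = rev[: len(rev) - len(rev) % 3]
            assert frames[-f] == str(Seq(rev).translate())

    def test_reverse_complement_swaps_frame_sets(self):
        rng = np.random.default_rng(2)
        seq = random_dna(rng, 99)  # multiple of 3 keeps frames aligned
        fwd = dict(cls.six_frame_translate(seq))
        rev = dict(cls.six_frame_translate(revcomp(seq)))
        assert {fwd[f] for f in (1, 2, 3)} == {rev[-f] for f in (1, 2, 3)}
        assert {fwd[-f] for f in (1, 2, 3)} == {rev[f] for f in (1, 2, 3)}


class TestEvalueModel:
    def test_strictly_decreasing_in_score(self):
        m = cls.ScoringModel(db_residue_count=10_000)
        es = [m.evalue(s, 100) for s in range(10, 200, 10)]
        assert all(a > b for a, b in zip(es, es[1:]))

    def test_doubling_database_doubles_evalue(self):
        a = cls.ScoringModel(db_residue_count=5_000).evalue(80, 120)
        b = cls.ScoringModel(db_residue_count=10_000).evalue(80, 120)
        assert b == pytest.approx(2 * a)

    def test_bit_score_definition(self):
        m = cls.ScoringModel()
        s = 100.0
        assert m.bit_score(s) == pytest.approx(
            (m.lambda_ * s - math.log(m.K)) / math.log(2)
        )


def brute_force_best_segment(query_nt, subject_res, matrix):
    """Independent oracle: over all 6 frames and all diagonals, the best
    contiguous ungapped segment score (stop codons split diagonals)."""
    best = (-math.inf, None)
    for frame, pep in cls.six_frame_translate(query_nt):
        for diag in range(-len(pep) + 1, len(subject_res)):
            lo = max(0, -diag)
            hi = min(len(pep), len(subject_res) - diag)
            run, run_start, cur = -math.inf, lo, 0.0
            start = lo
            for i in range(lo, hi):
                a, b = pep[i], subject_res[i + diag]
                if a == "*" or b == "*":
                    cur, start = 0.0, i + 1
                    continue
                s = matrix.get(a, {}).get(b, -4)
                if cur <= 0:
                    cur, start = s, i
                else:
                    cur += s
                if cur > run:
                    run, run_start = cur, start
                    run_end = i + 1
                if cur < 0:
                    cur = 0.0
            if run > best[0]:
                best = (run, (frame, run_start, run_end, diag))
    return best


@pytest.fixture(scope="module")
def db():
    rng = np.random.default_rng(7)
    recs = [
        ProteinDbRecord(f"v{i}", random_protein(rng, 200), "virus", f"taxon{i}")
        for i in range(20)
    ]
    return cls.ProteinDatabase(recs)


class TestTranslatedSearch:
    def test_exact_cds_fragment_tops_with_tiny_evalue(self, db):
        rng = np.random.default_rng(8)
        rec = db.records[3]
        cds = back_translate(rec.residues[50:100], rng)  # 150 nt
        query = random_dna(rng, 75) + cds + random_dna(rng, 75)
        model = cls.ScoringModel(db_residue_count=db.residue_count)
        hits = cls.translated_search("q", query, db, model, PARAMS)
        assert hits and hits[0].subject_id == "v3"
        assert hits[0].evalue < 1e-10

    def test_self_backtranslation_scores_blosum_diagonal_sum(self, db):
        rng = np.random.default_rng(9)
        rec = db.records[0]
        query = back_translate(rec.residues, rng)
        model = cls.ScoringModel(db_residue_count=db.residue_count)
        hits = cls.translated_search("q", query, db, model, PARAMS)
        top = hits[0]
        expected = sum(cls.BLOSUM62[a][a] for a in rec.residues)
        assert top.subject_id == "v0"
        assert top.raw_score == expected
        assert top.percent_identity == 100.0

    def test_random_queries_rarely_hit(self, db):
        rng = np.random.default_rng(10)
        model = cls.ScoringModel(db_residue_count=db.residue_count)
        n_hit = 0
        for _ in range(20):
            q = random_dna(rng, 300)
            if cls.translated_search("q", q, db, model, PARAMS):
                n_hit += 1
        assert n_hit <= 1  # >= 95% of trials stay below the candidate cutoff

    def test_against_brute_force_diagonal_oracle(self, db):
        """50 constructed (query, subject) pairs with a guaranteed seed word:
        top hit raw score and intervals equal the full-matrix search."""
        rng = np.random.default_rng(11)
        model = cls.ScoringModel(db_residue_count=db.residue_count)
        sub = "ACDEFGHIKLMNPQRSTVWY"
        for trial in range(50):
            rec = db.records[int(rng.integers(0, len(db.records)))]
            s0 = int(rng.integers(0, len(rec.residues) - 60))
            window = list(rec.residues[s0 : s0 + 60])
            for j in range(len(window)):  # ~10% divergence keeps a seed
                if rng.random() < 0.10:
                    window[j] = sub[rng.integers(0, 20)]
            query = (
                random_dna(rng, 30)
                + back_translate("".join(window), rng)
                + random_dna(rng, 30)
            )
            single = cls.ProteinDatabase([rec])
            hits = cls.translated_search("q", query, single, model, PARAMS,
                                         evalue_cutoff=math.inf)
            assert hits, f"trial {trial}: no hit"
            top = hits[0]
            b_score, (b_frame, b_qs, b_qe, b_diag) = brute_force_best_segment(
                query, rec.residues, cls.BLOSUM62
            )
            assert top.raw_score == b_score, f"trial {trial}"
            assert top.frame == b_frame
            assert top.query_interval == cls._nt_interval(b_frame, b_qs, b_qe, len(query))
            assert top.subject_interval == (b_qs + b_diag, b_qe + b_diag)

    def test_query_shorter_than_codon_is_empty(self, db):
        model = cls.ScoringModel(db_residue_count=db.residue_count)
        assert cls.translated_search("q", "AT", db, model, PARAMS) == []


@pytest.fixture(scope="module")
def setup():
    rng = np.random.default_rng(20)
    viral_pep = random_protein(rng, 150)
    host_pep = random_protein(rng, 150)
    recs = [
        ProteinDbRecord("vir1", viral_pep, "virus", "spiked_virus"),
        ProteinDbRecord("host1", host_pep, "nonvirus", "host"),
        # the same protein under both labels: an exact ranking tie
        ProteinDbRecord("twin_v", host_pep, "virus", "ambiguous"),
    ]
    return rng, viral_pep, host_pep, recs


class TestArbitration:
    def test_host_derived_candidate_removed(self, setup):
        rng, viral_pep, host_pep, recs = setup
        combined = cls.ProteinDatabase(recs)
        viral_db = cls.ProteinDatabase([r for r in recs if r.label == "virus"])
        model = cls.ScoringModel()
        q = cls.Query("hostq", back_translate(host_pep, rng), "contig")
        cands = cls.viral_candidates([q], viral_db, model, PARAMS)
        assert "hostq" in cands  # twin_v matches it in the viral db
        retained = cls.nr_filter(cands, [q], combined, model, PARAMS)
        # identical virus/nonvirus hits tie; nonvirus preferred -> removed
        assert retained == {}

    def test_purely_viral_candidate_retained(self, setup):
        rng, viral_pep, host_pep, recs = setup
        combined = cls.ProteinDatabase(recs)
        viral_db = cls.ProteinDatabase([r for r in recs if r.label == "virus"])
        model = cls.ScoringModel()
        q = cls.Query("virq", back_translate(viral_pep, rng), "contig")
        cands = cls.viral_candidates([q], viral_db, model, PARAMS)
        retained = cls.nr_filter(cands, [q], combined, model, PARAMS)
        assert list(retained) == ["virq"]
        top = retained["virq"]["best_combined_hit"]
        assert top.subject_label == "virus"
        # the winning combined hit is the same alignment the viral search found
        assert top.raw_score == retained["virq"]["viral_hit"].raw_score


class TestSummarize:
    @staticmethod
    def fake_hit(qid, taxon, evalue):
        return {
            "viral_hit": None,
            "best_combined_hit": AlignmentHit(
                query_id=qid, frame=1, query_interval=(0, 300),
                subject_id=f"{taxon}|p", subject_interval=(0, 100),
                raw_score=100, bit_score=40, evalue=evalue,
                percent_identity=80, subject_label="virus", subject_taxon=taxon,
            ),
        }

    def test_two_spiked_taxa_flagged(self):
        retained = {
            "c1": self.fake_hit("c1", "taxA", 1e-200),
            "c2": self.fake_hit("c2", "taxB", 1e-50),
        }
        queries = [cls.Query("c1", "", "contig"), cls.Query("c2", "", "contig")]
        rep = cls.summarize_virome(retained, queries, PARAMS)
        assert len(rep) == 2 and rep["detected"].all()

    def test_weak_taxon_present_but_not_flagged(self):
        retained = {"c1": self.fake_hit("c1", "taxA", 1e-5)}
        rep = cls.summarize_virome(retained, [cls.Query("c1", "", "contig")], PARAMS)
        assert len(rep) == 1 and not rep["detected"].iloc[0]

    def test_empty_report(self):
        rep = cls.summarize_virome({}, [], PARAMS)
        assert len(rep) == 0


def test_end_to_end_synthetic_classification(small_community):
    """Contigs from spiked genomes with ~65%-identity homologs in the db are
    retained; host sequence is removed."""
    db_records = sd.make_protein_db(small_community, 99)
    viral_db = cls.ProteinDatabase([r for r in db_records if r.label == "virus"])
    combined = cls.ProteinDatabase(db_records)
    model = cls.ScoringModel()
    queries = []
    for m in small_community.members:
        if m.kind == "viral":
            queries.append(cls.Query(m.genome.label, m.genome.seq, "contig"))
    host = next(m.genome for m in small_community.members if m.kind == "host")
    queries.append(cls.Query("host_fragment", host.seq[5000:9600], "contig"))

    cands = cls.viral_candidates(queries, viral_db, model, PARAMS)
    retained = cls.nr_filter(cands, queries, combined, model, PARAMS)
    kept = set(retained)
    assert {m.genome.label for m in small_community.members if m.kind == "viral"} <= kept
    assert "host_fragment" not in kept
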