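"""Translated homology classification of contigs and singlet reads.

Queries are translated in all six frames and searched against a labelled
protein database by exact-word seeding and ungapped X-drop extension under
BLOSUM62.  Significance uses the ungapped Karlin-Altschul statistic
``E = K * m * n * exp(-lambda * S)`` with m the translated query length and n
the total database residue count (no edge-effect length correction — a
deliberate simplification documented in the methods note).

Candidate queries are those whose best hit against the *viral* database has
E below ``candidate_evalue_cutoff`` (default 0.01).  Each candidate is then
re-searched against the combined virus + nonvirus database and kept only if
the top-ranked hit (lowest E, then highest raw score, residual ties resolved
toward nonvirus, then by record id) is labelled virus.  A taxon is flagged as
a mammalian-virus detection when its best E-value falls below
``report_evalue_cutoff`` (default 1e-10).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from ._sequtils import revcomp, read_fasta
from .records import AlignmentHit, ProteinDbRecord
from .synthetic_data import _translate_frame

#: Standard ungapped BLOSUM62 Karlin-Altschul parameters.
UNGAPPED_LAMBDA = 0.3176
UNGAPPED_K = 0.134


def _blosum62():
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    table: dict = {}
    for a in mat.alphabet:
        row = {}
        for b in mat.alphabet:
            row[b] = int(mat[a, b])
        table[a] = row
    return table


BLOSUM62 = _blosum62()


@dataclass
class ScoringModel:
    matrix: dict = field(default_factory=lambda: BLOSUM62)
    lambda_: float = UNGAPPED_LAMBDA
    K: float = UNGAPPED_K
    db_residue_count: int = 0

    def __post_init__(self):
        if self.lambda_ <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")

    def evalue(self, raw_score: float, query_len: int) -> float:
        x = -self.lambda_ * raw_score
        # exp underflow is fine (E -> 0); guard overflow for tiny scores
        if x > 700:
            return math.inf
        return self.K * query_len * self.db_residue_count * math.exp(x)

    def bit_score(self, raw_score: float) -> float:
        return (self.lambda_ * raw_score - math.log(self.K)) / math.log(2)


@dataclass
class ClassifyParams:
    candidate_evalue_cutoff: float = 0.01
    report_evalue_cutoff: float = 1e-10
    seed_word_length: int = 4
    xdrop: float = 15.0
    #: E-value ceiling when ranking hits against the combined database — the
    #: arbitration rule needs an ordering, not a significance cutoff
    max_rank_evalue: float = 10.0


def six_frame_translate(sequence: str) -> list:
    """All six translations of a nucleotide sequence.

    Returns [(frame, peptide)] for frames +1..+3 (forward strand) and -1..-3
    (reverse complement).  Stop codons are emitted as '*'; trailing partial
    codons are dropped.
    """
    out = []
    for strand_sign, seq in ((1, sequence), (-1, revcomp(sequence))):
        for f in range(3):
            sub = seq[f:]
            sub = sub[: len(sub) - (len(sub) % 3)]
            out.append((strand_sign * (f + 1), _translate_frame(sub)))
    return out


class ProteinDatabase:
    """Protein records plus a word index for seeded search."""

    def __init__(self, records, word_length: int = 4):
        self.records = list(records)
        self.residue_count = sum(len(r.residues) for r in self.records)
        self.word_length = word_length
        self._index: dict = {}
        for ri, rec in enumerate(self.records):
            res = rec.residues
            for i in range(len(res) - word_length + 1):
                w = res[i : i + word_length]
                if "*" in w:
                    continue
                self._index.setdefault(w, []).append((ri, i))

    def __len__(self):
        return len(self.records)

    @classmethod
    def from_fasta(cls, path, word_length: int = 4) -> "ProteinDatabase":
        """Load records from FASTA with ``label=...`` / ``taxon=...`` (and
        optional ``family=...``) key-value pairs in the description line."""
        records = []
        for header, seq in read_fasta(path):
            fields = header.split()
            kv = dict(f.split("=", 1) for f in fields[1:] if "=" in f)
            records.append(
                ProteinDbRecord(
                    id=fields[0],
                    residues=seq,
                    label=kv.get("label", "virus"),
                    taxon=kv.get("taxon", fields[0]),
                    family=kv.get("family"),
                )
            )
        return cls(records, word_length)


def _extend_ungapped(qpep: str, spep: str, qpos: int, spos: int, w: int,
                     matrix: dict, xdrop: float):
    """Bidirectional ungapped X-drop extension around an exact seed word.

    Returns (raw_score, q_start, q_end, s_start, s_end) of the best-scoring
    segment containing the seed; stop-codon columns terminate extension.
    """
    row = matrix
    score = 0.0
    for i in range(w):
        score += row[qpep[qpos + i]][spep[spos + i]]
    best = score
    best_qe = qpos + w
    # right
    cur = score
    i, j = qpos + w, spos + w
    nq, ns = len(qpep), len(spep)
    while i < nq and j < ns:
        a, b = qpep[i], spep[j]
        if a == "*" or b == "*":
            break
        cur += row.get(a, {}).get(b, -4)
        if cur > best:
            best, best_qe = cur, i + 1
        if best - cur > xdrop:
            break
        i += 1
        j += 1
    # left
    score_r = best
    cur = best
    best_qs = qpos
    i, j = qpos - 1, spos - 1
    while i >= 0 and j >= 0:
        a, b = qpep[i], spep[j]
        if a == "*" or b == "*":
            break
        cur += row.get(a, {}).get(b, -4)
        if cur > score_r:
            score_r, best_qs = cur, i
        if score_r - cur > xdrop:
            break
        i -= 1
        j -= 1
    diag = spos - qpos
    return score_r, best_qs, best_qe, best_qs + diag, best_qe + diag


def _nt_interval(frame: int, q_start: int, q_end: int, nt_len: int):
    """Map a peptide interval in a translation frame to forward-strand
    nucleotide coordinates (0-based half-open)."""
    off = abs(frame) - 1
    if frame > 0:
        return (off + 3 * q_start, off + 3 * q_end)
    return (nt_len - (off + 3 * q_end), nt_len - (off + 3 * q_start))


def translated_search(query_id: str, sequence: str, db: ProteinDatabase,
                      model: ScoringModel, params: ClassifyParams,
                      evalue_cutoff: float | None = None) -> list:
    """Six-frame seeded ungapped search of one nucleotide query.

    Returns AlignmentHits with E below ``evalue_cutoff`` (default: the
    candidate cutoff), sorted by (evalue, -raw_score, subject_id, frame).
    One extension is performed per (subject, frame, diagonal).
    """
    cutoff = params.candidate_evalue_cutoff if evalue_cutoff is None else evalue_cutoff
    w = params.seed_word_length
    if len(sequence) < 3:
        return []
    hits = []
    n = model.db_residue_count or db.residue_count
    for frame, pep in six_frame_translate(sequence):
        m = len(pep)
        if m < w:
            continue
        tried = set()
        for qpos in range(m - w + 1):
            word = pep[qpos : qpos + w]
            if "*" in word:
                continue
            for ri, spos in db._index.get(word, ()):
                diag = spos - qpos
                key = (ri, diag)
                if key in tried:
                    continue
                tried.add(key)
                rec = db.records[ri]
                raw, qs, qe, ss, se = _extend_ungapped(
                    pep, rec.residues, qpos, spos, w, model.matrix, params.xdrop
                )
                ev = model.K * m * n * math.exp(max(-700, -model.lambda_ * raw))
                if ev >= cutoff:
                    continue
                ident = sum(
                    1 for a, b in zip(pep[qs:qe], rec.residues[ss:se]) if a == b
                )
                hits.append(
                    AlignmentHit(
                        query_id=query_id,
                        frame=frame,
                        query_interval=_nt_interval(frame, qs, qe, len(sequence)),
                        subject_id=rec.id,
                        subject_interval=(ss, se),
                        raw_score=raw,
                        bit_score=model.bit_score(raw),
                        evalue=ev,
                        percent_identity=100.0 * ident / max(1, qe - qs),
                        subject_label=rec.label,
                        subject_taxon=rec.taxon,
                    )
                )
    hits.sort(key=lambda h: (h.evalue, -h.raw_score, h.subject_id, h.frame))
    # keep the best hit per (subject, frame, interval) to avoid seed-duplicates
    seen = set()
    uniq = []
    for h in hits:
        key = (h.subject_id, h.frame, h.query_interval, h.subject_interval)
        if key not in seen:
            seen.add(key)
            uniq.append(h)
    return uniq


@dataclass
class Query:
    id: str
    sequence: str
    kind: str = "contig"  # "contig" | "read"


def viral_candidates(queries, viral_db: ProteinDatabase, model: ScoringModel,
                     params: ClassifyParams) -> dict:
    """Queries whose best viral-database hit has E < candidate cutoff.

    Returns {query_id: best viral AlignmentHit}.
    """
    model = ScoringModel(model.matrix, model.lambda_, model.K, viral_db.residue_count)
    out = {}
    for q in queries:
        hits = translated_search(q.id, q.sequence, viral_db, model, params)
        if hits:
            out[q.id] = hits[0]
    return out


def _rank_key(hit: AlignmentHit):
    # lowest E first; raw score desc; residual ties prefer nonvirus (the
    # conservative direction for the removal filter); then record id
    return (hit.evalue, -hit.raw_score, 0 if hit.subject_label == "nonvirus" else 1, hit.subject_id)


def nr_filter(candidates: dict, queries, combined_db: ProteinDatabase,
              model: ScoringModel, params: ClassifyParams) -> dict:
    """Best-hit virus/nonvirus arbitration against the combined database.

    Each candidate's hits (E < max_rank_evalue) are ranked; the candidate is
    retained iff the top-ranked hit is labelled virus.  Returns
    {query_id: {"viral_hit": ..., "best_combined_hit": ...}}.
    """
    model = ScoringModel(model.matrix, model.lambda_, model.K, combined_db.residue_count)
    seq_by_id = {q.id: q.sequence for q in queries}
    retained = {}
    for qid, viral_hit in candidates.items():
        hits = translated_search(qid, seq_by_id[qid], combined_db, model, params,
                                 evalue_cutoff=params.max_rank_evalue)
        if not hits:
            continue
        hits.sort(key=_rank_key)
        top = hits[0]
        if top.subject_label == "virus":
            retained[qid] = {"viral_hit": viral_hit, "best_combined_hit": top}
    return retained


def summarize_virome(retained: dict, queries, params: ClassifyParams) -> pd.DataFrame:
    """Per-taxon virome report.

    Groups retained calls by the taxon of the best combined hit and reports
    query counts (contigs vs reads), total aligned nucleotides, best E-value
    and the mammalian-virus detection flag (best E < report cutoff).  Rows
    are ordered by best E-value.
    """
    kind_by_id = {q.id: q.kind for q in queries}
    rows: dict = {}
    for qid, call in retained.items():
        hit = call["best_combined_hit"]
        taxon = hit.subject_taxon
        row = rows.setdefault(
            taxon,
            {"taxon": taxon, "n_contigs": 0, "n_reads": 0, "aligned_bases": 0,
             "best_evalue": math.inf},
        )
        if kind_by_id.get(qid, "contig") == "contig":
            row["n_contigs"] += 1
        else:
            row["n_reads"] += 1
        row["aligned_bases"] += hit.query_interval[1] - hit.query_interval[0]
        row["best_evalue"] = min(row["best_evalue"], hit.evalue)
    for row in rows.values():
        row["detected"] = bool(row["best_evalue"] < params.report_evalue_cutoff)
    df = pd.DataFrame(
        sorted(rows.values(), key=lambda r: (r["best_evalue"], r["taxon"])),
        columns=["taxon", "n_contigs", "n_reads", "aligned_bases", "best_evalue", "detected"],
    )
    return df


def hits_to_table(hits) -> pd.DataFrame:
    """BLAST outfmt-6-style tabular export with label/taxon columns."""
    rows = []
    for h in hits:
        rows.append(
            {
                "qseqid": h.query_id,
                "sseqid": h.subject_id,
                "pident": round(h.percent_identity, 2),
                "length": (h.subject_interval[1] - h.subject_interval[0]),
                "qstart": h.query_interval[0] + 1,
                "qend": h.query_interval[1],
                "sstart": h.subject_interval[0] + 1,
                "send": h.subject_interval[1],
                "frame": h.frame,
                "bitscore": round(h.bit_score, 1),
                "evalue": h.evalue,
                "raw_score": h.raw_score,
                "label": h.subject_label,
                "taxon": h.subject_taxon,
            }
        )
    return pd.DataFrame(rows)
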