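"""Genome annotation: ORF finding on linear and circular genomes, a
degenerate protein-motif grammar, hallmark-motif panels for parvovirus
NS1/VP1 and polyomavirus LT, and the ICTV-style parvovirus species
demarcation rule (NS1 < 85% identical to any known parvovirus NS1).

Motif notation grammar (left-to-right, single pass):

* lowercase ``x``          — any residue
* lowercase ``u``          — uncharged residue (D, E, K, R and H excluded)
* ``-``                    — any residue or none (optional position)
* uppercase letter         — exactly that residue
* ``P/Q`` (slash chain)    — one position accepting any listed residue
* uppercase ``X``          — any residue

Examples: ``GxxxxGKT/S`` (Walker A), ``uuuuD/ED/E`` (Walker B),
``xuHuHuuux`` / ``uxxYux-Kxx`` (rolling-circle replication), ``LXCXE``
(Rb binding), ``CXXC`` (zinc binding).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Callable, Optional

import yaml

from ._sequtils import revcomp
from .synthetic_data import _translate_frame

#: Residues treated as uncharged: the 20 standard residues minus D, E, K, R
#: and histidine (treated as charged).  Configurable via compile_motif.
UNCHARGED = frozenset("ACFGILMNPQSTVWY")

_KIND_EXACT, _KIND_ANY, _KIND_UNCHARGED, _KIND_OPT_ANY = "exact", "any", "uncharged", "opt_any"


@dataclass(frozen=True)
class MotifToken:
    kind: str
    residues: Optional[frozenset] = None

    def matches(self, residue: str, uncharged=UNCHARGED) -> bool:
        if self.kind == _KIND_EXACT:
            return residue in self.residues
        if self.kind == _KIND_UNCHARGED:
            return residue in uncharged
        return True  # any / opt_any (when consuming)


@dataclass
class MotifPattern:
    name: str
    tokens: list
    source_notation: str
    uncharged: frozenset = UNCHARGED

    @property
    def min_length(self) -> int:
        return sum(1 for t in self.tokens if t.kind != _KIND_OPT_ANY)

    @property
    def max_length(self) -> int:
        return len(self.tokens)


@dataclass
class MotifMatch:
    pattern_name: str
    protein_id: str
    start: int  # 0-based residue offset
    window: str
    used_optional: bool = False


class MotifParseError(ValueError):
    pass


def compile_motif(notation: str, name: Optional[str] = None,
                  uncharged: frozenset = UNCHARGED) -> MotifPattern:
    """Compile degenerate motif notation into a token list.

    Raises MotifParseError (naming the offset) on a dangling ``/`` and on
    patterns with no mandatory position.
    """
    tokens = []
    i, n = 0, len(notation)
    while i < n:
        c = notation[i]
        if c == "x":
            tokens.append(MotifToken(_KIND_ANY))
            i += 1
        elif c == "u":
            tokens.append(MotifToken(_KIND_UNCHARGED))
            i += 1
        elif c == "-":
            tokens.append(MotifToken(_KIND_OPT_ANY))
            i += 1
        elif c == "/":
            raise MotifParseError(f"{notation!r}: dangling '/' at offset {i}")
        elif c.isalpha() and c.isupper():
            residues = {c}
            i += 1
            while i < n and notation[i] == "/":
                if i + 1 >= n or not (notation[i + 1].isalpha() and notation[i + 1].isupper()):
                    raise MotifParseError(f"{notation!r}: dangling '/' at offset {i}")
                residues.add(notation[i + 1])
                i += 2
            if residues == {"X"}:
                tokens.append(MotifToken(_KIND_ANY))
            else:
                tokens.append(MotifToken(_KIND_EXACT, frozenset(residues)))
        else:
            raise MotifParseError(f"{notation!r}: unexpected character {c!r} at offset {i}")
    if not any(t.kind != _KIND_OPT_ANY for t in tokens):
        raise MotifParseError(f"{notation!r}: pattern has no mandatory position")
    return MotifPattern(name or notation, tokens, notation, uncharged)


def _match_at(protein: str, offset: int, pattern: MotifPattern):
    """All (consumed_length, used_optional) variants matching at ``offset``.

    Optional positions are tried both consuming 0 and 1 residues; distinct
    consumed lengths are reported separately.
    """
    results = set()

    def walk(ti: int, pos: int, used: bool):
        if ti == len(pattern.tokens):
            results.add((pos - offset, used))
            return
        tok = pattern.tokens[ti]
        if tok.kind == _KIND_OPT_ANY:
            walk(ti + 1, pos, used)  # consume nothing
            if pos < len(protein):
                walk(ti + 1, pos + 1, True)
            return
        if pos < len(protein) and tok.matches(protein[pos], pattern.uncharged):
            walk(ti + 1, pos + 1, used)

    walk(0, offset, False)
    return results


def scan_motifs(protein: str, patterns, protein_id: str = "protein") -> list:
    """Every window of ``protein`` matching any compiled pattern.

    Matches are reported per offset and per optional-consumption variant,
    ordered by (pattern order, offset, window length).
    """
    out = []
    for pat in patterns:
        for offset in range(len(protein) - pat.min_length + 1):
            for consumed, used in sorted(_match_at(protein, offset, pat)):
                out.append(
                    MotifMatch(pat.name, protein_id, offset,
                               protein[offset : offset + consumed], used)
                )
    return out


# --- ORF finding ------------------------------------------------------------


@dataclass
class OrfRecord:
    genome_id: str
    strand: str
    start: int  # 0-based half-open, forward strand; end may exceed length
    end: int
    wraps_origin: bool
    peptide: str

    @property
    def length_nt(self) -> int:
        return self.end - self.start


def _scan_strand(seq: str, L: int, circular: bool):
    """ATG-initiated, stop-terminated ORFs in strand-local coordinates.

    Circular genomes are scanned as a tripled string: an ORF is accepted only
    once an in-frame stop has been seen (so its ATG has true upstream
    context) and only when its start falls in the middle copy, which reports
    every circular ORF exactly once regardless of rotation.
    """
    scan = seq * 3 if circular else seq
    lo, hi = (L, 2 * L) if circular else (0, L)
    found = []
    for f in range(3):
        start = None
        armed = not circular  # linear 5' ends have genuine upstream context
        for i in range(f, len(scan) - 2, 3):
            codon = scan[i : i + 3]
            if codon in ("TAA", "TAG", "TGA"):
                if armed and start is not None and lo <= start < hi:
                    found.append((start - lo, i + 3 - lo))
                start = None
                armed = True
            elif codon == "ATG" and start is None:
                start = i
    return found


def find_orfs(genome: str, circular: bool = False, min_orf_length: int = 100,
              genome_id: str = "genome") -> list:
    """ORFs on both strands; ``min_orf_length`` is in codons (peptide length).

    For circular genomes the sequence is scanned as a doubled string; ORFs
    wrapping the origin are reported once with ``wraps_origin=True`` and ORFs
    longer than the genome are rejected.
    """
    L = len(genome)
    orfs = []
    for strand in "+-":
        s = genome if strand == "+" else revcomp(genome)
        for a, b in _scan_strand(s, L, circular):
            if b - a > L:
                continue
            pep = _translate_frame((s + s)[a:b])[:-1]  # drop the stop
            if len(pep) < min_orf_length:
                continue
            if strand == "+":
                start, end = a, b
            else:
                start = (L - b) % L
                end = start + (b - a)
            orfs.append(
                OrfRecord(genome_id, strand, start, end, end > L, pep)
            )
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


# --- hallmark panels --------------------------------------------------------


def load_panels(path=None) -> dict:
    """Load the hallmark panel registry (name -> {motif_name: MotifPattern}).

    The shipped registry defines parvovirus_NS1, parvovirus_VP1 and
    polyomavirus_LT panels in the degenerate notation above.
    """
    if path is None:
        ref = importlib.resources.files("viroseek").joinpath("data/panels.yaml")
        doc = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    panels = {}
    for panel_name, motifs in doc["panels"].items():
        panels[panel_name] = {
            mname: compile_motif(notation, name=mname) for mname, notation in motifs.items()
        }
    return panels


_PANEL_VERDICTS = {
    "parvovirus_NS1": "consistent with parvovirus NS1",
    "parvovirus_VP1": "consistent with parvovirus VP1",
    "polyomavirus_LT": "consistent with polyomavirus LT",
}


@dataclass
class PanelResult:
    panel: str
    motif_hits: dict  # motif name -> list[MotifMatch]
    satisfied: bool


def _evaluate_panel(orf: OrfRecord, panel_name: str, patterns: dict,
                    vp1_n_terminal_fraction: float = 1 / 3,
                    pla2_d_gap: tuple = (20, 60)) -> PanelResult:
    pep = orf.peptide
    region = pep
    if panel_name == "parvovirus_VP1":
        region = pep[: max(1, int(len(pep) * vp1_n_terminal_fraction))]
    hits = {name: scan_motifs(region, [pat], protein_id=orf.genome_id)
            for name, pat in patterns.items()}
    if panel_name == "parvovirus_VP1" and "pla2_hd" in patterns and "pla2_d" in patterns:
        # the catalytic D must lie 20-60 residues downstream of an HD hit
        lo, gap_hi = pla2_d_gap
        valid_d = []
        for hd in hits.get("pla2_hd", []):
            hd_end = hd.start + len(hd.window)
            for d in hits.get("pla2_d", []):
                if lo <= d.start - hd_end <= gap_hi:
                    valid_d.append(d)
        hits["pla2_d"] = valid_d
    satisfied = all(len(v) > 0 for v in hits.values())
    return PanelResult(panel_name, hits, satisfied)


def hallmark_report(orfs, panels: Optional[dict] = None,
                    vp1_n_terminal_fraction: float = 1 / 3,
                    pla2_d_gap: tuple = (20, 60)) -> dict:
    """Evaluate every ORF against every hallmark panel.

    Returns {"orfs": {orf_key: {panel: PanelResult}}, "verdicts": [...]}; a
    verdict is issued for each panel fully satisfied by some ORF.
    """
    if panels is None:
        panels = load_panels()
    per_orf = {}
    satisfied_panels = set()
    for i, orf in enumerate(orfs):
        key = f"{orf.genome_id}:{orf.strand}:{orf.start}-{orf.end}"
        per_orf[key] = {}
        for panel_name, patterns in panels.items():
            res = _evaluate_panel(orf, panel_name, patterns,
                                  vp1_n_terminal_fraction, pla2_d_gap)
            per_orf[key][panel_name] = res
            if res.satisfied:
                satisfied_panels.add(panel_name)
    verdicts = [_PANEL_VERDICTS.get(p, p) for p in sorted(satisfied_panels)]
    return {"orfs": per_orf, "verdicts": verdicts}


# --- species demarcation ----------------------------------------------------


@dataclass
class DemarcationParams:
    ns1_identity_threshold: float = 85.0  # percent; strict "<" for novelty


@dataclass
class DemarcationDecision:
    max_identity: float
    closest_reference: Optional[str]
    is_new_species_candidate: bool
    per_reference: dict = field(default_factory=dict)


def species_demarcation(query_ns1: str, reference_ns1s: dict,
                        params: DemarcationParams = DemarcationParams(),
                        aligner: Optional[Callable] = None) -> DemarcationDecision:
    """ICTV-style demarcation: a genome is a new-species candidate iff its
    NS1 is strictly less than the threshold identity to every reference NS1.

    ``aligner(a, b) -> percent identity`` defaults to a global affine
    alignment under BLOSUM62 (see the compare module).
    """
    if aligner is None:
        from .compare import align_pair

        def aligner(a, b):
            return align_pair(a, b, mode="global").percent_identity

    per_ref = {name: aligner(query_ns1, ref) for name, ref in reference_ns1s.items()}
    if per_ref:
        closest = max(sorted(per_ref), key=lambda n: per_ref[n])
        max_ident = per_ref[closest]
    else:
        closest, max_ident = None, 0.0
    return DemarcationDecision(
        max_identity=max_ident,
        closest_reference=closest,
        is_new_species_candidate=bool(max_ident < params.ns1_identity_threshold),
        per_reference=per_ref,
    )


# --- GFF3 export ------------------------------------------------------------


def write_gff3(path, genome_id: str, genome_length: int, orfs,
               motif_matches=None) -> None:
    """Write ORFs (and optional per-ORF motif matches) as GFF3.

    ``motif_matches`` maps an OrfRecord to a list of MotifMatch; motif
    coordinates are translated back to genome nucleotides (wrapped features
    on circular genomes keep end > length, as produced by find_orfs).
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome_id} 1 {genome_length}\n")
        for i, orf in enumerate(orfs):
            oid = f"orf{i:03d}"
            fh.write(
                "\t".join(
                    [genome_id, "viroseek", "CDS", str(orf.start + 1), str(orf.end),
                     ".", orf.strand, "0",
                     f"ID={oid};wraps_origin={str(orf.wraps_origin).lower()}"]
                ) + "\n"
            )
            for m in (motif_matches or {}).get(id(orf), []):
                if orf.strand == "+":
                    s = orf.start + 3 * m.start
                    e = s + 3 * len(m.window)
                else:
                    e = orf.end - 3 * m.start
                    s = e - 3 * len(m.window)
                fh.write(
                    "\t".join(
                        [genome_id, "viroseek", "sequence_motif", str(s + 1), str(e),
                         ".", orf.strand, ".",
                         f"Name={m.pattern_name};Parent={oid};window={m.window}"]
                    ) + "\n"
                )
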