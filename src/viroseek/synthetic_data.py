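"""Seeded synthetic communities for exercising the discovery pipeline.

The generator emulates the kind of sample a virome study starts from: a read
pool overwhelmingly dominated by host and bacterial DNA, carrying a handful of
low-abundance viral genomes, sequenced as ~250 bp paired-end reads with PCR
duplicates, quality-decayed 3' tails and adaptor run-through.  Two default
viral genomes are provided: a linear ~4.6 kb two-ORF genome with the
replication (NS1) and capsid (VP1) organisation typical of parvoviruses, and a
circular ~4.8 kb four-ORF genome with the VP2/VP1/ST/LT organisation typical
of polyomaviruses.  Each carries verbatim instances of the hallmark motifs the
annotation module scans for, recorded in a truth annotation so every
downstream stage can be checked against ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from ._sequtils import encode, decode, revcomp, write_fasta
from .records import Read, ProteinDbRecord

# Reverse-translation table: residue -> codons (standard code, no stops).
_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"],
    "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
}
_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Verbatim hallmark-motif instances planted in the default viral genomes.
#: NS1 carries NTPase Walker A/B loops and the two rolling-circle-replication
#: motifs; VP1 carries the phospholipase A2 catalytic HD/D residues and the
#: YLGPG calcium-binding loop; LT carries the DnaJ box, Rb-binding LXCXE, a
#: Walker A loop and three zinc-binding clusters.
DEFAULT_MOTIF_INSTANCES = {
    "walker_a": "GPASTGKS",
    "walker_b": "VIWIEE",
    "rcr_1": "TKLHTHLILG",
    "rcr_2": "VLTYTHKQT",
    "pla2_hd": "HD",
    "pla2_d": "D",
    "ca_binding": "YLGPG",
    "dnaj": "HPDKGG",
    "rb_binding": "LYCHE",
    "walker_a_lt": "GPINSGKT",
    "zn_cxxc": "CKDC",
    "zn_clvc": "CLVC",
    "zn_cfsc": "CFSC",
}

#: Nextera transposase read-through adaptor.
DEFAULT_ADAPTOR = "CTGTCTCTTATACACATCTCCGAGCCCACGAGAC"


class InfeasibleLayout(ValueError):
    """Raised when a genome spec cannot be realised (e.g. motif > ORF)."""


@dataclass
class OrfSpec:
    """One ORF in a genome layout.

    ``start``/``end`` are 0-based half-open nucleotide coordinates on the
    forward strand, including the start and stop codons; for circular genomes
    ``end`` may exceed the genome length to denote wrapping the origin.
    ``motifs`` lists (motif_id, residue instance) pairs embedded, in order,
    into the translated peptide.
    """

    name: str
    start: int
    end: int
    strand: str = "+"
    motifs: list = field(default_factory=list)
    #: residue offset of the first embedded instance and gap between instances
    motif_offset: int = 5
    motif_gap: int = 25


@dataclass
class GenomeSpec:
    label: str
    length: int
    topology: str = "linear"  # "linear" | "circular"
    orf_layout: list = field(default_factory=list)
    gc_fraction: float = 0.45

    def validate(self) -> None:
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"{self.label}: topology must be linear|circular")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError(f"{self.label}: gc_fraction outside [0,1]")
        occupied = np.zeros(self.length, dtype=bool)
        for orf in self.orf_layout:
            span = orf.end - orf.start
            if span <= 0 or span % 3:
                raise InfeasibleLayout(f"{self.label}/{orf.name}: ORF span must be a positive multiple of 3")
            if span > self.length:
                raise InfeasibleLayout(f"{self.label}/{orf.name}: ORF longer than genome")
            if orf.end > self.length and self.topology != "circular":
                raise InfeasibleLayout(f"{self.label}/{orf.name}: ORF extends past the end of a linear genome")
            idx = np.arange(orf.start, orf.end) % self.length
            if occupied[idx].any():
                raise InfeasibleLayout(f"{self.label}/{orf.name}: ORFs overlap")
            occupied[idx] = True


@dataclass
class OrfTruth:
    name: str
    start: int
    end: int  # may exceed genome length (wrapping)
    strand: str
    wraps_origin: bool
    peptide: str


@dataclass
class MotifTruth:
    orf_name: str
    motif_id: str
    instance: str
    residue_offset: int


@dataclass
class GenomeTruth:
    orfs: list = field(default_factory=list)
    motifs: list = field(default_factory=list)


@dataclass
class Genome:
    label: str
    seq: str
    topology: str
    truth: GenomeTruth

    def __len__(self) -> int:
        return len(self.seq)


def _build_peptide(orf: OrfSpec, pep_len: int, rng: np.random.Generator) -> tuple:
    """Random peptide of ``pep_len`` residues (leading M) with the ORF's motif
    instances planted at deterministic offsets."""
    if pep_len < 2:
        raise InfeasibleLayout(f"{orf.name}: ORF too short to encode a peptide")
    pep = ["M"] + [_AA[i] for i in rng.integers(0, 20, pep_len - 1)]
    placements = []
    cursor = max(1, orf.motif_offset)
    for motif_id, instance in orf.motifs:
        if cursor + len(instance) > pep_len:
            raise InfeasibleLayout(
                f"{orf.name}: motif {motif_id} ({instance!r}) does not fit in a {pep_len}-residue ORF"
            )
        pep[cursor : cursor + len(instance)] = list(instance)
        placements.append((motif_id, instance, cursor))
        cursor += len(instance) + orf.motif_gap
    return "".join(pep), placements


def _reverse_translate(pep: str, rng: np.random.Generator) -> str:
    return "".join(_CODONS[a][rng.integers(0, len(_CODONS[a]))] for a in pep)


def make_genome(spec: GenomeSpec, seed: int) -> Genome:
    """Realise a genome spec as a concrete sequence plus truth annotation.

    ORF nucleotide sequence is built by reverse-translating a random peptide
    (uniform codon choice) around the embedded motif instances, which
    guarantees stop-free ORFs containing the instances verbatim.  Circular
    genomes are stored as linear strings with a topology flag; wrapped ORFs
    are written with modular indexing.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    gc = spec.gc_fraction
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=spec.length, p=p).astype(np.uint8)
    seq = list(decode(codes))

    occupied = set()
    for orf in spec.orf_layout:
        occupied.update(p % spec.length for p in range(orf.start, orf.end))

    truth = GenomeTruth()
    for orf in spec.orf_layout:
        n_codons = (orf.end - orf.start) // 3
        pep_len = n_codons - 1  # last codon is the stop
        pep, placements = _build_peptide(orf, pep_len, rng)
        nt = _reverse_translate(pep, rng) + "TAA"
        if orf.strand == "-":
            nt = revcomp(nt)
        for i, base in enumerate(nt):
            seq[(orf.start + i) % spec.length] = base
        # plant an in-frame stop immediately upstream of the start codon so
        # the ORF's first ATG is its true start (truth peptide is exact)
        if orf.strand == "+":
            up = range(orf.start - 3, orf.start)
            up_codon = "TAA"
        else:
            up = range(orf.end, orf.end + 3)
            up_codon = revcomp("TAA")
        positions = [p % spec.length for p in up]
        in_bounds = all(0 <= p < spec.length for p in up) or spec.topology == "circular"
        if in_bounds and not any((p % spec.length) in occupied for p in up):
            for p, base in zip(positions, up_codon):
                seq[p] = base
        truth.orfs.append(
            OrfTruth(
                name=orf.name,
                start=orf.start,
                end=orf.end,
                strand=orf.strand,
                wraps_origin=orf.end > spec.length,
                peptide=pep,
            )
        )
        for motif_id, instance, off in placements:
            truth.motifs.append(MotifTruth(orf.name, motif_id, instance, off))
    return Genome(spec.label, "".join(seq), spec.topology, truth)


# --- read simulation --------------------------------------------------------


@dataclass
class ReadSimParams:
    """Paired-end simulation parameters.

    Qualities start at ``quality_start`` and decline linearly to
    ``quality_floor`` over the read, with per-base Gaussian jitter — this
    produces the sub-Q20 tails the quality trimmer is meant to remove.
    Substitution noise is independent of the quality track.
    """

    n_pairs: int = 10_000
    read_length: int = 250
    substitution_rate: float = 0.002
    quality_start: int = 37
    quality_floor: int = 15
    quality_jitter_sd: float = 2.0
    duplicate_fraction: float = 0.10
    adaptor_sequence: str = DEFAULT_ADAPTOR
    insert_mean: float = 350.0
    insert_sd: float = 60.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("substitution_rate", "duplicate_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.read_length < 56:
            raise ValueError("read_length must be >= 56 (duplicate key spans positions 5..55)")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be positive")


@dataclass
class CommunityMember:
    genome: Genome
    abundance: float
    kind: str = "viral"  # "host" | "bacterial" | "viral"


@dataclass
class CommunitySpec:
    members: list

    def validate(self) -> None:
        total = sum(m.abundance for m in self.members)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances sum to {total}, not 1")
        for m in self.members:
            if m.kind not in ("host", "bacterial", "viral"):
                raise ValueError(f"{m.genome.label}: unknown kind {m.kind!r}")


def _emit_pairs(genome: Genome, n: int, params: ReadSimParams, rng: np.random.Generator):
    """Vectorised simulation of n read pairs from one genome.

    Returns (r1 list, r2 list, rows) where each row is
    (source, start, insert, wraps_origin) describing the sequenced fragment.
    """
    G = len(genome.seq)
    L = params.read_length
    circular = genome.topology == "circular"
    inserts = np.clip(
        np.rint(rng.normal(params.insert_mean, params.insert_sd, n)), 3 * L // 5, None
    ).astype(np.int64)
    if not circular:
        if G < inserts.max():
            inserts = np.minimum(inserts, G)
        starts = (rng.random(n) * (G - inserts + 1)).astype(np.int64)
    else:
        starts = rng.integers(0, G, n)

    codes = encode(genome.seq)
    adaptor_codes = encode(params.adaptor_sequence)

    # forward-read and reverse-read index matrices (gather; mod for circular)
    offs = np.arange(L)
    r1_take = np.minimum(inserts, L)
    idx1 = (starts[:, None] + offs[None, :]) % G
    r1 = codes[idx1]
    idx2 = (starts[:, None] + inserts[:, None] - 1 - offs[None, :]) % G
    r2 = 3 - codes[idx2]  # complement of reversed fragment; no N in synthetic genomes

    # adaptor run-through where insert < read length
    short = np.nonzero(inserts < L)[0]
    for i in short:
        take = int(r1_take[i])
        tail_len = L - take
        tail = np.concatenate([adaptor_codes, rng.integers(0, 4, L).astype(np.uint8)])[:tail_len]
        r1[i, take:] = tail
        r2[i, take:] = tail

    # substitution noise, independent per base
    if params.substitution_rate > 0:
        for mat in (r1, r2):
            mask = rng.random(mat.shape) < params.substitution_rate
            shift = rng.integers(1, 4, mat.shape).astype(np.uint8)
            mat[mask] = (mat[mask] + shift[mask]) % 4

    # linear quality decay plus jitter
    profile = params.quality_start - (params.quality_start - params.quality_floor) * offs / (L - 1)
    q1 = np.clip(np.rint(profile[None, :] + rng.normal(0, params.quality_jitter_sd, (n, L))), 2, 41).astype(np.uint8)
    q2 = np.clip(np.rint(profile[None, :] + rng.normal(0, params.quality_jitter_sd, (n, L))), 2, 41).astype(np.uint8)

    wraps = (starts + inserts) > G if circular else np.zeros(n, dtype=bool)
    r1_seqs = [decode(r1[i]) for i in range(n)]
    r2_seqs = [decode(r2[i]) for i in range(n)]
    rows = list(zip([genome.label] * n, starts.tolist(), inserts.tolist(), wraps.tolist()))
    return r1_seqs, r2_seqs, q1, q2, rows


def simulate_reads(community: CommunitySpec, params: ReadSimParams):
    """Simulate a paired-end read pool from a community.

    Returns ``(r1_reads, r2_reads, truth)`` where truth is a DataFrame with
    one row per pair: pair_id, source, start, insert, wraps_origin,
    is_duplicate, duplicate_of.  Exactly ``round(duplicate_fraction*n_pairs)``
    pairs are byte-identical re-emissions of earlier pairs.  Genomes shorter
    than the smallest usable insert are skipped with a warning.
    """
    import pandas as pd

    community.validate()
    params.validate()
    rng = np.random.default_rng(params.seed)

    members = list(community.members)
    usable, abunds = [], []
    for m in members:
        if m.genome.topology == "linear" and len(m.genome.seq) < params.read_length:
            warnings.warn(f"genome {m.genome.label} shorter than a read; skipped")
            continue
        usable.append(m)
        abunds.append(m.abundance)
    if not usable:
        raise ValueError("no usable community members")
    abunds = np.asarray(abunds) / sum(abunds)

    n_dup = int(round(params.duplicate_fraction * params.n_pairs))
    n_unique = params.n_pairs - n_dup
    counts = rng.multinomial(n_unique, abunds)

    r1_seq, r2_seq, q1s, q2s, rows = [], [], [], [], []
    for m, c in zip(usable, counts):
        if c == 0:
            continue
        a, b, qa, qb, rr = _emit_pairs(m.genome, int(c), params, rng)
        r1_seq += a
        r2_seq += b
        q1s.append(qa)
        q2s.append(qb)
        rows += rr
    q1 = np.concatenate(q1s)
    q2 = np.concatenate(q2s)

    dup_of = [None] * n_unique
    dup_flag = [False] * n_unique
    if n_dup:
        src = rng.integers(0, n_unique, n_dup)
        for s in src:
            r1_seq.append(r1_seq[s])
            r2_seq.append(r2_seq[s])
            rows.append(rows[s])
            dup_of.append(s)
            dup_flag.append(True)
        q1 = np.concatenate([q1, q1[src]])
        q2 = np.concatenate([q2, q2[src]])

    order = rng.permutation(params.n_pairs)
    ids = [f"pair{i:06d}" for i in range(params.n_pairs)]

    r1_reads, r2_reads, trows = [], [], []
    for i in order:
        pid = ids[i]
        r1_reads.append(Read(pid + "/1", r1_seq[i], q1[i], mate=pid + "/2"))
        r2_reads.append(Read(pid + "/2", r2_seq[i], q2[i], mate=pid + "/1"))
        src, start, insert, wraps = rows[i]
        trows.append(
            {
                "pair_id": pid,
                "source": src,
                "start": start,
                "insert": insert,
                "wraps_origin": wraps,
                "is_duplicate": dup_flag[i],
                "duplicate_of": ids[dup_of[i]] if dup_flag[i] else "",
            }
        )
    truth = pd.DataFrame(trows)
    return r1_reads, r2_reads, truth


# --- default study community ------------------------------------------------


def parvovirus_like_spec(label: str = "parvovirus_hanchett_like") -> GenomeSpec:
    """Linear ~4.6 kb genome: NS1 (replication) + VP1 (capsid) ORFs carrying
    the Walker A/B, RCR and PLA2/calcium-loop hallmark instances."""
    m = DEFAULT_MOTIF_INSTANCES
    return GenomeSpec(
        label=label,
        length=4600,
        topology="linear",
        orf_layout=[
            OrfSpec(
                "NS1", 150, 2151, "+",
                motifs=[("walker_a", m["walker_a"]), ("walker_b", m["walker_b"]),
                        ("rcr_1", m["rcr_1"]), ("rcr_2", m["rcr_2"])],
            ),
            OrfSpec(
                "VP1", 2250, 4500, "+",
                motifs=[("pla2_hd", m["pla2_hd"]), ("pla2_d", m["pla2_d"]),
                        ("ca_binding", m["ca_binding"])],
            ),
        ],
        gc_fraction=0.42,
    )


def polyomavirus_like_spec(label: str = "polyomavirus_csl_like") -> GenomeSpec:
    """Circular 4.8 kb genome with VP2/VP1/ST/LT organisation; the LT ORF wraps
    the origin and carries the DnaJ, LXCXE, Walker A and zinc-cluster
    instances."""
    m = DEFAULT_MOTIF_INSTANCES
    return GenomeSpec(
        label=label,
        length=4800,
        topology="circular",
        orf_layout=[
            OrfSpec("VP2", 200, 1100, "+"),
            OrfSpec("VP1", 1150, 2350, "+"),
            OrfSpec("ST", 2400, 3000, "-"),
            OrfSpec(
                "LT", 3100, 4900, "+",
                motifs=[("dnaj", m["dnaj"]), ("rb_binding", m["rb_binding"]),
                        ("walker_a_lt", m["walker_a_lt"]), ("zn_cxxc", m["zn_cxxc"]),
                        ("zn_clvc", m["zn_clvc"]), ("zn_cfsc", m["zn_cfsc"])],
            ),
        ],
        gc_fraction=0.40,
    )


def default_demo_community(
    seed: int,
    n_pairs: int = 50_000,
    read_length: int = 250,
    viral_coverage: float = 30.0,
    host_length: int = 200_000,
    bacterial_length: int = 100_000,
) -> CommunitySpec:
    """The study community: one host genome, one bacterial genome and the two
    default viral genomes at a target viral fold-coverage, with the remaining
    read mass split between host and bacterium proportional to length."""
    host = make_genome(GenomeSpec("sea_lion_host", host_length, gc_fraction=0.41), seed + 11)
    bact = make_genome(GenomeSpec("gut_bacterium", bacterial_length, gc_fraction=0.50), seed + 13)
    parvo = make_genome(parvovirus_like_spec(), seed + 17)
    polyo = make_genome(polyomavirus_like_spec(), seed + 19)

    viral_fracs = {}
    for g in (parvo, polyo):
        pairs = viral_coverage * len(g.seq) / (2 * read_length)
        viral_fracs[g.label] = pairs / n_pairs
    rest = 1.0 - sum(viral_fracs.values())
    if rest <= 0:
        raise ValueError(
            f"{n_pairs} pairs cannot hold both viral genomes at "
            f"{viral_coverage}x coverage; increase n_pairs or lower viral_coverage"
        )
    denom = host_length + bacterial_length
    members = [
        CommunityMember(host, rest * host_length / denom, "host"),
        CommunityMember(bact, rest * bacterial_length / denom, "bacterial"),
        CommunityMember(parvo, viral_fracs[parvo.label], "viral"),
        CommunityMember(polyo, viral_fracs[polyo.label], "viral"),
    ]
    # absorb rounding so abundances sum to 1 exactly
    members[0].abundance += 1.0 - sum(m.abundance for m in members)
    return CommunitySpec(members)


# --- labelled protein database ----------------------------------------------


def _mutate_peptide(pep: str, identity: float, rng: np.random.Generator) -> str:
    out = list(pep)
    for i in range(len(out)):
        if rng.random() > identity:
            choices = _AA.replace(out[i], "") if out[i] in _AA else _AA
            out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def make_protein_db(
    community: CommunitySpec,
    seed: int,
    homolog_identity: float = 0.65,
    n_host_windows: int = 30,
    n_decoys: int = 5,
) -> list:
    """Build a small labelled protein database for the classification stage.

    Viral records are diverged homologs (point substitutions at
    ``1 - homolog_identity`` per residue) of each spiked ORF, one taxon per
    viral genome — emulating a reference proteome that contains related but
    distinct viral species.  Nonvirus records are in-frame translations of
    host/bacterial genome windows (stops replaced), plus a few random "virus"
    decoys from an unrelated taxon.
    """
    rng = np.random.default_rng(seed)
    records = []
    for m in community.members:
        if m.kind == "viral":
            taxon = m.genome.label + "_related"
            for orf in m.genome.truth.orfs:
                hom = _mutate_peptide(orf.peptide, homolog_identity, rng)
                records.append(
                    ProteinDbRecord(
                        id=f"{taxon}|{orf.name}",
                        residues=hom,
                        label="virus",
                        taxon=taxon,
                        family="synthetic_viral_family",
                    )
                )
        else:
            G = len(m.genome.seq)
            n_win = n_host_windows if m.kind == "host" else n_host_windows // 2
            for j in range(n_win):
                start = int(rng.integers(0, max(1, G - 903)))
                window = m.genome.seq[start : start + 900]
                pep = _translate_frame(window)
                pep = "".join(
                    c if c != "*" else _AA[rng.integers(0, 20)] for c in pep
                )
                records.append(
                    ProteinDbRecord(
                        id=f"{m.genome.label}|w{j:03d}",
                        residues=pep,
                        label="nonvirus",
                        taxon=m.genome.label,
                    )
                )
    for j in range(n_decoys):
        pep = "".join(_AA[i] for i in rng.integers(0, 20, 300))
        records.append(
            ProteinDbRecord(id=f"decoy_phage|{j}", residues=pep, label="virus", taxon="unrelated_phage")
        )
    return records


_CODON_TO_AA = {}
for _aa, _cs in _CODONS.items():
    for _c in _cs:
        _CODON_TO_AA[_c] = _aa
for _c in ("TAA", "TAG", "TGA"):
    _CODON_TO_AA[_c] = "*"


def _translate_frame(nt: str) -> str:
    return "".join(_CODON_TO_AA.get(nt[i : i + 3], "X") for i in range(0, len(nt) - 2, 3))


# --- serialisation ----------------------------------------------------------


def write_genomes_fasta(path, genomes) -> None:
    write_fasta(path, ((f"{g.label} topology={g.topology}", g.seq) for g in genomes))


def write_truth_tsv(path, truth) -> None:
    truth.to_csv(path, sep="\t", index=False)


def write_protein_db_fasta(path, records) -> None:
    write_fasta(
        path,
        (
            (
                f"{r.id} label={r.label} taxon={r.taxon}"
                + (f" family={r.family}" if r.family else ""),
                r.residues,
            )
            for r in records
        ),
    )


def write_community_yaml(path, community: CommunitySpec, params: Optional[ReadSimParams] = None) -> None:
    doc = {
        "members": [
            {
                "label": m.genome.label,
                "kind": m.kind,
                "abundance": float(m.abundance),
                "length": len(m.genome.seq),
                "topology": m.genome.topology,
            }
            for m in community.members
        ]
    }
    if params is not None:
        doc["read_sim"] = {
            k: (v if not isinstance(v, float) else float(v))
            for k, v in vars(params).items()
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
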