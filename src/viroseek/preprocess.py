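"""Read preprocessing: positional-key deduplication, quality-tail trimming,
adaptor clipping, and host/bacterial read subtraction.

The subtraction contract is the one the discovery workflow relies on: a read
is background iff it has an ungapped alignment of at least
``min_aligned_length`` consecutive bases to a reference (either strand) with
at most ``max_mismatches`` mismatches.  It is implemented as exact-seed lookup
followed by mismatch counting along the seed diagonal, which is equivalent to
the exhaustive sliding-window check whenever a seed survives — guaranteed when
per-window divergence stays within the mismatch budget and
``seed_length <= min_aligned_length // (max_mismatches + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._sequtils import encode, kmer_codes, revcomp
from .records import Read


@dataclass
class PreprocessParams:
    #: 1-based inclusive positions of the duplicate key on each read
    dup_key_start: int = 5
    dup_key_end: int = 55
    qual_threshold: int = 20
    adaptors: list = field(default_factory=list)
    min_read_length_after_trim: int = 50

    def __post_init__(self):
        if self.dup_key_start < 1 or self.dup_key_end < self.dup_key_start:
            raise ValueError("duplicate key interval must satisfy 1 <= start <= end")


@dataclass
class SubtractionParams:
    min_aligned_length: int = 60
    max_mismatches: int = 2
    seed_length: int = 20
    gaps_allowed: bool = False  # the contract is ungapped; kept for the record

    def __post_init__(self):
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.seed_length > self.min_aligned_length:
            raise ValueError("seed_length must not exceed min_aligned_length")
        if self.gaps_allowed:
            raise ValueError("gapped subtraction is not part of the contract")


def dedup_key(read: Read, params: PreprocessParams) -> str:
    """Duplicate key: bases at 1-based positions [dup_key_start, dup_key_end].

    Reads shorter than the key interval are keyed on their full sequence;
    matching is exact string equality (N matches only N).
    """
    if len(read.bases) < params.dup_key_end:
        return read.bases
    return read.bases[params.dup_key_start - 1 : params.dup_key_end]


def dedup(reads, params: PreprocessParams, seed: int = 0, random_survivor: bool = False):
    """Collapse duplicate reads; returns (survivors, n_removed).

    Among reads sharing a key exactly one survives.  By default the
    first-seen copy is kept (reproducible independent of RNG state); with
    ``random_survivor=True`` the kept copy is chosen uniformly per group using
    the seeded RNG.  Survivors preserve input order.
    """
    groups: dict = {}
    for i, r in enumerate(reads):
        groups.setdefault(dedup_key(r, params), []).append(i)
    if random_survivor:
        rng = np.random.default_rng(seed)
        keep = set()
        for key in sorted(groups):
            idxs = groups[key]
            keep.add(idxs[int(rng.integers(0, len(idxs)))])
    else:
        keep = {idxs[0] for idxs in groups.values()}
    survivors = [r for i, r in enumerate(reads) if i in keep]
    return survivors, len(reads) - len(survivors)


def trim_quality(read: Read, threshold: int) -> Read:
    """Trim the 3' tail while quality < threshold.

    Scanning 3'->5', bases are removed until the first base with quality >=
    threshold; internal low-quality bases are retained.  A read trimmed to
    zero length is returned with empty sequence (caller discards).
    """
    q = read.quals
    cut = len(q)
    while cut > 0 and q[cut - 1] < threshold:
        cut -= 1
    if cut == len(q):
        return read
    return Read(read.id, read.bases[:cut], q[:cut], mate=read.mate)


def _adaptor_clip_pos(bases: str, adaptor: str) -> int | None:
    """Earliest clip position for one adaptor under the suffix-match rule:
    a read suffix matching an adaptor prefix of >= 8 exact bases, or a full
    adaptor occurrence with <= 1 mismatch."""
    n, alen = len(bases), len(adaptor)
    candidates = set()
    for block in (adaptor[:8], adaptor[8:16]):
        if len(block) < 8:
            continue
        off = 0 if block == adaptor[:8] else 8
        p = bases.find(block)
        while p != -1:
            if p - off >= 0:
                candidates.add(p - off)
            p = bases.find(block, p + 1)
    best = None
    for p in sorted(candidates):
        matchable = min(alen, n - p)
        if matchable < 8:
            continue
        seg = bases[p : p + matchable]
        mism = sum(a != b for a, b in zip(seg, adaptor))
        if (matchable == alen and mism <= 1) or (mism == 0):
            best = p
            break
    return best


def trim_adaptor(read: Read, adaptors) -> Read:
    """Clip the read at the earliest adaptor evidence (see _adaptor_clip_pos);
    multiple adaptors compete and the earliest clip wins."""
    best = None
    for ad in adaptors:
        p = _adaptor_clip_pos(read.bases, ad)
        if p is not None and (best is None or p < best):
            best = p
    if best is None:
        return read
    return Read(read.id, read.bases[:best], read.quals[:best], mate=read.mate)


class SubtractionIndex:
    """Seed index over reference sequences (both strands) for background
    subtraction.

    Every ``seed_length``-mer of every reference strand is recorded as a
    base-4 integer code; lookup returns (ref_idx, strand, position) tuples.
    """

    def __init__(self, references, params: SubtractionParams):
        """``references`` is a sequence of (name, sequence) pairs."""
        import warnings

        refs = list(references)
        if not refs:
            raise ValueError("reference set must be non-empty")
        self.params = params
        self.names = [n for n, _ in refs]
        # strand sequences: (ref_idx, '+'|'-') -> encoded array
        self._arrays: dict = {}
        self._index: dict = {}
        k = params.seed_length
        for ri, (name, seq) in enumerate(refs):
            arr = encode(seq)
            if (arr == 4).mean() > 0.5:
                warnings.warn(f"reference {name}: >50% non-ACGT bases")
            for strand, s in (("+", seq), ("-", revcomp(seq))):
                a = encode(s)
                self._arrays[(ri, strand)] = a
                codes = kmer_codes(a, k)
                for pos in range(codes.shape[0]):
                    c = codes[pos]
                    if c < 0:
                        continue
                    self._index.setdefault(int(c), []).append((ri, strand, pos))

    @classmethod
    def from_fasta(cls, path, params: SubtractionParams) -> "SubtractionIndex":
        from ._sequtils import read_fasta

        return cls([(h.split()[0], s) for h, s in read_fasta(path)], params)

    def lookup(self, code: int):
        return self._index.get(code, ())


def _diagonal_window(read_arr, ref_arr, diag, params: SubtractionParams):
    """Best qualifying window on one read/reference diagonal, or None.

    Returns (window_start_in_read, mismatches) for the minimum-mismatch
    window of ``min_aligned_length`` read bases with <= max_mismatches, using
    exact comparison (N counts as mismatch because codes differ).
    """
    w = params.min_aligned_length
    lo = max(0, -diag)
    hi = min(read_arr.shape[0], ref_arr.shape[0] - diag)
    if hi - lo < w:
        return None
    a = read_arr[lo:hi]
    b = ref_arr[lo + diag : hi + diag]
    mism = (a != b) | (a == 4) | (b == 4)
    c = np.concatenate([[0], np.cumsum(mism)])
    counts = c[w:] - c[:-w]
    best = int(np.argmin(counts))
    if counts[best] <= params.max_mismatches:
        return lo + best, int(counts[best])
    return None


def is_background(read: Read, index: SubtractionIndex):
    """Decide whether a read matches the background references.

    True iff some ungapped alignment of >= min_aligned_length consecutive
    read bases to a reference strand has <= max_mismatches.  Returns
    (bool, descriptor|None); the descriptor names the reference, strand,
    diagonal and window found.
    """
    params = index.params
    if len(read.bases) < params.min_aligned_length:
        return False, None
    arr = encode(read.bases)
    codes = kmer_codes(arr, params.seed_length)
    tried = set()
    for qpos in range(codes.shape[0]):
        c = codes[qpos]
        if c < 0:
            continue
        for ri, strand, rpos in index.lookup(int(c)):
            diag = rpos - qpos
            key = (ri, strand, diag)
            if key in tried:
                continue
            tried.add(key)
            hit = _diagonal_window(arr, index._arrays[(ri, strand)], diag, params)
            if hit is not None:
                start, mism = hit
                return True, {
                    "reference": index.names[ri],
                    "strand": strand,
                    "read_window_start": start,
                    "ref_window_start": start + diag,
                    "mismatches": mism,
                }
    return False, None


def subtract(reads, index: SubtractionIndex):
    """Remove background reads; returns (retained, n_removed), order preserved."""
    retained = [r for r in reads if not is_background(r, index)[0]]
    return retained, len(reads) - len(retained)


def preprocess_pairs(r1, r2, params: PreprocessParams, sub_index=None, seed: int = 0,
                     random_survivor: bool = False):
    """Full preprocessing of a read-pair pool in the pipeline's stage order:
    dedup (keyed on R1) -> quality trim -> adaptor trim -> length filter ->
    subtraction.  Returns (retained_reads, counts dict).

    Dedup drops whole pairs; trimming and subtraction act per read, so a pair
    may survive as a single read.
    """
    counts = {"input_reads": len(r1) + len(r2), "input_pairs": len(r1)}
    surv_r1, dup_removed_pairs = dedup(r1, params, seed=seed, random_survivor=random_survivor)
    keep_ids = {r.id for r in surv_r1}
    surv_r2 = [r for r in r2 if r.mate in keep_ids]
    counts["dedup_removed_reads"] = counts["input_reads"] - len(surv_r1) - len(surv_r2)

    reads = []
    short = 0
    for r in surv_r1 + surv_r2:
        r = trim_quality(r, params.qual_threshold)
        if params.adaptors:
            r = trim_adaptor(r, params.adaptors)
        if len(r) >= params.min_read_length_after_trim:
            reads.append(r)
        else:
            short += 1
    counts["trim_discarded_reads"] = short

    if sub_index is not None:
        reads, removed = subtract(reads, sub_index)
        counts["subtracted_reads"] = removed
    else:
        counts["subtracted_reads"] = 0
    counts["retained_reads"] = len(reads)
    return reads, counts
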