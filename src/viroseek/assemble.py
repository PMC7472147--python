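"""Ensemble de novo assembly: multi-k de Bruijn unitigs over random read
partitions, pooled and merged by a greedy overlap-layout-consensus pass, with
terminal-repeat detection for circular genomes.

The partitioned sub-assembly idea: reads are split into ``n_partitions``
random groups, each group is assembled independently at every k in
``k_values``, and the pooled fragments are merged by OLC.  Coverage gaps and
branch breakpoints differ between partitions and k values, so the union of
sub-assemblies tiles the underlying genome even where any single assembly
fragments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._sequtils import canonical, revcomp
from .records import Contig, Read


@dataclass
class AssemblyParams:
    k_values: tuple = (21, 31, 41)
    min_kmer_count: int = 2
    n_partitions: int = 4
    olc_min_overlap: int = 35
    olc_min_identity: float = 0.98
    min_contig_length: int = 200
    circular_min_terminal_repeat: int = 20
    #: a branch is followed if its k-mer count is >= this multiple of the
    #: alternative's (simple dominant-branch bubble/tip resolution)
    branch_dominance: float = 3.0

    def __post_init__(self):
        if any(k % 2 == 0 for k in self.k_values):
            raise ValueError("k values must be odd")
        if self.n_partitions < 1:
            raise ValueError("n_partitions must be >= 1")


class DeBruijnGraph:
    """Strand-canonical k-mer count graph.

    Nodes are implicit (k-1)-mers; an edge is a canonical k-mer with its
    observation count.  Palindromic k-mers are counted once per observation.
    """

    def __init__(self, k: int, counts: dict):
        self.k = k
        self.counts = counts

    def __len__(self):
        return len(self.counts)


def build_dbg(reads, k: int, min_kmer_count: int = 2) -> DeBruijnGraph:
    """Count canonical k-mers over reads (k-mers with N are skipped) and drop
    edges below ``min_kmer_count``."""
    counts: dict = {}
    for r in reads:
        bases = r.bases if isinstance(r, Read) else r
        for i in range(len(bases) - k + 1):
            kmer = bases[i : i + k]
            if "N" in kmer:
                continue
            c = canonical(kmer)
            counts[c] = counts.get(c, 0) + 1
    counts = {km: c for km, c in counts.items() if c >= min_kmer_count}
    return DeBruijnGraph(k, counts)


def _extensions(graph: DeBruijnGraph, kmer: str):
    """Forward extension candidates of an oriented k-mer: (next_kmer, count)."""
    suf = kmer[1:]
    out = []
    for b in "ACGT":
        nxt = suf + b
        c = graph.counts.get(canonical(nxt))
        if c:
            out.append((nxt, c))
    return out


def _unique_extension(graph: DeBruijnGraph, kmer: str, dominance: float):
    """The unambiguous (or dominant) forward extension, or None.

    With several candidates the highest-count one is taken only if it
    out-covers every alternative by ``dominance``; ties stall the walk."""
    cands = _extensions(graph, kmer)
    if not cands:
        return None
    if len(cands) == 1:
        return cands[0][0]
    cands.sort(key=lambda t: (-t[1], t[0]))
    if cands[0][1] >= dominance * cands[1][1]:
        return cands[0][0]
    return None


def dbg_contigs(graph: DeBruijnGraph, dominance: float = 3.0) -> list:
    """Extract unitigs: maximal walks that are unambiguous in both directions.

    Each walk extends while the current k-mer has a unique (or dominant)
    successor and that successor has a unique (or dominant) predecessor;
    cycles close when the walk returns to a visited k-mer, so an isolated
    circular genome yields one walk of length ``genome + k - 1``.
    """
    k = graph.k
    visited: set = set()
    unitigs = []
    for start in sorted(graph.counts):
        if start in visited:
            continue
        path = [start]
        visited.add(start)
        # extend right
        cur = start
        while True:
            nxt = _unique_extension(graph, cur, dominance)
            if nxt is None:
                break
            back = _unique_extension(graph, revcomp(nxt), dominance)
            if back is None or canonical(back) != canonical(revcomp(cur)):
                break
            if canonical(nxt) in visited:
                path.append(nxt)  # close a cycle once, then stop
                break
            visited.add(canonical(nxt))
            path.append(nxt)
            cur = nxt
        # extend left by walking right from the reverse complement of start
        rwalk = revcomp(start)
        cur = rwalk
        while True:
            nxt = _unique_extension(graph, cur, dominance)
            if nxt is None:
                break
            back = _unique_extension(graph, revcomp(nxt), dominance)
            if back is None or canonical(back) != canonical(revcomp(cur)):
                break
            if canonical(nxt) in visited:
                break
            visited.add(canonical(nxt))
            rwalk += nxt[-1]
            cur = nxt
        # revcomp(rwalk) ends with `start`; append the right walk beyond it
        seq = revcomp(rwalk) + "".join(km[-1] for km in path[1:])
        unitigs.append(seq)
    return unitigs


@dataclass
class AssemblyFragment:
    id: str
    bases: str
    source: str = ""  # provenance tag, e.g. "p0/k31"


def partitioned_assembly(reads, params: AssemblyParams, seed: int = 0) -> list:
    """Randomly split reads into ``n_partitions`` seeded groups, assemble each
    group at every k, and pool the resulting fragments with provenance tags.
    With ``n_partitions=1`` and one k this degenerates to plain DBG assembly.
    """
    reads = list(reads)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(reads))
    parts = [[] for _ in range(params.n_partitions)]
    for j, idx in enumerate(order):
        parts[j % params.n_partitions].append(reads[idx])

    fragments = []
    n = 0
    for pi, part in enumerate(parts):
        for k in params.k_values:
            graph = build_dbg(part, k, params.min_kmer_count)
            for seq in dbg_contigs(graph, params.branch_dominance):
                if len(seq) >= k + 1:  # drop bare k-mers
                    fragments.append(AssemblyFragment(f"f{n:05d}", seq, f"p{pi}/k{k}"))
                    n += 1
    return fragments


# --- greedy OLC merge -------------------------------------------------------


def _hamming(a: str, b: str) -> int:
    if a == b:
        return 0
    return sum(x != y for x, y in zip(a, b))


def _contained_in(small: str, large: str, min_identity: float) -> bool:
    """Is ``small`` a (near-)substring of ``large``?  Anchored check: a 20-mer
    of small must occur exactly in large, then the full window is verified at
    ``min_identity``."""
    if small in large:
        return True
    budget = int((1 - min_identity) * len(small))
    if budget == 0 or len(small) < 40:
        return False
    for off in (0, len(small) // 2):
        anchor = small[off : off + 20]
        p = large.find(anchor)
        while p != -1:
            s = p - off
            if 0 <= s and s + len(small) <= len(large):
                if _hamming(small, large[s : s + len(small)]) <= budget:
                    return True
            p = large.find(anchor, p + 1)
    return False


def _best_overlap(x: str, y: str, params: AssemblyParams):
    """Longest suffix(x)/prefix(y) overlap >= olc_min_overlap at
    >= olc_min_identity, found via exact 20-mer anchors near the end of x.
    Returns overlap length or None.  Overlaps equal to a whole fragment are
    containments and are not reported."""
    candidates = set()
    for off in (20, 40):
        if len(x) < off:
            break
        anchor = x[-off : len(x) - off + 20]
        p = y.find(anchor)
        while p != -1:
            candidates.add(p + off)
            p = y.find(anchor, p + 1)
    best = None
    for ov in sorted(candidates, reverse=True):
        if ov < params.olc_min_overlap or ov >= len(x) or ov >= len(y):
            continue
        budget = int((1 - params.olc_min_identity) * ov)
        if _hamming(x[-ov:], y[:ov]) <= budget:
            best = ov
            break
    return best


def _merge(x: str, y: str, ov: int) -> str:
    """Merge with the overlap columns taken from the longer fragment
    (majority of two columns is a tie; ties go to the longer fragment)."""
    if len(x) >= len(y):
        return x + y[ov:]
    return x[:-ov] + y


def olc_merge(fragments, params: AssemblyParams) -> list:
    """Greedy longest-overlap-first merging of assembly fragments.

    Containment (a fragment matching within another at >= olc_min_identity,
    either strand) removes the contained fragment.  Both strands are
    considered for overlaps; merging repeats until no qualifying overlap
    remains.  Deterministic: fragments are processed sorted by (length desc,
    id) and ties between equal overlaps break on fragment ids.
    """
    frags = {f.id: f.bases for f in fragments}

    def drop_contained():
        ids = sorted(frags, key=lambda i: (-len(frags[i]), i))
        dropped = set()
        for i, small_id in enumerate(reversed(ids)):
            small = frags[small_id]
            for large_id in ids:
                if large_id == small_id or large_id in dropped:
                    continue
                if len(frags[large_id]) < len(small):
                    break
                if _contained_in(small, frags[large_id], params.olc_min_identity) or _contained_in(
                    revcomp(small), frags[large_id], params.olc_min_identity
                ):
                    dropped.add(small_id)
                    break
        for d in dropped:
            del frags[d]

    drop_contained()

    cache: dict = {}

    def pair_best(i, j):
        """Best (ov, variant) over the four orientation combinations."""
        key = (i, j)
        if key in cache:
            return cache[key]
        a, b = frags[i], frags[j]
        rb = revcomp(b)
        best = None
        for variant, (x, y) in enumerate(((a, b), (b, a), (a, rb), (rb, a))):
            ov = _best_overlap(x, y, params)
            if ov is not None and (best is None or ov > best[0]):
                best = (ov, variant)
        cache[key] = best
        return best

    counter = 0
    while True:
        ids = sorted(frags, key=lambda i: (-len(frags[i]), i))
        best = None  # (ov, i, j, variant)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                r = pair_best(ids[ai], ids[bi])
                if r is not None and (best is None or r[0] > best[0]):
                    best = (r[0], ids[ai], ids[bi], r[1])
        if best is None:
            break
        ov, i, j, variant = best
        a, b = frags[i], frags[j]
        rb = revcomp(b)
        x, y = ((a, b), (b, a), (a, rb), (rb, a))[variant]
        merged = _merge(x, y, ov)
        del frags[i], frags[j]
        cache.clear()
        new_id = f"m{counter:05d}"
        counter += 1
        # the merged fragment may now contain others
        for other in sorted(frags):
            o = frags[other]
            if _contained_in(o, merged, params.olc_min_identity) or _contained_in(
                revcomp(o), merged, params.olc_min_identity
            ):
                del frags[other]
        frags[new_id] = merged
    return [AssemblyFragment(i, frags[i], "olc") for i in sorted(frags, key=lambda i: (-len(frags[i]), i))]


def detect_circularity(contig: Contig, min_terminal_repeat: int = 20) -> Contig:
    """Collapse an exact terminal repeat into a circular contig.

    If the contig's prefix equals its suffix over >= min_terminal_repeat
    bases, the repeat is collapsed once and the contig flagged circular.
    Homopolymers (period-1 repeats) are flagged ambiguous instead.
    """
    seq = contig.bases
    n = len(seq)
    if n < 2 * min_terminal_repeat:
        return contig
    if len(set(seq)) == 1:
        return Contig(contig.id, seq, contig.support, contig.mean_coverage,
                      circular=False, circularity_ambiguous=True)
    probe = seq[:min_terminal_repeat]
    best = 0
    p = seq.find(probe, 1)
    while p != -1:
        r = n - p
        if r >= min_terminal_repeat and r <= n // 2 and seq[:r] == seq[-r:]:
            best = max(best, r)
        p = seq.find(probe, p + 1)
    if best == 0:
        return contig
    return Contig(contig.id, seq[: n - best], contig.support, contig.mean_coverage,
                  circular=True)


def assemble_reads(reads, params: AssemblyParams, seed: int = 0) -> list:
    """Full ensemble assembly: partitioned multi-k DBG -> OLC merge ->
    circularity detection -> length filter; contigs get read support and mean
    coverage assigned by k-mer membership, and are sorted by length."""
    reads = list(reads)
    fragments = partitioned_assembly(reads, params, seed)
    merged = olc_merge(fragments, params)

    contigs = []
    for i, frag in enumerate(merged):
        c = detect_circularity(
            Contig(f"contig{i:04d}", frag.bases), params.circular_min_terminal_repeat
        )
        if len(c) >= params.min_contig_length or c.circular:
            contigs.append(c)

    # assign supporting reads by sampled k-mer membership
    k = min(params.k_values)
    kmer_to_contig: dict = {}
    for c in contigs:
        probe_seq = c.bases + (c.bases[: k - 1] if c.circular else "")
        for j in range(len(probe_seq) - k + 1):
            kmer_to_contig.setdefault(canonical(probe_seq[j : j + k]), c.id)
    by_id = {c.id: c for c in contigs}
    for r in reads:
        if len(r.bases) < k:
            continue
        mid = (len(r.bases) - k) // 2
        for pos in (0, mid, len(r.bases) - k):
            cid = kmer_to_contig.get(canonical(r.bases[pos : pos + k]))
            if cid is not None:
                by_id[cid].support.append(r.id)
                break
    # mean coverage: supporting read bases / contig length
    read_len = {r.id: len(r.bases) for r in reads}
    for c in contigs:
        c.mean_coverage = sum(read_len.get(i, 0) for i in c.support) / max(1, len(c))
    contigs.sort(key=lambda c: (-len(c), c.id))
    return contigs
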