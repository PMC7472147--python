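"""Pairwise protein comparison and distance-based trees.

``align_pair`` is an affine-gap dynamic-programming aligner (Gotoh's three
matrices) under BLOSUM62 with gap open 11 / extend 1 — a gap of length L
costs ``open + extend*L``.  Percent identity is identical columns over
aligned columns, gap columns excluded; local mode is the headline identity
(approximating BLAST-style hit-region identities), global mode serves the
species-demarcation rule.

``nj_tree`` is Saitou-Nei neighbor joining with the standard Q criterion,
deterministic label-order tie-breaking, and negative branch lengths clamped
to zero with the deficit shifted to the sibling branch.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import BLOSUM62


@dataclass
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    mode: str

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")

    @property
    def aligned_columns(self) -> int:
        return sum(1 for a, b in zip(self.aligned_a, self.aligned_b) if a != "-" and b != "-")

    @property
    def identities(self) -> int:
        return sum(1 for a, b in zip(self.aligned_a, self.aligned_b) if a == b and a != "-")

    @property
    def percent_identity(self) -> float:
        cols = self.aligned_columns
        return 100.0 * self.identities / cols if cols else 0.0


def _score(matrix, a, b) -> float:
    try:
        return matrix[a][b]
    except KeyError:
        return -4.0


def align_pair(a: str, b: str, mode: str = "local", matrix=None,
               gap_open: float = 11.0, gap_extend: float = 1.0) -> PairwiseAlignment:
    """Optimal affine-gap alignment of two residue strings.

    Deterministic traceback: ties prefer diagonal, then up (gap in ``b``),
    then left (gap in ``a``).  ``mode`` is "global" or "local"; the local
    alignment may be empty (score 0) for unrelated sequences.
    """
    if mode not in ("global", "local"):
        raise ValueError("mode must be global|local")
    matrix = matrix or BLOSUM62
    n, m = len(a), len(b)
    NEG = -1e18
    go = gap_open + gap_extend  # cost of opening a gap of length 1
    ge = gap_extend

    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in b (consumes a; "up")
    Iy = np.full((n + 1, m + 1), NEG)  # gap in a (consumes b; "left")
    # pointers: 0=stop/local-start, 1=from M, 2=from Ix, 3=from Iy
    Pm = np.zeros((n + 1, m + 1), dtype=np.int8)
    Px = np.zeros((n + 1, m + 1), dtype=np.int8)
    Py = np.zeros((n + 1, m + 1), dtype=np.int8)

    local = mode == "local"
    M[0, 0] = 0.0
    if not local:
        for i in range(1, n + 1):
            Ix[i, 0] = -(go + ge * (i - 1))
            Px[i, 0] = 2 if i > 1 else 1
        for j in range(1, m + 1):
            Iy[0, j] = -(go + ge * (j - 1))
            Py[0, j] = 3 if j > 1 else 1
    else:
        M[:, 0] = 0.0
        M[0, :] = 0.0

    best = (0.0, 0, 0, 1) if local else None
    for i in range(1, n + 1):
        ai = a[i - 1]
        row_m, row_x, row_y = M[i], Ix[i], Iy[i]
        prev_m, prev_x, prev_y = M[i - 1], Ix[i - 1], Iy[i - 1]
        for j in range(1, m + 1):
            s = _score(matrix, ai, b[j - 1])
            # M: diagonal moves from M, Ix, Iy (priority order on ties)
            cm, cx, cy = prev_m[j - 1], prev_x[j - 1], prev_y[j - 1]
            v, p = cm, 1
            if cx > v:
                v, p = cx, 2
            if cy > v:
                v, p = cy, 3
            v += s
            if local and v < 0:
                v, p = 0.0, 0
            row_m[j] = v
            Pm[i, j] = p
            # Ix: gap in b — extend from above
            vo, ve = prev_m[j] - go, prev_x[j] - ge
            if vo >= ve:
                row_x[j] = vo
                Px[i, j] = 1
            else:
                row_x[j] = ve
                Px[i, j] = 2
            # Iy: gap in a — extend from the left
            vo, ve = row_m[j - 1] - go, row_y[j - 1] - ge
            if vo >= ve:
                row_y[j] = vo
                Py[i, j] = 1
            else:
                row_y[j] = ve
                Py[i, j] = 3
            if local and row_m[j] > best[0]:
                best = (row_m[j], i, j, 1)

    if local:
        score, i, j, state = best
    else:
        # end state: prefer M, then Ix, then Iy on ties
        cands = ((M[n, m], 1), (Ix[n, m], 2), (Iy[n, m], 3))
        score, state = max(cands, key=lambda t: (t[0], -t[1]))
        i, j = n, m

    out_a, out_b = [], []
    while True:
        if local and (i == 0 or j == 0 or (state == 1 and M[i, j] == 0 and Pm[i, j] == 0)):
            break
        if not local and i == 0 and j == 0:
            break
        if state == 1:
            p = Pm[i, j]
            if local and p == 0:
                break
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j, state = i - 1, j - 1, p
        elif state == 2:
            p = Px[i, j]
            out_a.append(a[i - 1])
            out_b.append("-")
            i, state = i - 1, p
        else:
            p = Py[i, j]
            out_a.append("-")
            out_b.append(b[j - 1])
            j, state = j - 1, p
        if not local and i == 0 and j == 0:
            break
        if local and state == 1 and M[i, j] == 0 and Pm[i, j] == 0:
            break
    return PairwiseAlignment("".join(reversed(out_a)), "".join(reversed(out_b)),
                             float(score), mode)


def identity_matrix(seqs: dict, mode: str = "local", matrix=None,
                    gap_open: float = 11.0, gap_extend: float = 1.0):
    """All-vs-all percent identity and the derived distance matrix.

    ``seqs`` maps label -> residue string.  Returns
    (identity DataFrame in percent, DistanceMatrix with d = 1 - identity/100).
    Label order follows the input mapping.
    """
    labels = list(seqs)
    k = len(labels)
    ident = np.full((k, k), 100.0)
    for i in range(k):
        for j in range(i + 1, k):
            aln = align_pair(seqs[labels[i]], seqs[labels[j]], mode=mode,
                             matrix=matrix, gap_open=gap_open, gap_extend=gap_extend)
            ident[i, j] = ident[j, i] = aln.percent_identity
    dm = DistanceMatrix(labels, 1.0 - ident / 100.0)
    return pd.DataFrame(ident, index=labels, columns=labels), dm


@dataclass
class DistanceMatrix:
    labels: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric within 1e-12")
        if (np.diag(self.values) != 0).any():
            raise ValueError("distance matrix diagonal must be zero")
        if (self.values < 0).any():
            raise ValueError("distances must be non-negative")


@dataclass
class TreeNode:
    """A rooted view of an unrooted NJ topology (trifurcating root)."""

    name: str = None
    children: list = field(default_factory=list)  # [(TreeNode, branch_length)]

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list:
        if self.is_leaf:
            return [self.name]
        out = []
        for child, _ in self.children:
            out += child.leaf_names()
        return out

    def path_lengths(self) -> dict:
        """Patristic distance between every pair of leaves."""
        dists = {}

        def depths(node, acc):
            if node.is_leaf:
                return {node.name: acc}
            out = {}
            for child, bl in node.children:
                out.update(depths(child, acc + bl))
            return out

        def visit(node):
            groups = []
            for child, bl in node.children:
                groups.append(depths(child, bl))
                visit(child)
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for x, dx in groups[gi].items():
                        for y, dy in groups[gj].items():
                            dists[frozenset((x, y))] = dx + dy

        visit(self)
        return dists


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Joins the pair minimising Q(i,j) = (n-2) d(i,j) - r_i - r_j; ties break
    on sorted label pairs.  Negative branch lengths are clamped to zero with
    the deficit moved to the sibling branch.  Two-taxon input yields a single
    edge split evenly; the final join leaves a trifurcating root.
    """
    labels = list(dm.labels)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two taxa")
    nodes = {lab: TreeNode(name=lab) for lab in labels}
    d = {frozenset((a, b)): float(dm.values[i, j])
         for i, a in enumerate(labels) for j, b in enumerate(labels) if i < j}
    active = sorted(labels)
    counter = 0

    def dist(a, b):
        return d[frozenset((a, b))]

    while len(active) > 3:
        n_act = len(active)
        r = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best = None
        for ii in range(n_act):
            for jj in range(ii + 1, n_act):
                a, b = active[ii], active[jj]
                q = (n_act - 2) * dist(a, b) - r[a] - r[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        dab = dist(a, b)
        la = dab / 2 + (r[a] - r[b]) / (2 * (n_act - 2))
        lb = dab - la
        if la < 0:
            la, lb = 0.0, dab
        if lb < 0:
            la, lb = dab, 0.0
        new_name = f"__internal{counter}"
        counter += 1
        node = TreeNode(children=[(nodes[a], la), (nodes[b], lb)])
        nodes[new_name] = node
        for c in active:
            if c in (a, b):
                continue
            d[frozenset((new_name, c))] = max(0.0, (dist(a, c) + dist(b, c) - dab) / 2)
        active = sorted([c for c in active if c not in (a, b)] + [new_name])

    if len(active) == 2:
        a, b = active
        dab = dist(a, b)
        return TreeNode(children=[(nodes[a], dab / 2), (nodes[b], dab / 2)])
    a, b, c = active
    la = (dist(a, b) + dist(a, c) - dist(b, c)) / 2
    lb = (dist(a, b) + dist(b, c) - dist(a, c)) / 2
    lc = (dist(a, c) + dist(b, c) - dist(a, b)) / 2
    children = []
    for x, lx in ((a, la), (b, lb), (c, lc)):
        children.append((nodes[x], max(0.0, lx)))
    return TreeNode(children=children)


def write_newick(tree: TreeNode) -> str:
    """Serialise with branch lengths; round-trips through read_newick."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            return node.name
        inner = ",".join(f"{fmt(c)}:{bl:.10g}" for c, bl in node.children)
        return f"({inner})"

    return fmt(tree) + ";"


def read_newick(text: str) -> TreeNode:
    """Parse the subset of Newick this module writes (names, branch lengths)."""
    tokens = re.findall(r"[(),;]|[^(),;:]+|:", text.strip())
    pos = 0

    def parse_node() -> tuple:
        nonlocal pos
        node = TreeNode()
        if tokens[pos] == "(":
            pos += 1
            while True:
                child, bl = parse_node()
                node.children.append((child, bl))
                if tokens[pos] == ",":
                    pos += 1
                    continue
                break
            assert tokens[pos] == ")", "unbalanced parentheses"
            pos += 1
        if pos < len(tokens) and tokens[pos] not in "(),;:":
            node.name = tokens[pos]
            pos += 1
        bl = 0.0
        if pos < len(tokens) and tokens[pos] == ":":
            pos += 1
            bl = float(tokens[pos])
            pos += 1
        return node, bl

    root, _ = parse_node()
    assert tokens[pos] == ";", "missing terminal semicolon"
    return root


def write_identity_tsv(path, ident: pd.DataFrame) -> None:
    ident.to_csv(path, sep="\t", float_format="%.3f")
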