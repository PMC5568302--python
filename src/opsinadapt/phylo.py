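"""Allele phylogenies: heterozygote expansion, JC distances, NJ, bootstrap.

Direct-sequenced diploids carry IUPAC ambiguity codes at heterozygous
sites; :func:`expand_heterozygotes` splits such a sequence into two allele
sequences under a declared (not inferred) phase convention.  Distances use
the Jukes–Cantor correction; trees are built with the Saitou–Nei
neighbor-joining algorithm with deterministic tie-breaking, and internal
edges receive bootstrap supports as the percentage of column-resampled
replicates containing the same bipartition.
"""

from __future__ import annotations

import io
import itertools
import math

import numpy as np
from skbio import TreeNode

from .core import Alignment, BIALLELIC_CODES, IUPAC_CODES


def expand_heterozygotes(sequence: str) -> tuple[str, str]:
    """Split a sequence with IUPAC heterozygous calls into two alleles.

    At each biallelic ambiguity code (R, Y, S, W, K, M) the first listed
    base of the code goes to allele 1 and the second to allele 2 — a fixed
    convention, not phase inference, so multi-site phase is arbitrary.
    Three- or four-fold codes (B, D, H, V, N) are not expandable and raise
    ``ValueError`` listing the offending sites.
    """
    sequence = sequence.upper()
    bad = [i + 1 for i, ch in enumerate(sequence)
           if ch not in "ACGT-." and ch not in BIALLELIC_CODES]
    if bad:
        raise ValueError(f"non-biallelic ambiguity at 1-based sites {bad}")
    a1 = []
    a2 = []
    for ch in sequence:
        if ch in BIALLELIC_CODES:
            b1, b2 = IUPAC_CODES[ch]
            a1.append(b1)
            a2.append(b2)
        else:
            a1.append(ch)
            a2.append(ch)
    return "".join(a1), "".join(a2)


def concatenate_regions(alignments: list[Alignment]) -> Alignment:
    """Concatenate per-region alignments sharing one id set (allele ids)."""
    if not alignments:
        raise ValueError("no alignments given")
    ids = alignments[0].ids
    for aln in alignments[1:]:
        if set(aln.ids) != set(ids):
            raise ValueError("alignments do not share the same sequence ids")
    seqs = ["".join(aln.sequence(i) for aln in alignments) for i in ids]
    return Alignment(ids, seqs)


def jc_distance_matrix(alignment: Alignment) -> tuple[list[str], np.ndarray]:
    """Jukes–Cantor distance matrix with pairwise deletion.

    d = −(3/4)·ln(1 − 4p/3) with p the proportion of differing sites among
    columns where both sequences carry an unambiguous base.  p ≥ 3/4
    (saturation) leaves the entry NaN; tree building rejects such matrices.
    """
    n = alignment.n
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        diffs, valid = _hamming_fast(alignment.seqs[i], alignment.seqs[j])
        if valid == 0:
            d[i, j] = d[j, i] = np.nan
            continue
        p = diffs / valid
        d[i, j] = d[j, i] = (
            np.nan if p >= 0.75 else
            (0.0 if p == 0 else -0.75 * math.log(1.0 - 4.0 * p / 3.0))
        )
    return list(alignment.ids), d


_ACGT_BYTES = np.frombuffer(b"ACGT", dtype="S1")


def _hamming_fast(s1: str, s2: str) -> tuple[int, int]:
    a = np.frombuffer(s1.encode(), dtype="S1")
    b = np.frombuffer(s2.encode(), dtype="S1")
    ok = np.isin(a, _ACGT_BYTES) & np.isin(b, _ACGT_BYTES)
    return int(np.sum((a != b) & ok)), int(ok.sum())


class _Node:
    __slots__ = ("label", "children", "min_leaf")

    def __init__(self, label=None, children=None):
        self.label = label
        self.children = children or []  # list of (child, branch_length)
        self.min_leaf = label if label is not None else min(
            c.min_leaf for c, _ in self.children)

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c.newick()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})"


def neighbor_joining(ids: list[str], distances: np.ndarray) -> TreeNode:
    """Saitou–Nei neighbor joining with deterministic conventions.

    Ties in the Q criterion are broken by joining the pair whose sorted
    label pair is lexicographically smallest (labels of internal nodes are
    the smallest leaf label beneath them).  Negative branch lengths are
    clamped to 0 with the excess transferred to the sister branch.  Returns
    an unrooted tree (trifurcating root) as a scikit-bio ``TreeNode``.
    """
    n = len(ids)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    d = np.asarray(distances, dtype=float).copy()
    if d.shape != (n, n):
        raise ValueError("distance matrix shape mismatch")
    if np.any(~np.isfinite(d)):
        raise ValueError("distance matrix contains undefined entries")

    nodes: list[_Node] = [_Node(label=i) for i in ids]
    active = list(range(n))

    def _clamp(la: float, lb: float) -> tuple[float, float]:
        if la < 0:
            lb = max(lb + la, 0.0)
            la = 0.0
        if lb < 0:
            la = max(la + lb, 0.0)
            lb = 0.0
        return la, lb

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ai, aj in itertools.combinations(range(m), 2):
            q = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
            i_glob, j_glob = active[ai], active[aj]
            key = tuple(sorted((nodes[i_glob].min_leaf, nodes[j_glob].min_leaf)))
            if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and key < best[1]):
                best = (q, key, ai, aj)
        _, _, ai, aj = best
        i_glob, j_glob = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = _clamp(li, lj)
        new = _Node(children=[(nodes[i_glob], li), (nodes[j_glob], lj)])
        # distances of the new node to the remaining actives
        new_idx = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for ak in range(m):
            if ak in (ai, aj):
                continue
            k_glob = active[ak]
            dk = 0.5 * (sub[ai, ak] + sub[aj, ak] - dij)
            d[new_idx, k_glob] = d[k_glob, new_idx] = max(dk, 0.0)
        nodes.append(new)
        active = [g for g in active if g not in (i_glob, j_glob)] + [new_idx]

    # terminal three-node star: three-point formulas
    x, y, z = active
    dxy, dxz, dyz = d[x, y], d[x, z], d[y, z]
    lx = max((dxy + dxz - dyz) / 2.0, 0.0)
    ly = max((dxy + dyz - dxz) / 2.0, 0.0)
    lz = max((dxz + dyz - dxy) / 2.0, 0.0)
    root = _Node(children=[(nodes[x], lx), (nodes[y], ly), (nodes[z], lz)])
    return TreeNode.read(io.StringIO(root.newick() + ";"))


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Internal-edge bipartitions as frozensets of leaf names.

    Each bipartition is represented by the side not containing the
    lexicographically smallest leaf, so representation is rooting-invariant.
    """
    leaves = {t.name for t in tree.tips()}
    ref = min(leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(leaves - side) < 2:
            continue
        if ref in side:
            side = frozenset(leaves - side)
        splits.add(side)
    return splits


def bootstrap_support(alignment: Alignment, reps: int = 1000,
                      seed: int | None = None) -> TreeNode:
    """NJ tree with bootstrap supports on internal nodes.

    Columns are resampled with replacement ``reps`` times; each internal
    bipartition of the point-estimate tree gets the percentage of
    replicates in which it reappears, stored as the internal node's
    ``name`` (scikit-bio convention for support values).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    ids, d = jc_distance_matrix(alignment)
    tree = neighbor_joining(ids, d)
    counts: dict[frozenset[str], int] = {split: 0 for split in bipartitions(tree)}

    rng = np.random.default_rng(seed)
    mat = alignment.matrix()
    L = alignment.length
    for _ in range(reps):
        cols = rng.integers(0, L, size=L)
        boot = Alignment(ids, ["".join(row) for row in mat[:, cols]])
        _, db = jc_distance_matrix(boot)
        rep_splits = bipartitions(neighbor_joining(ids, db))
        for split in counts:
            if split in rep_splits:
                counts[split] += 1

    leaves = {t.name for t in tree.tips()}
    ref = min(leaves)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(leaves - side) < 2:
            continue
        if ref in side:
            side = frozenset(leaves - side)
        node.name = f"{100.0 * counts[side] / reps:g}"
    return tree
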