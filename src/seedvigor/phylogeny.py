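"""Protein-distance neighbor-joining phylogenetics with Poisson
correction, site bootstrap and low-support collapse.

Pipeline: a precomputed protein multiple alignment is reduced by complete
deletion (every column containing a gap or ambiguous residue is dropped
for all taxa), pairwise distances are the Poisson-corrected substitutions
per site d = -ln(1 - p) with p the observed proportion of differing
sites, the tree is built by Saitou & Nei's neighbor-joining, and internal
branches are assigned bootstrap supports (percent of column-resampled
replicates containing the same bipartition); branches below the collapse
threshold are contracted to multifurcations.

Deterministic details (left open by the classical descriptions) are fixed
here: ties in the Q-criterion are broken by the lowest (i, j) index pair,
and negative NJ branch lengths are clamped to zero with the excess
transferred to the sibling branch so path lengths are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ProteinAlignment",
    "TreeNode",
    "SupportTree",
    "AMINO_ACIDS",
    "complete_deletion",
    "poisson_distance",
    "distance_matrix",
    "nj",
    "bootstrap_tree",
    "bipartitions",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class ProteinAlignment:
    names: list[str]
    seqs: list[str]

    def __post_init__(self):
        if len(self.names) != len(self.seqs):
            raise ValueError("names and seqs must align")
        if not self.seqs:
            raise ValueError("empty alignment")
        L = len(self.seqs[0])
        if any(len(s) != L for s in self.seqs):
            raise ValueError("all rows must have equal length")
        self.seqs = [s.upper() for s in self.seqs]

    @property
    def n_taxa(self) -> int:
        return len(self.names)

    @property
    def n_sites(self) -> int:
        return len(self.seqs[0])


@dataclass
class TreeNode:
    """Minimal rooted-representation node of the (unrooted) NJ tree."""

    name: str | None = None
    length: float = 0.0  # branch length to parent
    support: float | None = None  # percent, internal nodes only
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self, with_support: bool = True) -> str:
        return self._newick(with_support) + ";"

    def _newick(self, with_support: bool) -> str:
        if self.is_leaf:
            return f"{self.name}:{self.length:.6f}"
        inner = ",".join(c._newick(with_support) for c in self.children)
        label = ""
        if with_support and self.support is not None:
            label = f"{self.support:g}"
        return f"({inner}){label}:{self.length:.6f}"


@dataclass
class SupportTree:
    """Unrooted tree with branch lengths (subst/site) and percent supports."""

    root: TreeNode
    taxa: list[str]

    def newick(self, with_support: bool = True) -> str:
        return self.root.newick(with_support)

    def bipartitions(self) -> dict[frozenset, TreeNode]:
        return bipartitions(self.root, set(self.taxa))

    def collapse_below(self, threshold: float) -> "SupportTree":
        """Contract internal edges with support < threshold into
        multifurcations (supports must have been assigned)."""
        root = _copy(self.root)
        _collapse(root, threshold)
        return SupportTree(root, list(self.taxa))


def _copy(node: TreeNode) -> TreeNode:
    return TreeNode(
        name=node.name,
        length=node.length,
        support=node.support,
        children=[_copy(c) for c in node.children],
    )


def _collapse(node: TreeNode, threshold: float) -> None:
    new_children = []
    for c in node.children:
        _collapse(c, threshold)
        if (not c.is_leaf) and c.support is not None and c.support < threshold:
            # splice grandchildren up; their lengths absorb the dead edge
            for gc in c.children:
                gc.length += 0.0  # lengths below the collapsed edge are kept
                new_children.append(gc)
        else:
            new_children.append(c)
    node.children = new_children


def complete_deletion(aln: ProteinAlignment) -> ProteinAlignment:
    """Drop every column where any row carries a gap or ambiguous symbol."""
    cols = []
    for j in range(aln.n_sites):
        if all(s[j] in AMINO_ACIDS for s in aln.seqs):
            cols.append(j)
    if not cols:
        raise ValueError("no unambiguous columns survive complete deletion")
    seqs = ["".join(s[j] for j in cols) for s in aln.seqs]
    return ProteinAlignment(list(aln.names), seqs)


def poisson_distance(seq_a: str, seq_b: str) -> float:
    """Poisson-corrected protein distance d = -ln(1 - p), subst/site."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    if not seq_a:
        raise ValueError("empty sequences")
    p = sum(a != b for a, b in zip(seq_a, seq_b)) / len(seq_a)
    if p >= 1.0:
        raise ValueError("saturated pair (p = 1): Poisson distance undefined")
    return -np.log(1.0 - p)


def _encode(aln: ProteinAlignment) -> np.ndarray:
    return np.array([[ord(c) for c in s] for s in aln.seqs], dtype=np.int16)


def distance_matrix(aln: ProteinAlignment) -> np.ndarray:
    """Pairwise Poisson-corrected distance matrix of an alignment."""
    enc = _encode(aln)
    n = aln.n_taxa
    D = np.zeros((n, n))
    for i in range(n):
        diff = (enc[i] != enc[i + 1 :]).mean(axis=1)
        if np.any(diff >= 1.0):
            raise ValueError("saturated pair (p = 1): Poisson distance undefined")
        D[i, i + 1 :] = -np.log(1.0 - diff)
    return D + D.T


def nj(dist: np.ndarray, labels: list[str]) -> SupportTree:
    """Saitou-Nei neighbor joining on a symmetric distance matrix.

    Agglomerates the pair minimizing Q(i, j) = (n - 2) d(i, j) - r_i - r_j
    at each step; branch lengths from the standard three-point formulas;
    final join leaves a trifurcating root (unrooted tree).  Negative
    branch lengths are clamped to zero with the excess moved to the
    sibling so the pairwise path length is unchanged.
    """
    D = np.array(dist, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or n < 3:
        raise ValueError("need a square matrix with >= 3 taxa")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("matrix must be symmetric with zero diagonal")
    if len(labels) != n:
        raise ValueError("labels must match matrix size")

    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in labels]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (i, j) tie-break: argmin on the flattened upper triangle scans in index order
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if best is None or q[a, b] < best[0] - 1e-12:
                    best = (q[a, b], a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = D[i, j]
        li = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        lj = dij - li
        # clamp negatives, preserving li + lj
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode()
        ni, nj_ = nodes[i], nodes[j]
        ni.length, nj_.length = li, lj
        parent.children = [ni, nj_]
        # distances from the new node
        newd = np.zeros(D.shape[0] + 1)
        for c in active:
            if c in (i, j):
                continue
            newd[c] = 0.5 * (D[i, c] + D[j, c] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = newd[:-1]
        D[:-1, -1] = newd[:-1]
        nodes.append(parent)
        active = [c for c in active if c not in (i, j)] + [len(nodes) - 1]
    # final three-point join
    i, j, k = active
    dij, dik, djk = D[i, j], D[i, k], D[j, k]
    li = 0.5 * (dij + dik - djk)
    lj = 0.5 * (dij + djk - dik)
    lk = 0.5 * (dik + djk - dij)
    root = TreeNode()
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = max(ln, 0.0)
        root.children.append(nodes[idx])
    return SupportTree(root, list(labels))


def bipartitions(root: TreeNode, all_taxa: set) -> dict[frozenset, TreeNode]:
    """Non-trivial bipartitions of an unrooted tree, each keyed by its
    canonical side (the side not containing the alphabetically first
    taxon), mapped to the child node subtending the edge."""
    ref = min(all_taxa)
    out: dict[frozenset, TreeNode] = {}

    def walk(node: TreeNode) -> set:
        if node.is_leaf:
            return {node.name}
        below = set()
        for c in node.children:
            below |= walk(c)
        if 1 < len(below) < len(all_taxa) - 1:
            side = below if ref not in below else all_taxa - below
            out[frozenset(side)] = node
        return below

    walk(root)
    return out


def bootstrap_tree(
    aln: ProteinAlignment,
    B: int = 1000,
    collapse_below: float = 50.0,
    seed: int = 0,
) -> SupportTree:
    """NJ tree with site-bootstrap supports, low-support branches collapsed.

    Supports are mapped onto the full-data tree (not a consensus): for
    each internal edge, support = percent of ``B`` column-resampled
    replicates whose NJ tree contains the same bipartition.  Edges with
    support < ``collapse_below`` are then contracted.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    clean = complete_deletion(aln)
    base = nj(distance_matrix(clean), clean.names)
    taxa = set(clean.names)
    base_bip = bipartitions(base.root, taxa)
    counts = {bp: 0 for bp in base_bip}

    enc = _encode(clean)
    n, L = enc.shape
    # pairwise per-column mismatch table, resampled per replicate
    pair_idx = [(i, j) for i in range(n) for j in range(i + 1, n)]
    diff = np.stack([(enc[i] != enc[j]) for i, j in pair_idx]).astype(np.float32)
    rng = np.random.default_rng(seed)
    for _ in range(B):
        cols = rng.integers(0, L, size=L)
        p = diff[:, cols].mean(axis=1)
        p = np.minimum(p, 1.0 - 1e-12)  # saturated resamples get a huge finite distance
        d = -np.log(1.0 - p)
        D = np.zeros((n, n))
        for (i, j), v in zip(pair_idx, d):
            D[i, j] = D[j, i] = v
        rep = nj(D, clean.names)
        rep_bip = bipartitions(rep.root, taxa)
        for bp in counts:
            if bp in rep_bip:
                counts[bp] += 1
    for bp, node in base_bip.items():
        node.support = 100.0 * counts[bp] / B
    return base.collapse_below(collapse_below)
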