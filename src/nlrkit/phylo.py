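"""NB-ARC phylogeny: distances, neighbor joining, bootstrap, motif display.

The tree over a catalog is built from the conserved NB-ARC domain of
each protein — the only region alignable across the whole family.  The
stages are deliberately self-contained:

* **p-distance** from global pairwise alignments (mismatching columns
  over aligned non-gap columns).  No multiple alignment is required; an
  externally produced MSA can be supplied instead by passing equal-length
  sequences.
* **Neighbor joining** in its classical Saitou–Nei form: iteratively
  join the pair minimizing the Q criterion, with ties broken by the
  lexicographically smallest label pair so runs are reproducible.
  Negative branch-length estimates are clamped to zero and flagged.  For
  an additive input matrix the tree reproduces the input distances
  exactly.
* **Bootstrap** by column resampling of a reference-anchored profile:
  every sequence is threaded onto the coordinates of the longest input
  sequence via pairwise alignment, replicate column draws re-weight the
  per-pair mismatch counts, and support is the percentage of replicate
  trees containing each internal bipartition.  Deterministic per seed
  and invariant to leaf input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import alignment
from .errors import NlrkitError


# ---------------------------------------------------------------------------
# Inputs
# ---------------------------------------------------------------------------

def extract_nbarc(protein: str, domains) -> str:
    """Slice the single merged NB-ARC span out of a protein.

    ``domains`` are 1-based inclusive annotations; zero or multiple
    NB-ARC spans, or a span past the protein end, raise.
    """
    nb = [d for d in domains if d.domain_name == "NB-ARC"]
    if len(nb) != 1:
        pid = domains[0].protein_id if domains else "?"
        raise NlrkitError(
            f"protein {pid}: expected exactly one NB-ARC span, got {len(nb)}")
    span = nb[0]
    if span.end > len(protein):
        raise NlrkitError(
            f"protein {span.protein_id}: NB-ARC span {span.start}-{span.end} "
            f"beyond protein length {len(protein)}")
    return protein[span.start - 1:span.end]


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise NlrkitError("distance matrix shape mismatch")
        if not np.all(np.isfinite(self.d)):
            raise NlrkitError("non-finite distances")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise NlrkitError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise NlrkitError("nonzero diagonal")
        if np.any(self.d < -1e-12):
            raise NlrkitError("negative distances")


def pairwise_distance(seqs: dict[str, str]) -> DistanceMatrix:
    """p-distance matrix from global pairwise alignments."""
    labels = list(seqs)
    n = len(labels)
    if n < 3:
        raise NlrkitError("need at least 3 sequences")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = alignment.p_distance(
                seqs[labels[i]], seqs[labels[j]])
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# Tree structure
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree stored with an arbitrary internal node as root."""

    root: TreeNode
    negative_clamped: bool = False

    @property
    def labels(self) -> list[str]:
        return sorted(self.root.leaves())

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each canonicalized as the side not
        containing the lexicographically smallest leaf."""
        all_leaves = set(self.root.leaves())
        anchor = min(all_leaves)
        parts: set[frozenset] = set()

        def walk(node: TreeNode):
            below = set()
            if node.is_leaf:
                return {node.name}
            for child, _ in node.children:
                side = walk(child)
                if 2 <= len(side) <= len(all_leaves) - 2:
                    canon = (all_leaves - side if anchor in side
                             else frozenset(side))
                    parts.add(frozenset(canon))
                below |= side
            return below

        walk(self.root)
        return parts

    def _edges(self):
        """Yield (parent, index, child) over all edges."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            for i, (child, _) in enumerate(node.children):
                yield node, i, child
                stack.append(child)

    def leaf_distances(self) -> DistanceMatrix:
        """Path-length distances between all leaf pairs."""
        labels = self.labels
        index = {l: i for i, l in enumerate(labels)}
        n = len(labels)
        d = np.zeros((n, n))

        def below(node, depth, acc):
            if node.is_leaf:
                acc.append((node.name, depth))
                return
            for child, length in node.children:
                below(child, depth + length, acc)

        def walk(node):
            groups = []
            for child, length in node.children:
                acc = []
                below(child, length, acc)
                groups.append(acc)
                walk(child)
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for la, da in groups[gi]:
                        for lb, db in groups[gj]:
                            d[index[la], index[lb]] = da + db
                            d[index[lb], index[la]] = da + db

        walk(self.root)
        return DistanceMatrix(labels, d)

    def to_newick(self) -> str:
        def fmt(node: TreeNode, length: float | None) -> str:
            if node.is_leaf:
                body = node.name
            else:
                inner = ",".join(fmt(c, l) for c, l in node.children)
                label = ("" if node.support is None
                         else f"{node.support:g}")
                body = f"({inner}){label}"
            return body if length is None else f"{body}:{length:.6g}"
        return fmt(self.root, None) + ";"


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(matrix: DistanceMatrix) -> PhyloTree:
    """Classical Saitou–Nei NJ with deterministic tie-breaking.

    At each step the pair minimizing Q(i,j) = (m-2)·d(i,j) − r(i) − r(j)
    is joined; among Q ties the pair whose sorted (smallest-leaf) labels
    are lexicographically least wins.  Branch lengths follow the standard
    formulas; negative estimates are clamped to 0 and flagged.
    """
    labels = matrix.labels
    n = len(labels)
    if n < 3:
        raise NlrkitError("neighbor joining needs at least 3 taxa")
    size = 2 * n
    D = np.zeros((size, size))
    D[:n, :n] = matrix.d
    nodes: list[TreeNode] = [TreeNode(name=l) for l in labels]
    keys: list[str] = list(labels)  # smallest leaf label in each cluster
    active = list(range(n))
    clamped = False
    nxt = n

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped = True
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(Q <= qmin + 1e-12)
        best = None
        for a, b in cand:
            if a >= b:
                continue
            key = tuple(sorted((keys[active[a]], keys[active[b]])))
            if best is None or key < best[0]:
                best = (key, int(a), int(b))
        _, a, b = best
        i, j = active[a], active[b]
        dij = D[i, j]
        li = clamp(0.5 * dij + (r[a] - r[b]) / (2 * (m - 2)))
        lj = clamp(dij - (0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))))
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        nodes.append(new)
        keys.append(min(keys[i], keys[j]))
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (D[i, k] + D[j, k] - dij)
            D[nxt, k] = D[k, nxt] = dk
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1

    # final three clusters meet at one internal node (closed form)
    i, j, k = sorted(active, key=lambda x: keys[x])
    li = clamp(0.5 * (D[i, j] + D[i, k] - D[j, k]))
    lj = clamp(0.5 * (D[i, j] + D[j, k] - D[i, k]))
    lk = clamp(0.5 * (D[i, k] + D[j, k] - D[i, j]))
    root = TreeNode(children=[(nodes[i], li), (nodes[j], lj), (nodes[k], lk)])
    return PhyloTree(root=root, negative_clamped=clamped)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _build_profile(seqs: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """Thread every sequence onto the coordinates of the longest one.

    Returns (labels, n×L uint8 matrix); 0 encodes a gap.  Insertions
    relative to the reference are dropped — a deliberate simplification
    that keeps the profile a fixed-width resampling target.
    """
    labels = sorted(seqs)
    ref_label = max(labels, key=lambda l: (len(seqs[l]), l))
    ref = seqs[ref_label].upper()
    L = len(ref)
    prof = np.zeros((len(labels), L), dtype=np.uint8)
    for row, label in enumerate(labels):
        s = seqs[label].upper()
        if s == ref:
            prof[row] = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
            continue
        res = alignment.global_pairwise(s, ref)
        for op, ln, q, t in alignment.cigar_walk(res.cigar):
            if op in "=XM":
                prof[row, t:t + ln] = np.frombuffer(
                    s[q:q + ln].encode("ascii"), dtype=np.uint8)
            # 'D' leaves gap zeros; 'I' (insertion vs ref) is dropped
    return labels, prof


def _profile_distances(labels, prof, weights=None) -> DistanceMatrix:
    n, L = prof.shape
    if weights is None:
        weights = np.ones(L)
    d = np.zeros((n, n))
    nongap = prof != 0
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            shared = float(weights[both].sum())
            if shared == 0:
                dij = 1.0
            else:
                mism = float(weights[both & (prof[i] != prof[j])].sum())
                dij = mism / shared
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(labels, d)


def bootstrap_support(seqs: dict[str, str], n_replicates: int = 1000,
                      seed: int = 0) -> PhyloTree:
    """NJ tree with bootstrap supports on its internal edges.

    Profile columns are resampled with replacement per replicate;
    support is the percentage of replicate trees containing each
    internal bipartition of the main tree.
    """
    if n_replicates < 1:
        raise NlrkitError("n_replicates must be >= 1")
    labels, prof = _build_profile(seqs)
    n, L = prof.shape
    main = neighbor_joining(_profile_distances(labels, prof))

    # Per-pair per-column mismatch/valid masks allow O(pairs) replicate
    # distance computation via a single weight vector.
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    nongap = prof != 0
    valid = np.zeros((len(pairs), L), dtype=np.float64)
    mism = np.zeros((len(pairs), L), dtype=np.float64)
    for p, (i, j) in enumerate(pairs):
        both = nongap[i] & nongap[j]
        valid[p] = both
        mism[p] = both & (prof[i] != prof[j])

    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        w = np.bincount(cols, minlength=L).astype(np.float64)
        shared = valid @ w
        mis = mism @ w
        with np.errstate(invalid="ignore", divide="ignore"):
            dvec = np.where(shared > 0, mis / np.maximum(shared, 1e-300), 1.0)
        d = np.zeros((n, n))
        for p, (i, j) in enumerate(pairs):
            d[i, j] = d[j, i] = dvec[p]
        rep_tree = neighbor_joining(DistanceMatrix(labels, d))
        for part in rep_tree.bipartitions():
            counts[part] = counts.get(part, 0) + 1

    # attach supports to the main tree's internal edges
    all_leaves = set(labels)
    anchor = min(all_leaves)

    def annotate(node: TreeNode) -> set:
        if node.is_leaf:
            return {node.name}
        below = set()
        for child, _ in node.children:
            below |= annotate(child)
        if 2 <= len(below) <= len(all_leaves) - 2:
            canon = (all_leaves - below if anchor in below
                     else frozenset(below))
            node.support = 100.0 * counts.get(frozenset(canon), 0) / n_replicates
        return below

    annotate(main.root)
    return main


# ---------------------------------------------------------------------------
# Motif display sidecar
# ---------------------------------------------------------------------------

def attach_motif_profiles(tree: PhyloTree, loci_by_label: dict) -> "pd.DataFrame":
    """Per-leaf ordered motif-id strings for tree display.

    ``loci_by_label`` maps each leaf label to an object with a
    ``motif_chain``; an unmapped leaf raises.
    """
    import pandas as pd

    rows = []
    for leaf in tree.labels:
        if leaf not in loci_by_label:
            raise NlrkitError(f"leaf {leaf} has no locus mapping")
        chain = loci_by_label[leaf].motif_chain
        rows.append({"leaf": leaf, "motif_profile": ",".join(chain)})
    return pd.DataFrame(rows, columns=["leaf", "motif_profile"])
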