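"""Distance-based phylogenetics for species-monophyly verification.

For a short mini-barcode there are too few characters to estimate a
probabilistic substitution model reliably, so tree building here follows
the simplest route: a p-distance matrix (proportion of differing sites,
pairwise deletion of gap/N sites), classic Saitou-Nei neighbour joining,
and nonparametric bootstrap (column resampling) mapped as percent support
onto the reference tree's bipartitions.  Species-level monophyly — all
sequences of a species forming an exclusive clade — is the diagnostic
criterion the marker must satisfy.

Determinism contracts: Q-matrix ties break on the lowest (row, column)
index pair; negative NJ branch lengths are clamped to zero with the
deficit transferred to the sister branch; bootstrap is driven by an
explicit seed.  On additive matrices NJ recovers the generating tree
exactly, branch lengths included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import numpy as np

from .seqcore import BarcodeSeq

__all__ = [
    "DistanceMatrix",
    "PhyloTree",
    "p_distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
    "species_monophyly",
]

_EXCLUDED = frozenset("-N")  # sites removed pairwise before comparison


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    #: comparable-site counts per pair (pairwise deletion bookkeeping)
    denominators: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix has nonzero diagonal")
        if np.any(v < 0):
            raise ValueError("distance matrix has negative entries")
        self.values = v


def _char_matrix(aln: Sequence[BarcodeSeq | str]) -> tuple[list[str], np.ndarray]:
    seqs = [
        (s.id, s.residues) if isinstance(s, BarcodeSeq) else (f"seq{i+1}", s)
        for i, s in enumerate(aln)
    ]
    lengths = {len(r) for _, r in seqs}
    if len(lengths) != 1:
        raise ValueError("alignment sequences must be of equal length")
    labels = [lab for lab, _ in seqs]
    arr = np.array([list(r) for _, r in seqs])
    return labels, arr


def p_distance_matrix(aln: Sequence[BarcodeSeq | str]) -> DistanceMatrix:
    """Pairwise proportion of differing sites with pairwise deletion.

    Sites where either sequence carries a gap (``-``) or ``N`` are excluded
    for that pair; the per-pair comparable-site count is recorded in
    ``denominators``.  A pair with zero comparable sites is an error.
    """
    if len(aln) < 2:
        raise ValueError("need at least two sequences")
    labels, arr = _char_matrix(aln)
    n = len(labels)
    ok = ~np.isin(arr, list(_EXCLUDED))
    values = np.zeros((n, n))
    denom = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            comparable = ok[i] & ok[j]
            m = int(comparable.sum())
            if m == 0:
                raise ValueError(
                    f"pair ({labels[i]!r}, {labels[j]!r}) has no comparable sites"
                )
            diff = int((arr[i][comparable] != arr[j][comparable]).sum())
            values[i, j] = values[j, i] = diff / m
            denom[i, j] = denom[j, i] = m
    return DistanceMatrix(labels=labels, values=values, denominators=denom)


@dataclass
class PhyloTree:
    """Unrooted NJ tree with optional bootstrap supports.

    ``supports`` maps canonical bipartitions (frozenset of tip labels on
    the side *not* containing the alphabetically first tip) to percent
    support in [0, 100]; ``None`` when no bootstrap was run or the
    alignment carried no signal.
    """

    tree: dendropy.Tree
    labels: list[str]
    supports: Optional[dict[frozenset, float]] = None
    n_replicates: int = 0
    n_dropped: int = 0
    no_signal: bool = False
    seed: Optional[int] = None

    def bipartitions(self) -> set[frozenset]:
        return _bipartitions(self.tree, self.labels)

    def to_newick(self) -> str:
        if self.supports:
            _annotate_supports(self.tree, self.labels, self.supports)
        return self.tree.as_string(
            schema="newick", suppress_rooting=True
        ).strip()


def _canonical(side: Iterable[str], labels: Sequence[str]) -> frozenset:
    anchor = min(labels)
    side = frozenset(side)
    if anchor in side:
        side = frozenset(labels) - side
    return side


def _bipartitions(tree: dendropy.Tree, labels: Sequence[str]) -> set[frozenset]:
    """Non-trivial bipartitions as canonical tip-label sets."""
    out: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 2 <= len(below) <= len(labels) - 2:
            out.add(_canonical(below, labels))
    return out


def _annotate_supports(
    tree: dendropy.Tree, labels: Sequence[str], supports: Mapping[frozenset, float]
) -> None:
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = _canonical(
            (lf.taxon.label for lf in node.leaf_iter()), labels
        )
        if below in supports:
            node.label = str(int(round(supports[below])))


def neighbor_joining(d: DistanceMatrix) -> PhyloTree:
    """Classic Saitou-Nei neighbour joining.

    Q(i,j) = (m-2)·d(i,j) - r_i - r_j is minimised at each step (ties to
    the lowest index pair); branch lengths use the standard formulas, with
    negative values clamped to zero and the deficit moved to the sister
    branch so the joined path length is preserved.
    """
    n = len(d.labels)
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 tips")
    ns = dendropy.TaxonNamespace(list(d.labels))
    nodes: list[dendropy.Node] = []
    for lab in d.labels:
        node = dendropy.Node(taxon=ns.get_taxon(lab))
        nodes.append(node)
    D = [list(map(float, row)) for row in d.values]

    def clamp_pair(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(nodes) > 3:
        m = len(nodes)
        r = [sum(row) for row in D]
        best_q = None
        bi = bj = 0
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i][j] - r[i] - r[j]
                if best_q is None or q < best_q - 1e-12:
                    best_q, bi, bj = q, i, j
        i, j = bi, bj
        li = D[i][j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i][j] - li
        li, lj = clamp_pair(li, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        new_row = [
            max(0.0, (D[i][k] + D[j][k] - D[i][j]) / 2)
            for k in range(m)
            if k not in (i, j)
        ]
        keep = [k for k in range(m) if k not in (i, j)]
        D = [[D[a][b] for b in keep] for a in keep]
        for idx, row in enumerate(D):
            row.append(new_row[idx])
        D.append(new_row + [0.0])
        nodes = [nodes[k] for k in keep] + [parent]

    # final three-point closed form
    (a, b, c) = nodes
    dab, dac, dbc = D[0][1], D[0][2], D[1][2]
    la = (dab + dac - dbc) / 2
    lb = (dab + dbc - dac) / 2
    lc = (dac + dbc - dab) / 2
    root = dendropy.Node()
    for node, ln in ((a, la), (b, lb), (c, lc)):
        root.add_child(node)
        node.edge.length = max(ln, 0.0)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    tree.is_rooted = False
    return PhyloTree(tree=tree, labels=list(d.labels))


def bootstrap_support(
    aln: Sequence[BarcodeSeq],
    n_replicates: int = 500,
    seed: Optional[int] = None,
) -> PhyloTree:
    """Nonparametric bootstrap supports on the all-data NJ reference tree.

    Alignment columns are resampled with replacement; NJ is rebuilt per
    replicate; each reference-tree bipartition's support is the percent of
    retained replicates containing it.  Replicates in which some pair loses
    all comparable sites are dropped (counted, with a warning).  An
    alignment with no variable comparable sites carries no signal: supports
    are reported as n/a and ``no_signal`` is set.
    """
    ref = neighbor_joining(p_distance_matrix(aln))
    labels, arr = _char_matrix(aln)
    L = arr.shape[1]
    ok = ~np.isin(arr, list(_EXCLUDED))
    variable = False
    for col in range(L):
        vals = arr[ok[:, col], col]
        if len(set(vals.tolist())) > 1:
            variable = True
            break
    ref.seed = seed
    ref.n_replicates = n_replicates
    if not variable:
        ref.no_signal = True
        ref.supports = None
        return ref

    rng = np.random.default_rng(seed)
    ref_bps = ref.bipartitions()
    counts = {bp: 0 for bp in ref_bps}
    dropped = 0
    for _ in range(n_replicates):
        idx = rng.integers(0, L, size=L)
        sub = arr[:, idx]
        seqs = ["".join(row) for row in sub]
        try:
            dm = p_distance_matrix(
                [BarcodeSeq(lab, s) for lab, s in zip(labels, seqs)]
            )
        except ValueError:
            dropped += 1
            continue
        rep = neighbor_joining(dm)
        for bp in rep.bipartitions():
            if bp in counts:
                counts[bp] += 1
    retained = n_replicates - dropped
    if dropped:
        warnings.warn(
            f"{dropped} of {n_replicates} bootstrap replicates dropped "
            "(pair with no comparable sites)"
        )
    if retained == 0:
        ref.no_signal = True
        ref.supports = None
        ref.n_dropped = dropped
        return ref
    ref.supports = {bp: 100.0 * c / retained for bp, c in counts.items()}
    ref.n_dropped = dropped
    return ref


def species_monophyly(
    ptree: PhyloTree, species_of: Mapping[str, str]
) -> dict[str, dict]:
    """Per-species monophyly and the bootstrap support of the defining edge.

    A species with two or more tips is monophyletic iff some edge
    bipartition separates exactly its tips from all others; a single-tip
    species is trivially monophyletic with support n/a (None).
    """
    missing = [t for t in ptree.labels if t not in species_of]
    if missing:
        raise ValueError(f"tips without species label: {missing}")
    bps = ptree.bipartitions()
    out: dict[str, dict] = {}
    for sp in sorted(set(species_of.values())):
        tips = [t for t in ptree.labels if species_of[t] == sp]
        if len(tips) == 1:
            out[sp] = {"monophyletic": True, "n_tips": 1, "support": None}
            continue
        target = _canonical(tips, ptree.labels)
        # unrooted corner cases: all tips, or all-but-one, are always a clade
        mono = target in bps or len(tips) >= len(ptree.labels) - 1
        support = None
        if mono and ptree.supports:
            support = ptree.supports.get(target)
        out[sp] = {
            "monophyletic": mono,
            "n_tips": len(tips),
            "support": support,
        }
    return out
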