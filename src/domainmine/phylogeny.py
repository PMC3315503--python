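"""Distance-based phylogeny over the extended alignment.

Trees are built by classic neighbor joining over Poisson-corrected pairwise
distances. NJ replaces the approximate maximum-likelihood step a web service
would delegate to an external program: it is self-contained, deterministic
(ties broken by the lexicographically smallest leaf-label pair), and entirely
adequate for the tree's only downstream consumer, clade-based class
assignment. Trees are dendropy objects throughout; newick serialization
canonicalizes child order by smallest descendant label so round trips are
byte-stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

MIN_SHARED_COLUMNS = 20


class PhylogenyError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray  # symmetric, zero diagonal
    flagged_pairs: list[tuple[str, str]]  # pairs with too few shared columns

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise PhylogenyError("matrix shape does not match labels")
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0):
            raise PhylogenyError("distance matrix must be symmetric with zero diagonal")
        if not np.isfinite(m).all() or (m < 0).any():
            raise PhylogenyError("distances must be finite and non-negative")
        self.matrix = m


def _encode_rows(rows: dict[str, str]) -> tuple[list[str], np.ndarray]:
    labels = list(rows)
    n_cols = len(next(iter(rows.values())))
    arr = np.full((len(labels), n_cols), -1, dtype=np.int16)
    for i, lab in enumerate(labels):
        row = rows[lab]
        arr[i] = np.frombuffer(row.encode("ascii"), dtype=np.uint8).astype(np.int16)
        arr[i][arr[i] == ord("-")] = -1
    return labels, arr


def compute_distances(alignment_rows, model: str = "poisson") -> DistanceMatrix:
    """Pairwise distances over mutually ungapped columns.

    ``model`` is 'p-distance' (raw mismatch fraction) or 'poisson'
    (-ln(1 - p), the standard multiple-hit correction). Pairs sharing fewer
    than 20 ungapped columns (or saturated pairs) get the matrix maximum and
    are flagged.
    """
    if hasattr(alignment_rows, "all_rows"):
        rows = alignment_rows.all_rows()
    elif hasattr(alignment_rows, "rows"):
        rows = dict(alignment_rows.rows)
    else:
        rows = dict(alignment_rows)
    if len(rows) < 3:
        raise PhylogenyError("need at least 3 rows for a distance matrix")
    if model not in ("poisson", "p-distance"):
        raise PhylogenyError(f"unknown distance model {model!r}")
    labels, arr = _encode_rows(rows)
    n = len(labels)
    dist = np.zeros((n, n))
    undefined = np.zeros((n, n), dtype=bool)
    present = arr >= 0
    for i in range(n):
        shared = present[i] & present
        n_shared = shared.sum(axis=1)
        mism = ((arr[i] != arr) & shared).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_shared > 0, mism / np.maximum(n_shared, 1), 1.0)
        if model == "poisson":
            d = np.where(p < 0.999, -np.log1p(-np.minimum(p, 0.999)), np.inf)
        else:
            d = p
        bad = (n_shared < MIN_SHARED_COLUMNS) | ~np.isfinite(d)
        dist[i] = np.where(bad, np.nan, d)
        undefined[i] = bad
    np.fill_diagonal(dist, 0.0)
    np.fill_diagonal(undefined, False)
    finite = dist[~np.isnan(dist)]
    ceiling = finite.max() if finite.size else 1.0
    flagged = []
    for i in range(n):
        for j in range(i + 1, n):
            if undefined[i, j]:
                dist[i, j] = dist[j, i] = ceiling
                flagged.append((labels[i], labels[j]))
    dist = (dist + dist.T) / 2  # exact symmetry
    return DistanceMatrix(labels, dist, flagged)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Classic Saitou-Nei neighbor joining.

    Deterministic: among equal-Q pairs the pair with the lexicographically
    smallest (min leaf label, max leaf label) key is merged. Negative branch
    lengths are clamped to 0 with the deficit moved to the sister branch.
    """
    n = len(dm.labels)
    if n < 3:
        raise PhylogenyError("neighbor joining needs at least 3 labels")
    if not np.isfinite(dm.matrix).all():
        raise PhylogenyError("non-finite distances")
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for lab in dm.labels:
        node = dendropy.Node(taxon=taxa.new_taxon(lab))
        nodes.append(node)
    keys = [lab for lab in dm.labels]  # smallest descendant label per node
    D = dm.matrix.copy()
    active = list(range(n))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        k = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(Q <= qmin + 1e-12)
        best = min(
            (tuple(sorted((keys[active[a]], keys[active[b]]))), (a, b))
            for a, b in cand
            if a < b
        )
        a, b = best[1]
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = 0.5 * dij + (r[a] - r[b]) / (2 * (k - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        parent = dendropy.Node()
        ni, nj = nodes[i], nodes[j]
        parent.add_child(ni)
        parent.add_child(nj)
        ni.edge.length = li
        nj.edge.length = lj
        # distances to the new node
        new_d = 0.5 * (D[i, :] + D[j, :] - dij)
        D[i, :] = new_d
        D[:, i] = new_d
        D[i, i] = 0.0
        nodes[i] = parent
        keys[i] = min(keys[i], keys[j])
        active.remove(j)
    # final three-way join (closed-form star lengths)
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    center = dendropy.Node()
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        center.add_child(nodes[idx])
        nodes[idx].edge.length = max(ln, 0.0)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root a copy of the tree at the midpoint of its longest leaf-to-leaf
    path (the readout the clade classifier walks rootward on)."""
    rooted = tree.clone(depth=1)
    if len(rooted.seed_node.child_nodes()) == 2:
        rooted.deroot()  # collapse an existing root so rerooting is clean
    rooted.reroot_at_midpoint(update_bipartitions=False)
    rooted.is_rooted = True
    return rooted


def _canonical_sort(tree: dendropy.Tree) -> None:
    def min_label(node) -> str:
        if node.is_leaf():
            return node.taxon.label if node.taxon else ""
        return min(min_label(c) for c in node.child_nodes())

    for node in tree.preorder_node_iter():
        children = node.child_nodes()
        if len(children) > 1:
            node.set_child_nodes(sorted(children, key=min_label))


def write_newick(tree: dendropy.Tree, path=None) -> str:
    """Canonical newick (children sorted by smallest descendant label,
    branch lengths to 6 significant digits)."""
    out = tree.clone(depth=1)
    _canonical_sort(out)
    text = out.as_string(
        schema="newick",
        suppress_rooting=True,
        preserve_spaces=True,
        real_value_format_specifier=".6g",
    ).strip() + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_newick(text: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise PhylogenyError(f"malformed newick: {exc}") from exc


def patristic_distances(tree: dendropy.Tree):
    """Leaf-to-leaf path-length matrix as (labels, ndarray)."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            out[i, j] = out[j, i] = d
    return labels, out
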