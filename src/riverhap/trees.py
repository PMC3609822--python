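"""Neighbor-joining and UPGMA trees, site bootstrap, and clade extraction.

Trees are :class:`dendropy.Tree` objects. Bootstrap support (percent of
replicates reproducing a bipartition) is stored in the *label* of the
bipartition's head node, so it survives cloning and newick round trips.

The haplogroup (clade) partition is derived mechanically: after collapsing
branches below the support threshold, the maximal midpoint-rooted clusters
whose subtending branch keeps >= threshold support become clades; leaves
outside any supported cluster become singleton clades.
"""

from __future__ import annotations

import numpy as np
import dendropy

from .distances import DistanceMatrix, base_frequencies, _tn93_pair
from .errors import InputError
from .io import Alignment, MISSING_CODES


# ---------------------------------------------------------------------------
# agglomeration


def _check_matrix(d: DistanceMatrix, min_n: int) -> np.ndarray:
    if len(d.labels) < min_n:
        raise InputError(f"need at least {min_n} taxa, got {len(d.labels)}")
    vals = np.asarray(d.values, float)
    if np.isnan(vals).any():
        raise InputError("distance matrix contains NaN entries")
    return vals.copy()


def _pick_pair(score: np.ndarray, reps: list[str], alive: list[int]):
    """Index pair minimising ``score``; ties broken by sorted cluster reps."""
    smin = score.min()
    tol = 1e-12 * max(1.0, abs(smin))
    best = None
    best_key = None
    for a, b in np.argwhere(score <= smin + tol):
        if a >= b:
            continue
        key = tuple(sorted((reps[alive[a]], reps[alive[b]])))
        if best_key is None or key < best_key:
            best_key, best = key, (int(a), int(b))
    return best


def build_nj(d: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Returns an unrooted tree (trifurcation at the seed node). Negative branch
    lengths are retained internally and only clamped when writing newick.
    """
    D = _check_matrix(d, 3)
    taxa = dendropy.TaxonNamespace(d.labels)
    tree = dendropy.Tree(taxon_namespace=taxa)

    nodes: list[dendropy.Node] = []
    reps: list[str] = []
    for label in d.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
        reps.append(label)
    alive = list(range(len(d.labels)))

    full = D  # grows as clusters are added
    while len(alive) > 3:
        m = len(alive)
        sub = full[np.ix_(alive, alive)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        a, b = _pick_pair(q, reps, alive)
        i, j = alive[a], alive[b]
        dij = sub[a, b]
        bi = 0.5 * dij + (r[a] - r[b]) / (2.0 * (m - 2))
        bj = dij - bi
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = bi
        nodes[j].edge.length = bj
        # distances from the new cluster to the remaining ones
        new_row = np.full(full.shape[0] + 1, 0.0)
        for c in alive:
            if c in (i, j):
                continue
            new_row[c] = 0.5 * (full[i, c] + full[j, c] - dij)
        full = np.pad(full, ((0, 1), (0, 1)))
        full[-1, :-1] = new_row[:-1]
        full[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        reps.append(min(reps[i], reps[j]))
        alive = [c for c in alive if c not in (i, j)] + [len(nodes) - 1]

    # final trifurcation (or the n == 3 case directly)
    i, j, k = alive
    root = tree.seed_node
    for child in (nodes[i], nodes[j], nodes[k]):
        root.add_child(child)
    nodes[i].edge.length = 0.5 * (full[i, j] + full[i, k] - full[j, k])
    nodes[j].edge.length = 0.5 * (full[i, j] + full[j, k] - full[i, k])
    nodes[k].edge.length = 0.5 * (full[i, k] + full[j, k] - full[i, j])
    tree.is_rooted = False
    return tree


def build_upgma(d: DistanceMatrix) -> dendropy.Tree:
    """Average-linkage (UPGMA) ultrametric tree with deterministic ties."""
    D = _check_matrix(d, 2)
    taxa = dendropy.TaxonNamespace(d.labels)
    tree = dendropy.Tree(taxon_namespace=taxa)

    nodes = [dendropy.Node(taxon=taxa.get_taxon(l)) for l in d.labels]
    reps = list(d.labels)
    sizes = [1] * len(d.labels)
    heights = [0.0] * len(d.labels)
    alive = list(range(len(d.labels)))
    full = D

    while len(alive) > 1:
        sub = full[np.ix_(alive, alive)]
        np.fill_diagonal(sub, np.inf)
        a, b = _pick_pair(sub, reps, alive)
        i, j = alive[a], alive[b]
        h = full[i, j] / 2.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = h - heights[i]
        nodes[j].edge.length = h - heights[j]
        new_row = np.zeros(full.shape[0] + 1)
        for c in alive:
            if c in (i, j):
                continue
            new_row[c] = (sizes[i] * full[i, c] + sizes[j] * full[j, c]) / (
                sizes[i] + sizes[j])
        full = np.pad(full, ((0, 1), (0, 1)))
        full[-1, :-1] = new_row[:-1]
        full[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        reps.append(min(reps[i], reps[j]))
        sizes.append(sizes[i] + sizes[j])
        heights.append(h)
        alive = [c for c in alive if c not in (i, j)] + [len(nodes) - 1]

    root = nodes[alive[0]]
    tree.seed_node = root
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# bipartitions and bootstrap


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return sorted(l.taxon.label for l in tree.leaf_node_iter())


def _canon(side: frozenset, universe: frozenset) -> frozenset:
    """Canonical form of a bipartition: the side without the anchor leaf."""
    anchor = min(universe)
    return frozenset(universe - side) if anchor in side else side


def bipartitions(tree: dendropy.Tree) -> dict[frozenset, dendropy.Node]:
    """Non-trivial bipartitions, canonicalised, mapped to their head node."""
    universe = frozenset(leaf_labels(tree))
    n = len(universe)
    out: dict[frozenset, dendropy.Node] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._leafset = frozenset([node.taxon.label])
            continue
        node._leafset = frozenset().union(*(c._leafset for c in
                                            node.child_nodes()))
        if node.parent_node is None:
            continue
        side = node._leafset
        if 2 <= len(side) <= n - 2:
            out[_canon(side, universe)] = node
    return out


def node_support(node: dendropy.Node) -> float | None:
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


def _resampled_distance(enc: np.ndarray, labels, metric: str):
    """Distance matrix from an encoded (possibly resampled) alignment."""
    n, L = enc.shape
    ok = np.ones(enc.shape, bool)
    for code in MISSING_CODES:
        ok &= enc != code
    vals = np.zeros((n, n))
    degenerate = False
    if metric == "diff_count":
        for i in range(n):
            both = ok[i] & ok[i + 1:]
            neq = (enc[i] != enc[i + 1:]) & both
            vals[i, i + 1:] = neq.sum(axis=1)
            if (both.sum(axis=1) == 0).any():
                degenerate = True
        vals += vals.T
    elif metric == "tn93":
        counts = np.array([(enc == b).sum() for b in range(4)], float)
        if (counts == 0).any():
            return None, True
        freqs = counts / counts.sum()
        for i in range(n):
            for j in range(i + 1, n):
                v = _tn93_pair(enc[i], enc[j], freqs, strict=False)
                if np.isnan(v):
                    degenerate = True
                vals[i, j] = vals[j, i] = v
    else:
        raise InputError(f"unknown metric {metric!r}")
    return vals, degenerate


def bootstrap_support(aln: Alignment, n_reps: int, seed: int,
                      metric: str = "diff_count",
                      builder: str = "nj") -> dendropy.Tree:
    """Site bootstrap: percent of replicates reproducing each bipartition.

    Sites are resampled with replacement ``n_reps`` times; the chosen builder
    (``nj`` or ``upgma``) is re-run on each resampled distance matrix, and
    each internal branch of the point-estimate tree gets the percentage of
    replicates containing its bipartition (stored as the node label).
    Replicates where some pair has no comparable sites (or TN93 saturates)
    are skipped; the number skipped is recorded as ``tree.bootstrap_skipped``.
    """
    if n_reps < 1:
        raise InputError("n_reps must be >= 1")
    build = {"nj": build_nj, "upgma": build_upgma}[builder]
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        enc = aln.encoded()
        vals, degenerate = _resampled_distance(enc, aln.ids, metric)
        if vals is None or degenerate:
            raise InputError("point-estimate distances are degenerate")
        point = build(DistanceMatrix(list(aln.ids), vals, metric))
        point_bp = bipartitions(point)
        counts = {bp: 0 for bp in point_bp}
        rng = np.random.default_rng(seed)
        used = 0
        skipped = 0
        for _ in range(n_reps):
            cols = rng.integers(0, aln.length, aln.length)
            rvals, bad = _resampled_distance(enc[:, cols], aln.ids, metric)
            if rvals is None or bad:
                skipped += 1
                continue
            rep_tree = build(DistanceMatrix(list(aln.ids), rvals, metric))
            rep_bp = bipartitions(rep_tree)
            for bp in counts:
                node = rep_bp.get(bp)
                # a zero-length branch carries no signal for its bipartition
                if node is not None and node.edge.length is not None \
                        and node.edge.length > 1e-12:
                    counts[bp] += 1
            used += 1
    if used == 0:
        raise InputError("all bootstrap replicates were degenerate")
    for bp, node in point_bp.items():
        node.label = f"{100.0 * counts[bp] / used:g}"
    point.bootstrap_reps = used
    point.bootstrap_skipped = skipped
    return point


# ---------------------------------------------------------------------------
# collapsing and clade extraction


def _clone(tree: dendropy.Tree) -> dendropy.Tree:
    return tree.clone(depth=1)


def collapse_low_support(tree: dendropy.Tree,
                         threshold_percent: float = 70.0) -> dendropy.Tree:
    """Contract every internal branch with support below the threshold.

    The leaf set is unchanged; the result is generally multifurcating.
    """
    out = _clone(tree)
    to_collapse = []
    for node in out.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        sup = node_support(node)
        if sup is not None and sup < threshold_percent:
            to_collapse.append(node)
    for node in to_collapse:
        node.edge.collapse()
    return out


def to_newick(tree: dendropy.Tree, clamp_negative: bool = True) -> str:
    """Newick string with supports as internal labels; lengths clamped >= 0."""
    out = _clone(tree)
    if clamp_negative:
        for edge in out.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                edge.length = 0.0
    return out.as_string(schema="newick", suppress_rooting=True).strip()


def extract_clades(tree: dendropy.Tree,
                   min_support: float = 70.0) -> dict[str, str]:
    """Partition leaves into clades = maximal supported rooted clusters.

    Descending from the root, the first cluster on each path whose
    subtending bipartition keeps >= ``min_support`` percent support becomes
    a clade; leaves in no supported cluster are singleton clades.

    The root for the descent is chosen as the internal node from which the
    largest number of supported clusters emanate (counting each adjacent
    component, including the one "above" the node) — i.e. the backbone
    centre of the collapsed tree; ties resolve to the earliest such node in
    preorder. This makes the partition independent of where the builder
    happened to leave its seed node. When the chosen root has exactly two
    children both sides carry the same bipartition, and naively accepting
    the larger side would fuse everything outside the deeper cluster into
    one clade; the larger child is then treated as the ancestral side and
    is descended into whenever it resolves into two or more supported
    internal clusters.

    Labels ``C1, C2, ...`` are assigned by decreasing cluster size, then by
    lexicographically smallest member.
    """
    universe = frozenset(leaf_labels(tree))
    n = len(universe)
    supports: dict[frozenset, float] = {}
    for bp, node in bipartitions(tree).items():
        sup = node_support(node)
        if sup is not None:
            supports[bp] = sup

    rooted = _clone(tree)

    def _supported_side(side: frozenset) -> bool:
        if not (2 <= len(side) <= n - 2):
            return False
        sup = supports.get(_canon(side, universe))
        return sup is not None and sup >= min_support

    # root at the backbone centre: max count of supported adjacent clusters
    sets: dict[int, frozenset] = {}
    for node in rooted.postorder_node_iter():
        if node.is_leaf():
            sets[id(node)] = frozenset([node.taxon.label])
        else:
            sets[id(node)] = frozenset().union(
                *(sets[id(c)] for c in node.child_nodes()))
    best_node, best_count = None, -1
    for node in rooted.preorder_internal_node_iter():
        sides = [sets[id(c)] for c in node.child_nodes()]
        if node.parent_node is not None:
            sides.append(universe - sets[id(node)])
        count = sum(1 for s in sides if _supported_side(s))
        if count > best_count:
            best_node, best_count = node, count
    if best_node is not None and best_node is not rooted.seed_node:
        rooted.reroot_at_node(best_node, update_bipartitions=False)

    clusters: list[set[str]] = []

    def leafset(node) -> frozenset:
        return frozenset(l.taxon.label for l in node.leaf_iter())

    def supported(side: frozenset) -> bool:
        if not (2 <= len(side) <= n - 2):
            return False
        sup = supports.get(_canon(side, universe))
        return sup is not None and sup >= min_support

    def descend(node, ancestral_side: bool = False) -> None:
        if node.is_leaf():
            clusters.append({node.taxon.label})
            return
        side = leafset(node)
        if ancestral_side:
            internal_supported = sum(
                1 for c in node.child_nodes()
                if not c.is_leaf() and supported(leafset(c)))
            if internal_supported >= 2:
                for child in node.child_nodes():
                    descend(child)
                return
        if node.parent_node is not None and supported(side):
            clusters.append(set(side))
            return
        for child in node.child_nodes():
            descend(child)

    root = rooted.seed_node
    children = root.child_nodes()
    if len(children) == 2:
        # order so the smaller (clade-like) side is processed normally and
        # the larger side as the ancestral remainder
        sized = sorted(children, key=lambda c: (len(leafset(c)),
                                                min(leafset(c))))
        descend(sized[0])
        descend(sized[1], ancestral_side=True)
    else:
        for child in children:
            descend(child)

    clusters.sort(key=lambda c: (-len(c), min(c)))
    partition: dict[str, str] = {}
    for k, cluster in enumerate(clusters, start=1):
        for leaf in sorted(cluster):
            partition[leaf] = f"C{k}"
    return partition
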