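"""Dated-tree I/O, validation, and taxonomic imputation.

Trees are rooted, dated (branch lengths in Myr), and nominally ultrametric:
node ages are measured backward from the present, so every extant tip sits at
age 0.  :class:`dendropy.Tree` is the interchange container; numerical modules
convert to the flat :class:`TreeArrays` view.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "TreeArrays",
    "UltrametricReport",
    "TaxonConstraint",
    "read_trees",
    "write_trees",
    "parse_newick",
    "to_arrays",
    "validate_ultrametric",
    "impute_missing_taxa",
]

#: significant digits used when writing branch lengths
_BLEN_FORMAT = ".12g"


class TreeFormatError(ValueError):
    """Raised for unparseable or structurally invalid tree input."""


@dataclass
class UltrametricReport:
    ok: bool
    max_deviation: float
    tol: float


@dataclass
class TaxonConstraint:
    """Placement constraint: ``missing_taxon`` attaches within ``clade``.

    ``clade`` is a set of tip labels that must be monophyletic in the target
    tree; the new taxon may attach to any branch of that clade including its
    stem branch.
    """

    missing_taxon: str
    clade: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        self.clade = frozenset(self.clade)


@dataclass
class TreeArrays:
    """Flat array view of a rooted tree.

    Nodes are indexed 0..2n-2 with tips first (0..n-1, in ``labels`` order).
    ``parent[root] == -1``; ``postorder`` lists node indices children-first.
    """

    parent: np.ndarray
    blen: np.ndarray
    age: np.ndarray
    children: list
    postorder: np.ndarray
    labels: list

    @property
    def n_tips(self) -> int:
        return len(self.labels)

    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    @property
    def root_age(self) -> float:
        return float(self.age[self.root])

    def is_binary(self) -> bool:
        return all(len(c) in (0, 2) for c in self.children)

    def total_length(self) -> float:
        mask = self.parent >= 0
        return float(self.blen[mask].sum())

    def n_subtended_tips(self) -> np.ndarray:
        out = np.zeros(self.n_nodes, dtype=int)
        for i in self.postorder:
            out[i] = 1 if not self.children[i] else sum(out[c] for c in self.children[i])
        return out

    def clade_matrix(self) -> np.ndarray:
        """Boolean (n_nodes, n_tips): tip j descends from (or is) node i."""
        m = np.zeros((self.n_nodes, self.n_tips), dtype=bool)
        for i in self.postorder:
            if not self.children[i]:
                m[i, i] = True
            else:
                for c in self.children[i]:
                    m[i] |= m[c]
        return m


def parse_newick(s: str) -> dendropy.Tree:
    """Parse a single Newick string into a rooted dendropy tree."""
    return read_trees(io.StringIO(s), fmt="newick")[0]


def _check_tree(tree: dendropy.Tree) -> None:
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise TreeFormatError(f"duplicate tip labels: {sorted(dupes)}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise TreeFormatError(f"negative branch length {edge.length}")


def read_trees(path, fmt: str = "newick") -> list:
    """Read one or more rooted trees from ``path`` (str/Path or file object).

    Supports Newick and Nexus (with or without a translate table).  Raises
    :class:`TreeFormatError` with a distinct message for unreadable files,
    duplicate tip labels, and negative branch lengths.
    """
    if fmt not in ("newick", "nexus"):
        raise ValueError(f"unknown tree format {fmt!r}")
    kwargs = dict(schema=fmt, rooting="force-rooted",
                  preserve_underscores=True)
    try:
        if hasattr(path, "read"):
            tl = dendropy.TreeList.get(file=path, **kwargs)
        else:
            tl = dendropy.TreeList.get(path=str(path), **kwargs)
    except (OSError, dendropy.utility.error.DataParseError, ValueError) as e:
        raise TreeFormatError(f"could not read {fmt} trees: {e}") from e
    trees = list(tl)
    if not trees:
        raise TreeFormatError("file contains no trees")
    for t in trees:
        _check_tree(t)
    return trees


def write_trees(trees, path, fmt: str = "newick") -> None:
    """Write trees to ``path`` in Newick or Nexus."""
    if isinstance(trees, dendropy.Tree):
        trees = [trees]
    tns = trees[0].taxon_namespace
    tl = dendropy.TreeList(trees, taxon_namespace=tns)
    kwargs = dict(schema=fmt, real_value_format_specifier=_BLEN_FORMAT,
                  unquoted_underscores=True)
    if fmt == "newick":
        kwargs["suppress_rooting"] = True
    if hasattr(path, "write"):
        tl.write(file=path, **kwargs)
    else:
        tl.write(path=str(path), **kwargs)


def to_arrays(tree: dendropy.Tree) -> TreeArrays:
    """Convert a dendropy tree to the flat array view (tips first)."""
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label if lf.taxon else "" for lf in leaves]
    index = {id(lf): i for i, lf in enumerate(leaves)}
    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    for j, nd in enumerate(internals):
        index[id(nd)] = len(leaves) + j
    n = len(leaves) + len(internals)
    parent = np.full(n, -1, dtype=int)
    blen = np.zeros(n)
    children: list = [[] for _ in range(n)]
    for nd in tree.preorder_node_iter():
        i = index[id(nd)]
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            blen[i] = nd.edge.length if nd.edge.length is not None else 0.0
            children[parent[i]].append(i)
    # node depths from root, then ages relative to deepest tip
    depth = np.zeros(n)
    order = [index[id(nd)] for nd in tree.preorder_node_iter()]
    for i in order:
        if parent[i] >= 0:
            depth[i] = depth[parent[i]] + blen[i]
    height = depth[: len(leaves)].max() if leaves else 0.0
    age = height - depth
    postorder = np.array(list(reversed(order)), dtype=int)
    return TreeArrays(parent=parent, blen=blen, age=age, children=children,
                      postorder=postorder, labels=labels)


def from_arrays(arr: TreeArrays) -> dendropy.Tree:
    """Rebuild a dendropy tree from a :class:`TreeArrays`."""
    tns = dendropy.TaxonNamespace()
    nodes = [dendropy.Node() for _ in range(arr.n_nodes)]
    for i, lab in enumerate(arr.labels):
        nodes[i].taxon = tns.require_taxon(label=lab)
    for i in range(arr.n_nodes):
        p = arr.parent[i]
        if p >= 0:
            nodes[p].add_child(nodes[i])
            nodes[i].edge.length = float(arr.blen[i])
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = nodes[arr.root]
    tree.is_rooted = True
    return tree


def validate_ultrametric(tree, tol: float = None) -> UltrametricReport:
    """Check tip-depth agreement: ok iff max |depth_i - mean depth| <= tol.

    ``tol`` defaults to 1e-6 relative to tree height.  Diagnostic only; never
    raises.
    """
    arr = tree if isinstance(tree, TreeArrays) else to_arrays(tree)
    n = arr.n_tips
    depth = np.zeros(arr.n_nodes)
    for i in arr.postorder[::-1]:
        p = arr.parent[i]
        if p >= 0:
            depth[i] = depth[p] + arr.blen[i]
    tip_depth = depth[:n]
    dev = float(np.max(np.abs(tip_depth - tip_depth.mean()))) if n else 0.0
    if tol is None:
        height = float(tip_depth.max()) if n else 0.0
        tol = 1e-6 * max(height, 1.0)
    return UltrametricReport(ok=dev <= tol, max_deviation=dev, tol=tol)


def _mrca(tree: dendropy.Tree, labels) -> dendropy.Node:
    taxa = [tree.taxon_namespace.get_taxon(l) for l in labels]
    if any(t is None for t in taxa):
        missing = [l for l, t in zip(labels, taxa) if t is None]
        raise ValueError(f"constraint labels not in tree: {missing}")
    if len(taxa) == 1:
        return tree.find_node_with_taxon_label(labels[0] if isinstance(labels, list) else next(iter(labels)))
    return tree.mrca(taxa=taxa)


def impute_missing_taxa(tree: dendropy.Tree, constraints, seed=None) -> dendropy.Tree:
    """Attach each missing taxon inside its constraint clade.

    The attachment branch is drawn with probability proportional to branch
    length among the clade's branches (its stem included); the attachment age
    is uniform on that branch.  The new tip is pendant to age 0, so the output
    stays ultrametric.  The induced subtree on the original tips is unchanged.
    """
    rng = np.random.default_rng(seed)
    tree = tree.clone(depth=1)
    tree.is_rooted = True  # mrca() silently deroots trees not flagged rooted
    if not constraints:
        return tree
    existing = {lf.taxon.label for lf in tree.leaf_node_iter()}
    for con in constraints:
        if con.missing_taxon in existing:
            raise ValueError(f"taxon {con.missing_taxon!r} already present")
        clade_labels = sorted(con.clade)
        mrca = _mrca(tree, clade_labels)
        n_under = sum(1 for _ in mrca.leaf_iter())
        if n_under != len(clade_labels):
            raise ValueError(
                f"constraint clade for {con.missing_taxon!r} is not "
                f"monophyletic ({n_under} tips under MRCA, {len(clade_labels)} listed)")
        # candidate branches: clade stem + every branch inside the clade
        cand = [nd for nd in mrca.preorder_iter()
                if nd.edge.length is not None and nd.parent_node is not None]
        if mrca.parent_node is None:
            # clade is the whole tree: no stem branch available
            cand = [nd for nd in cand if nd is not mrca]
        lens = np.array([nd.edge.length for nd in cand], dtype=float)
        if lens.sum() <= 0:
            raise ValueError("constraint clade has zero total branch length")
        k = rng.choice(len(cand), p=lens / lens.sum())
        host = cand[k]
        # ages: host node age a0, parent age a0 + len; attach uniform between
        a0 = _node_age(host)
        attach_age = a0 + rng.uniform(0.0, host.edge.length)
        _attach_pendant(tree, host, con.missing_taxon, attach_age, a0)
        existing.add(con.missing_taxon)
    return tree


def _node_age(nd: dendropy.Node) -> float:
    # age above the deepest descendant tip; extant trees have tips at age 0
    best = 0.0
    stack = [(nd, 0.0)]
    while stack:
        cur, d = stack.pop()
        if cur.is_leaf():
            best = max(best, d)
        for ch in cur.child_nodes():
            stack.append((ch, d + (ch.edge.length or 0.0)))
    return best


def _attach_pendant(tree, host, label, attach_age, host_age):
    parent = host.parent_node
    new_internal = dendropy.Node()
    parent.remove_child(host)
    parent.add_child(new_internal)
    new_internal.add_child(host)
    new_internal.edge.length = host.edge.length - (attach_age - host_age)
    host.edge.length = attach_age - host_age
    tip = dendropy.Node()
    tip.taxon = tree.taxon_namespace.require_taxon(label=label)
    new_internal.add_child(tip)
    tip.edge.length = attach_age
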