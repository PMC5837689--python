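"""Reading, canonicalizing, and writing phylogenetic trees and tree sets.

Trees are held as :class:`dendropy.Tree` objects on a shared
:class:`dendropy.TaxonNamespace`.  All cross-tree comparisons in this
package operate on unrooted, metadata-stripped canonical forms; this module
provides the canonicalization primitives (:func:`strip_metadata`,
:func:`unroot`, :func:`restrict`) plus a deterministic newick writer whose
output is a usable topology key.

Newick dialect: internal node labels that parse as numbers in [0, 100] are
interpreted as support values (the common RAxML / consensus convention);
anything else is kept as an internal node name.  Negative branch lengths
are rejected at parse time; zero lengths are allowed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy

__all__ = [
    "TaxonSet",
    "TreeSet",
    "NewickParseError",
    "TreeValidationError",
    "parse_newick",
    "parse_newick_list",
    "write_newick",
    "canonical_newick",
    "strip_metadata",
    "unroot",
    "restrict",
    "leaf_labels",
    "get_support",
    "set_support",
    "read_tree_file",
    "read_manifest",
    "write_manifest",
]


class NewickParseError(ValueError):
    """Raised for malformed newick input; carries a character offset when known."""

    def __init__(self, message: str, offset: int | None = None):
        if offset is not None:
            message = f"{message} (at character offset {offset})"
        super().__init__(message)
        self.offset = offset


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates a structural invariant."""


@dataclass(frozen=True)
class TaxonSet:
    """An ordered (lexicographic) universe of unique taxon labels.

    The first label in sorted order is the *reference taxon* used to
    canonicalize bipartitions.
    """

    labels: tuple[str, ...]

    def __post_init__(self):
        ordered = tuple(sorted(self.labels))
        if len(set(ordered)) != len(ordered):
            raise TreeValidationError("taxon labels must be unique")
        if any(not lab for lab in ordered):
            raise TreeValidationError("taxon labels must be non-empty")
        object.__setattr__(self, "labels", ordered)

    @property
    def reference_taxon(self) -> str:
        return self.labels[0]

    def __contains__(self, label: str) -> bool:
        return label in set(self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)


def _check_balanced(text: str) -> None:
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError("unbalanced ')'", offset=i)
    if depth != 0:
        raise NewickParseError("unbalanced '(': missing closing parenthesis",
                               offset=len(text) - 1)
    if ";" not in text:
        raise NewickParseError("missing terminal ';'", offset=len(text) - 1)


def _interpret_supports(tree: dendropy.Tree) -> None:
    """Move numeric internal-node labels in [0, 100] onto ``node.support``."""
    for nd in tree.preorder_node_iter():
        nd.support = None
        if nd.is_leaf() or nd is tree.seed_node:
            continue
        if nd.label is not None:
            try:
                val = float(nd.label)
            except ValueError:
                continue
            if 0.0 <= val <= 100.0:
                nd.support = val
                nd.label = None


def _validate(tree: dendropy.Tree) -> None:
    seen: set[str] = set()
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise TreeValidationError("every leaf must be labeled")
        if leaf.taxon.label in seen:
            raise TreeValidationError(
                f"duplicate leaf label {leaf.taxon.label!r}")
        seen.add(leaf.taxon.label)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise TreeValidationError(
                f"negative branch length {edge.length} rejected")


def parse_newick(text: str,
                 taxon_namespace: dendropy.TaxonNamespace | None = None,
                 ) -> dendropy.Tree:
    """Parse one newick string into a tree.

    Internal labels that are numbers in [0, 100] become support values
    (``node.support``); branch lengths and bracketed comments follow the
    standard newick conventions.  Duplicate leaf labels and negative branch
    lengths raise errors.
    """
    _check_balanced(text)
    tn = taxon_namespace if taxon_namespace is not None else dendropy.TaxonNamespace()
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            taxon_namespace=tn,
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        if "duplicate" in str(exc).lower():
            raise TreeValidationError(
                f"duplicate leaf label: {exc}") from exc
        raise NewickParseError(f"malformed newick: {exc}") from exc
    _validate(tree)
    _interpret_supports(tree)
    return tree


def parse_newick_list(text: str,
                      taxon_namespace: dendropy.TaxonNamespace | None = None,
                      ) -> list[dendropy.Tree]:
    """Parse a multi-tree newick document (one tree per ';')."""
    chunks = [c.strip() for c in text.split(";") if c.strip()]
    tn = taxon_namespace if taxon_namespace is not None else dendropy.TaxonNamespace()
    return [parse_newick(c + ";", taxon_namespace=tn) for c in chunks]


def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


def get_support(node: dendropy.Node) -> float | None:
    return getattr(node, "support", None)


def set_support(node: dendropy.Node, value: float | None) -> None:
    node.support = value


def _min_descendant(node: dendropy.Node, cache: dict) -> str:
    if id(node) in cache:
        return cache[id(node)]
    if node.is_leaf():
        val = node.taxon.label
    else:
        val = min(_min_descendant(c, cache) for c in node.child_nodes())
    cache[id(node)] = val
    return val


def _write_node(node: dendropy.Node, cache: dict, lengths: bool,
                supports: bool, out: io.StringIO) -> None:
    if node.is_leaf():
        out.write(node.taxon.label)
    else:
        children = sorted(node.child_nodes(),
                          key=lambda c: _min_descendant(c, cache))
        out.write("(")
        for i, c in enumerate(children):
            if i:
                out.write(",")
            _write_node(c, cache, lengths, supports, out)
        out.write(")")
        sup = get_support(node)
        if supports and sup is not None:
            out.write(f"{sup:g}")
        elif node.label:
            out.write(node.label)
    if lengths and node.edge.length is not None and node.parent_node is not None:
        out.write(f":{node.edge.length:g}")


def write_newick(tree: dendropy.Tree, lengths: bool = True,
                 supports: bool = True) -> str:
    """Write a tree as newick with children ordered by smallest descendant label.

    The ordering makes output deterministic: two structurally identical
    trees always serialize identically.
    """
    out = io.StringIO()
    _write_node(tree.seed_node, {}, lengths, supports, out)
    out.write(";")
    return out.getvalue()


def canonical_newick(tree: dendropy.Tree) -> str:
    """Topology key: canonical newick of the unrooted, metadata-stripped form.

    Two trees yield the same string iff they have the same unrooted
    topology (the tree is rebuilt from its canonical split set, so the
    result does not depend on the input's rooting or child order).
    """
    from .splits import split_set, tree_from_splits

    rebuilt = tree_from_splits(split_set(tree), leaf_labels(tree))
    return write_newick(rebuilt, lengths=False, supports=False)


def _clone(tree: dendropy.Tree) -> dendropy.Tree:
    t = tree.clone(depth=1)
    # dendropy's clone does not copy dynamic attributes reliably for all paths
    for orig, copy in zip(tree.preorder_node_iter(), t.preorder_node_iter()):
        copy.support = get_support(orig)
    return t


def strip_metadata(tree: dendropy.Tree) -> dendropy.Tree:
    """Return a copy with all branch lengths and support values removed."""
    t = _clone(tree)
    for nd in t.preorder_node_iter():
        nd.edge.length = None
        nd.support = None
    return t


def unroot(tree: dendropy.Tree) -> dendropy.Tree:
    """Return an unrooted copy: a degree-2 root is suppressed.

    The nontrivial split set is unchanged.  Requires >= 3 leaves.
    """
    n_leaves = sum(1 for _ in tree.leaf_node_iter())
    if n_leaves < 3:
        raise TreeValidationError("unrooting requires at least 3 leaves")
    t = _clone(tree)
    t.is_rooted = False
    seed = t.seed_node
    children = seed.child_nodes()
    if len(children) == 2:
        # merge: absorb an internal child's children into the seed node
        internal = next((c for c in children if not c.is_leaf()), None)
        if internal is None:  # 2-leaf case excluded above; defensive
            return t
        other = children[0] if children[1] is internal else children[1]
        length = None
        if internal.edge.length is not None or other.edge.length is not None:
            length = (internal.edge.length or 0.0) + (other.edge.length or 0.0)
        seed.remove_child(internal)
        for gc in internal.child_nodes():
            internal.remove_child(gc)
            seed.add_child(gc)
        other.edge.length = length
    return t


def restrict(tree: dendropy.Tree, keep: Iterable[str]) -> dendropy.Tree:
    """Return the induced subtree on ``keep`` (intersected with the leaf set).

    Pruned degree-2 nodes are suppressed with branch lengths summed.
    Requires at least 3 surviving leaves.
    """
    keep = set(keep)
    survivors = keep & leaf_labels(tree)
    if len(survivors) < 3:
        raise TreeValidationError(
            f"restriction leaves only {len(survivors)} taxa (need >= 3)")
    t = _clone(tree)
    t.retain_taxa_with_labels(sorted(survivors))
    return t


# ---------------------------------------------------------------------------
# Tree sets and manifests


@dataclass
class TreeSet:
    """Trees on a shared taxon namespace with per-tree provenance labels."""

    trees: list[dendropy.Tree] = field(default_factory=list)
    group_labels: list[str] = field(default_factory=list)
    analysis_ids: list[str] = field(default_factory=list)
    taxon_namespace: dendropy.TaxonNamespace = field(
        default_factory=dendropy.TaxonNamespace)

    def __post_init__(self):
        if not (len(self.trees) == len(self.group_labels) == len(self.analysis_ids)):
            raise ValueError("trees, group_labels, analysis_ids must align")
        if any(not g for g in self.group_labels):
            raise ValueError("group labels must be non-empty")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(zip(self.trees, self.group_labels, self.analysis_ids))

    def add(self, tree: dendropy.Tree, group: str, analysis_id: str) -> None:
        if not group:
            raise ValueError("group label must be non-empty")
        self.trees.append(tree)
        self.group_labels.append(group)
        self.analysis_ids.append(analysis_id)

    @property
    def taxon_set(self) -> TaxonSet:
        labels: set[str] = set()
        for t in self.trees:
            labels |= leaf_labels(t)
        return TaxonSet(tuple(labels))

    def subset(self, group: str) -> "TreeSet":
        ts = TreeSet(taxon_namespace=self.taxon_namespace)
        for t, g, a in self:
            if g == group:
                ts.add(t, g, a)
        return ts

    def groups(self) -> list[str]:
        seen = []
        for g in self.group_labels:
            if g not in seen:
                seen.append(g)
        return seen


def read_tree_file(path: str | Path,
                   taxon_namespace: dendropy.TaxonNamespace | None = None,
                   ) -> list[dendropy.Tree]:
    return parse_newick_list(Path(path).read_text(), taxon_namespace)


def read_manifest(path: str | Path) -> TreeSet:
    """Read a tree-set manifest: TSV rows of (path, group_label, analysis_id).

    Paths are resolved relative to the manifest's directory.  A file with
    multiple trees yields one entry per tree with ``analysis_id`` suffixed
    by its index.
    """
    path = Path(path)
    ts = TreeSet()
    rows = [ln.split("\t") for ln in path.read_text().splitlines()
            if ln.strip() and not ln.startswith("#")]
    if not rows:
        raise ValueError(f"empty manifest: {path}")
    for row in rows:
        if len(row) != 3:
            raise ValueError(f"manifest row must have 3 columns: {row!r}")
        tree_path, group, analysis_id = row
        p = Path(tree_path)
        if not p.is_absolute():
            p = path.parent / p
        try:
            trees = read_tree_file(p, ts.taxon_namespace)
        except (OSError, NewickParseError, TreeValidationError) as exc:
            raise ValueError(f"manifest row {row!r}: {exc}") from exc
        if len(trees) == 1:
            ts.add(trees[0], group, analysis_id)
        else:
            for i, t in enumerate(trees):
                ts.add(t, group, f"{analysis_id}.{i}")
    return ts


def write_manifest(ts: TreeSet, out_dir: str | Path,
                   manifest_name: str = "trees.tsv") -> Path:
    """Write each tree to its own newick file plus a manifest TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = []
    for i, (tree, group, aid) in enumerate(ts):
        fname = f"tree_{i:04d}.nwk"
        (out_dir / fname).write_text(write_newick(tree) + "\n")
        lines.append(f"{fname}\t{group}\t{aid}")
    manifest = out_dir / manifest_name
    manifest.write_text("\n".join(lines) + "\n")
    return manifest
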